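"""Reading and writing external formats: FASTA, GFF3/BED + genome, TSV tables.

FASTA headers for pre-extracted transcript records carry key=value metadata::

    >YDR082W cds_start=101 tl_length=49 species=yeast

``cds_start`` is the 1-based position of the first CDS base within the given
sequence; ``tl_length`` may instead come from a separate TL-length table
(gene_id -> length, tab-separated). The record's TL is the ``tl_length``
bases immediately 5' of ``cds_start`` and the downstream sequence is
everything from ``cds_start`` to the end of the entry.

ORF-call tables are TSV with columns gene/start/stop/class/length_aa/
frame_offset, start and stop in the package's relative coordinates (stop =
position of the third base of the stop codon; NA when absent).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .orf_scanner import OrfClass, UpstreamOrfCall
from .records import TranscriptLeaderRecord, reverse_complement

logger = logging.getLogger(__name__)

ORF_TABLE_COLUMNS = ["gene", "start", "stop", "class", "length_aa", "frame_offset"]


@dataclass
class LoadResult(Sequence):
    """Records plus a skip report; behaves as a sequence of records."""

    records: list[TranscriptLeaderRecord] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (gene_id, reason)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[TranscriptLeaderRecord]:
        return iter(self.records)

    @property
    def skip_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.skipped:
            out[reason] = out.get(reason, 0) + 1
        return out


def _parse_header_meta(description: str) -> dict[str, str]:
    meta = {}
    for tok in description.split()[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    return meta


def read_transcript_fasta(
    path: str | os.PathLike,
    tl_table: Mapping[str, int] | None = None,
) -> LoadResult:
    """Read pre-extracted transcript records from FASTA.

    Each entry needs ``cds_start`` in its header and a TL length, either as
    header ``tl_length`` or via ``tl_table``. Genes with no TL length are
    skipped and counted; a declared TL longer than the available upstream
    sequence skips the record with reason ``tl_longer_than_upstream``.
    """
    result = LoadResult()
    try:
        entries = list(SeqIO.parse(os.fspath(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - Bio raises on malformed input
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    for entry in entries:
        gene_id = entry.id
        if not gene_id:
            raise ValueError(f"malformed FASTA {path}: entry with empty header")
        meta = _parse_header_meta(entry.description)
        if "cds_start" not in meta:
            result.skipped.append((gene_id, "no_cds_start"))
            continue
        cds_start = int(meta["cds_start"])
        if "tl_length" in meta:
            tl_len = int(meta["tl_length"])
        elif tl_table is not None and gene_id in tl_table:
            tl_len = int(tl_table[gene_id])
        else:
            result.skipped.append((gene_id, "no_tl_length"))
            continue
        seq = str(entry.seq).upper()
        if tl_len > cds_start - 1:
            result.skipped.append((gene_id, "tl_longer_than_upstream"))
            continue
        tl = seq[cds_start - 1 - tl_len : cds_start - 1]
        ds = seq[cds_start - 1 :]
        if len(ds) < 3:
            result.skipped.append((gene_id, "downstream_too_short"))
            continue
        result.records.append(
            TranscriptLeaderRecord(
                gene_id=gene_id, tl_seq=tl, downstream_seq=ds,
                species_label=meta.get("species"),
            )
        )
    return result


def write_transcript_fasta(
    records: Sequence[TranscriptLeaderRecord], path: str | os.PathLike
) -> None:
    """Write records as FASTA with cds_start/tl_length header metadata."""
    entries = []
    for rec in records:
        desc = f"cds_start={rec.tl_length + 1} tl_length={rec.tl_length}"
        if rec.species_label:
            desc += f" species={rec.species_label}"
        entries.append(
            SeqRecord(Seq(rec.tl_seq + rec.downstream_seq), id=rec.gene_id, description=desc)
        )
    SeqIO.write(entries, os.fspath(path), "fasta")


# ---------------------------------------------------------------------------
# genome + features extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Feature:
    gene_id: str
    contig: str
    cds_start: int  # 1-based position of the first CDS base on the contig
    cds_end: int    # 1-based inclusive end of the feature span
    strand: str


def _read_gff3_features(path: str) -> list[_Feature]:
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    for f in db.all_features():
        if f.featuretype not in ("gene", "mRNA", "CDS"):
            continue
        gene_id = f.attributes.get("ID", [f.id])[0]
        if f.strand not in "+-":
            raise ValueError(f"{path}: unknown strand {f.strand!r} for {gene_id}")
        feats.append(_Feature(gene_id, f.seqid, f.start, f.end, f.strand))
    return feats


def _read_bed_features(path: str) -> list[_Feature]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    feats = []
    for row in df.itertuples(index=False):
        if row.strand not in "+-":
            raise ValueError(f"{path}: unknown strand {row.strand!r} for {row.name}")
        # BED is 0-based half-open -> 1-based inclusive
        feats.append(_Feature(str(row.name), str(row.contig), int(row.start) + 1,
                              int(row.end), str(row.strand)))
    return feats


def extract_records_from_genome(
    genome: str | os.PathLike,
    features: str | os.PathLike,
    tl_table: Mapping[str, int],
    window: int = 300,
    dialect: str | None = None,
) -> LoadResult:
    """Extract TL + downstream records from a genome FASTA and feature file.

    The feature span is taken as the CDS; for minus-strand genes both
    sequences are reverse-complemented so every record reads 5'->3'.
    ``dialect`` is "gff3" (1-based inclusive) or "bed" (0-based half-open);
    by default it is chosen from the file extension.
    """
    features = os.fspath(features)
    if dialect is None:
        dialect = "bed" if features.lower().endswith(".bed") else "gff3"
    if dialect == "gff3":
        feats = _read_gff3_features(features)
    elif dialect == "bed":
        feats = _read_bed_features(features)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    fa = Fasta(os.fspath(genome))
    result = LoadResult()
    for f in feats:
        if f.gene_id not in tl_table:
            result.skipped.append((f.gene_id, "no_tl_length"))
            continue
        L = int(tl_table[f.gene_id])
        if f.contig not in fa:
            result.skipped.append((f.gene_id, "contig_not_in_genome"))
            continue
        contig = fa[f.contig]
        clen = len(contig)
        if f.strand == "+":
            tl_lo, tl_hi = f.cds_start - 1 - L, f.cds_start - 1  # 0-based half-open
            ds_lo, ds_hi = f.cds_start - 1, f.cds_start - 1 + window
            if tl_lo < 0 or ds_hi > clen:
                result.skipped.append((f.gene_id, "coordinates_outside_contig"))
                continue
            tl = str(contig[tl_lo:tl_hi]).upper()
            ds = str(contig[ds_lo:ds_hi]).upper()
        else:
            # CDS first base is the feature end on the forward strand
            tl_lo, tl_hi = f.cds_end, f.cds_end + L
            ds_lo, ds_hi = f.cds_end - window, f.cds_end
            if ds_lo < 0 or tl_hi > clen:
                result.skipped.append((f.gene_id, "coordinates_outside_contig"))
                continue
            tl = reverse_complement(str(contig[tl_lo:tl_hi]).upper())
            ds = reverse_complement(str(contig[ds_lo:ds_hi]).upper())
        if len(ds) < 3:
            result.skipped.append((f.gene_id, "downstream_too_short"))
            continue
        result.records.append(TranscriptLeaderRecord(f.gene_id, tl, ds))
    return result


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def write_orf_table(calls: Sequence[UpstreamOrfCall], path: str | os.PathLike) -> None:
    """Write ORF calls as TSV in the relative-coordinate convention."""
    rows = [
        {
            "gene": c.gene_id,
            "start": c.start,
            "stop": c.stop_third_base,
            "class": c.orf_class.value,
            "length_aa": c.length_aa,
            "frame_offset": c.frame_offset,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=ORF_TABLE_COLUMNS)
    df.to_csv(os.fspath(path), sep="\t", index=False, na_rep="NA")


def read_orf_table(path: str | os.PathLike) -> list[UpstreamOrfCall]:
    """Read an ORF-call TSV back into UpstreamOrfCall objects."""
    df = pd.read_csv(os.fspath(path), sep="\t", na_values=["NA"])
    calls = []
    for row in df.to_dict("records"):
        stop = None if pd.isna(row["stop"]) else int(row["stop"])
        length = None if pd.isna(row["length_aa"]) else int(row["length_aa"])
        calls.append(
            UpstreamOrfCall(
                gene_id=str(row["gene"]),
                start=int(row["start"]),
                stop_third_base=stop,
                length_aa=length,
                frame_offset=int(row["frame_offset"]),
                orf_class=OrfClass(row["class"]),
            )
        )
    return calls


def read_tl_table(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column gene_id -> TL length TSV (header optional)."""
    df = pd.read_csv(os.fspath(path), sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    out: dict[str, int] = {}
    for g, v in zip(df.iloc[:, 0], df.iloc[:, 1]):
        try:
            out[str(g)] = int(v)
        except (TypeError, ValueError):
            continue  # header or malformed row
    if not out:
        raise ValueError(f"{path}: no numeric TL lengths found")
    return out


def read_abundance_table(path: str | os.PathLike) -> tuple[dict[str, float], int]:
    """Read a gene_id -> abundance TSV; returns (mapping, n_dropped).

    Non-numeric or missing values are dropped and counted; on duplicated
    gene_ids the last value wins (with a logged warning).
    """
    df = pd.read_csv(os.fspath(path), sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    dropped = 0
    out: dict[str, float] = {}
    for g, v in zip(df.iloc[:, 0], df.iloc[:, 1]):
        val = pd.to_numeric(v, errors="coerce")
        if pd.isna(val):
            dropped += 1
            continue
        g = str(g)
        if g in out:
            logger.warning("duplicated gene_id %s in %s: last value wins", g, path)
        out[g] = float(val)
    if not out:
        raise ValueError("empty abundance table")
    return out, dropped
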