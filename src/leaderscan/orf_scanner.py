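"""Scan transcript leaders for upstream AUGs and classify the resulting ORFs.

Every AUG lying entirely within the transcript leader (first base at relative
position <= -3) opens a potential upstream ORF. Walking codons 3' from that
AUG, the first in-frame stop (TAA/TAG/TGA) decides the class:

* **uORF** - the stop lies wholly within the leader (third stop base <= -1).
  uORFs can occur in any of the 3 reading frames relative to the CDS.
* **oORF** - the AUG is out of frame with the CDS (frame offset != 0) and the
  stop ends at or after the first CDS base (third stop base >= +1), so the
  upstream ORF overlaps the main ORF's start. Only 2 reading frames can
  produce an oORF: in the CDS frame an upstream AUG with no leader-internal
  stop is an N-terminal extension instead.
* **n_terminal_extension** - in-frame AUG with no stop wholly within the
  leader; translation would extend the main protein.
* **no_stop_in_window** - out-of-frame AUG with no stop found within
  leader + downstream window. Excluded from cohort fractions (reported
  separately); with windows >= 300 nt these are vanishingly rare.

Codons containing N match nothing (neither start nor stop).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .records import TranscriptLeaderRecord

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class OrfClass(str, Enum):
    UORF = "uORF"
    OORF = "oORF"
    NTE = "n_terminal_extension"
    NO_STOP = "no_stop_in_window"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class UpstreamOrfCall:
    """One upstream-AUG-initiated ORF in relative coordinates.

    ``start`` is the relative position of the uAUG first base (<= -3).
    ``stop_third_base`` is the relative position of the third base of the
    first in-frame stop codon (None when no stop was found in the window).
    ``length_aa`` counts sense codons including the initiator Met, stop
    excluded. ``frame_offset`` is d mod 3 with d the nucleotide distance from
    the uAUG first base to the CDS first base; 0 means in frame with the CDS.
    """

    gene_id: str
    start: int
    stop_third_base: int | None
    length_aa: int | None
    frame_offset: int
    orf_class: OrfClass


@dataclass(frozen=True)
class GeneOrfSummary:
    """Per-gene call tallies; the unit of cohort fractions."""

    gene_id: str
    tl_length: int
    n_uORF: int = 0
    n_oORF: int = 0
    n_nte: int = 0
    n_nostop: int = 0
    tl_has_n: bool = False

    @property
    def has_uORF(self) -> bool:
        return self.n_uORF >= 1

    @property
    def has_oORF(self) -> bool:
        return self.n_oORF >= 1

    @property
    def group(self) -> str:
        if self.has_uORF and self.has_oORF:
            return "both"
        if self.has_uORF:
            return "uORF_only"
        if self.has_oORF:
            return "oORF_only"
        return "none"


def scan_transcript(
    record: TranscriptLeaderRecord, window: int | None = None
) -> list[UpstreamOrfCall]:
    """Find and classify every upstream-AUG ORF in one transcript leader.

    Each uAUG is scanned independently, so nested and overlapping ORFs are
    all reported and two uAUGs may share a stop codon. Calls are ordered by
    start coordinate. The result is a pure function of
    (tl_seq, downstream_seq[:window]).
    """
    tl = record.tl_seq
    ds = record.downstream_seq if window is None else record.downstream_seq[:window]
    L = len(tl)
    combined = tl + ds
    calls: list[UpstreamOrfCall] = []

    i = tl.find(START_CODON)
    while i != -1:
        # the whole AUG must lie within the leader: first base at <= -3
        if i + 3 <= L:
            calls.append(_classify_from(record.gene_id, combined, L, i))
        i = tl.find(START_CODON, i + 1)
    return calls


def _classify_from(gene_id: str, combined: str, L: int, i: int) -> UpstreamOrfCall:
    d = L - i
    frame_offset = d % 3
    stop_end: int | None = None
    for j in range(i + 3, len(combined) - 2, 3):
        codon = combined[j : j + 3]
        if codon in STOP_CODONS:
            stop_end = j + 2
            break

    def rel(idx: int) -> int:
        return idx - L if idx < L else idx - L + 1

    if stop_end is not None:
        stop_rel = rel(stop_end)
        length_aa = (stop_end - 2 - i) // 3
        if stop_rel <= -1:
            cls = OrfClass.UORF
        elif frame_offset != 0:
            cls = OrfClass.OORF
        else:
            # in frame with the CDS and no leader-internal stop: an
            # N-terminal extension; the downstream stop belongs to the CDS
            # frame and is not part of the call (keeps calls independent of
            # the window size)
            return UpstreamOrfCall(gene_id, rel(i), None, None, 0, OrfClass.NTE)
        return UpstreamOrfCall(gene_id, rel(i), stop_rel, length_aa, frame_offset, cls)

    cls = OrfClass.NTE if frame_offset == 0 else OrfClass.NO_STOP
    return UpstreamOrfCall(gene_id, rel(i), None, None, frame_offset, cls)


def summarize_gene(
    calls: Sequence[UpstreamOrfCall],
    tl_length: int,
    gene_id: str | None = None,
    tl_has_n: bool = False,
) -> GeneOrfSummary:
    """Tally one gene's calls into presence flags and counts.

    N-terminal extensions and no-stop calls never set has_uORF/has_oORF.
    """
    ids = {c.gene_id for c in calls}
    if len(ids) > 1:
        raise ValueError(f"calls mix gene_ids: {sorted(ids)}")
    if gene_id is None:
        if not ids:
            raise ValueError("gene_id required when the call list is empty")
        gene_id = ids.pop()
    elif ids and ids != {gene_id}:
        raise ValueError(f"calls belong to {ids.pop()!r}, not {gene_id!r}")

    n = Counter(c.orf_class for c in calls)
    return GeneOrfSummary(
        gene_id=gene_id,
        tl_length=tl_length,
        n_uORF=n[OrfClass.UORF],
        n_oORF=n[OrfClass.OORF],
        n_nte=n[OrfClass.NTE],
        n_nostop=n[OrfClass.NO_STOP],
        tl_has_n=tl_has_n,
    )


def scan_and_summarize(
    record: TranscriptLeaderRecord, window: int | None = None
) -> tuple[list[UpstreamOrfCall], GeneOrfSummary]:
    calls = scan_transcript(record, window=window)
    return calls, summarize_gene(
        calls, record.tl_length, gene_id=record.gene_id, tl_has_n=record.tl_has_n
    )


def scan_cohort(
    records: Iterable[TranscriptLeaderRecord], window: int | None = None
) -> tuple[list[UpstreamOrfCall], list[GeneOrfSummary]]:
    """Scan a cohort; returns the flat call list and one summary per gene."""
    all_calls: list[UpstreamOrfCall] = []
    summaries: list[GeneOrfSummary] = []
    for rec in records:
        calls, summ = scan_and_summarize(rec, window=window)
        all_calls.extend(calls)
        summaries.append(summ)
    return all_calls, summaries
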