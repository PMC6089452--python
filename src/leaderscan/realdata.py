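"""Entry points for analyses of real (user-retrieved) sequence data.

The package ships no genome or transcriptome data. To run the real-data
analyses, download the inputs yourself and place them under ``data/real/``
in the working directory (all plain text):

* ``stn1_yeast.fasta`` — the S. cerevisiae STN1 (YDR082W) region: CDS plus
  at least 500 nt upstream, one FASTA entry with ``cds_start``/``tl_length``
  header metadata (see :mod:`leaderscan.transcript_io`). Retrievable from
  YeastMine / SGD.
* ``stn1_human.fasta`` — the human STN1 (OBFC1/ENSG00000107960) transcript
  leader plus CDS, same header convention. Retrievable from Ensembl Biomart.
* ``cohort_<species>.fasta`` + ``tl_lengths_<species>.tsv`` — a genome-wide
  transcript cohort and its TL-length table for the observed-vs-expected
  fractions analysis.

These loaders raise FileNotFoundError with retrieval instructions when the
files are absent; nothing is downloaded automatically.
"""

from __future__ import annotations

import os
from pathlib import Path

from .null_model import NullConfig
from .records import TranscriptLeaderRecord
from .selection_analysis import CohortFractions, cohort_fractions
from .transcript_io import read_tl_table, read_transcript_fasta

DEFAULT_DATA_DIR = Path("data/real")


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: {what} must be retrieved by the user "
            "(see leaderscan.realdata module docs) — no data ships with the package"
        )
    return path


def load_real_stn1(species: str, data_dir: str | os.PathLike = DEFAULT_DATA_DIR) -> TranscriptLeaderRecord:
    """Load the user-retrieved real STN1 record for 'yeast' or 'human'."""
    if species not in ("yeast", "human"):
        raise ValueError("species must be 'yeast' or 'human'")
    path = _require(Path(data_dir) / f"stn1_{species}.fasta", f"the real {species} STN1 sequence")
    res = read_transcript_fasta(path)
    if len(res) != 1:
        raise ValueError(f"{path}: expected exactly one record, found {len(res)}")
    return res[0]


def real_cohort_fractions(
    species: str,
    data_dir: str | os.PathLike = DEFAULT_DATA_DIR,
    n_randomizations: int = 1,
    seed: int = 17,
    window: int = 300,
) -> CohortFractions:
    """Observed vs single-randomization expected fractions on a real cohort."""
    data_dir = Path(data_dir)
    fasta = _require(data_dir / f"cohort_{species}.fasta", f"the {species} transcript cohort")
    tl_path = _require(data_dir / f"tl_lengths_{species}.tsv", f"the {species} TL-length table")
    records = list(read_transcript_fasta(fasta, read_tl_table(tl_path)))
    cfg = NullConfig(n_randomizations=n_randomizations, seed=seed, window=window)
    return cohort_fractions(records, cfg)
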