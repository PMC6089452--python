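"""Core record type: a transcript leader plus its CDS-proximal downstream sequence.

Relative coordinate convention used throughout the package (mirrors the
supplementary-table convention of uORF/oORF location lists): coordinates are
1-based with **no position 0**. The first base of the CDS is +1 and the last
base of the transcript leader (TL) is -1, so positions run

    ... -3, -2, -1, +1, +2, +3 ...

across the TL/CDS boundary. A nucleotide span that straddles the boundary is
therefore one shorter than ``stop - start + 1`` would suggest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

_ALPHABET = set("ACGTN")

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class TranscriptLeaderRecord:
    """One gene's transcript leader (5' UTR) and downstream CDS-side sequence.

    Parameters
    ----------
    gene_id
        Opaque gene identifier.
    tl_seq
        Transcript-leader sequence, 5'->3', over {A,C,G,T,N}. May be empty.
    downstream_seq
        Sequence starting at the first base of the annotated CDS (so it
        normally begins with ATG); at least 3 nt. The oORF stop-codon search
        runs into this sequence.
    species_label
        Optional free-text label (e.g. "yeast", "human").
    """

    gene_id: str
    tl_seq: str
    downstream_seq: str
    species_label: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "tl_seq", self.tl_seq.upper())
        object.__setattr__(self, "downstream_seq", self.downstream_seq.upper())
        for name, seq in (("tl_seq", self.tl_seq), ("downstream_seq", self.downstream_seq)):
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(
                    f"{self.gene_id}: {name} contains non-DNA characters {sorted(bad)!r}"
                )
        if len(self.downstream_seq) < 3:
            raise ValueError(
                f"{self.gene_id}: downstream_seq must be at least 3 nt "
                f"(got {len(self.downstream_seq)})"
            )
        if not self.downstream_seq.startswith("ATG"):
            warnings.warn(
                f"{self.gene_id}: downstream sequence does not begin with ATG",
                stacklevel=2,
            )

    @property
    def tl_length(self) -> int:
        return len(self.tl_seq)

    @property
    def window(self) -> int:
        return len(self.downstream_seq)

    @property
    def tl_has_n(self) -> bool:
        return "N" in self.tl_seq

    # -- relative-coordinate helpers ------------------------------------

    def rel_to_index(self, pos: int) -> int:
        """Map a relative coordinate (no position 0) to an index in tl+downstream."""
        if pos == 0:
            raise ValueError("there is no position 0: CDS first base is +1, last TL base is -1")
        if pos < 0:
            idx = self.tl_length + pos
            if idx < 0:
                raise ValueError(f"position {pos} lies upstream of the TL (length {self.tl_length})")
            return idx
        idx = self.tl_length + pos - 1
        if idx >= self.tl_length + len(self.downstream_seq):
            raise ValueError(f"position {pos} lies beyond the downstream window")
        return idx

    def index_to_rel(self, idx: int) -> int:
        """Inverse of :meth:`rel_to_index` for an index into tl+downstream."""
        if idx < self.tl_length:
            return idx - self.tl_length
        return idx - self.tl_length + 1

    def with_tl(self, new_tl: str) -> "TranscriptLeaderRecord":
        return replace(self, tl_seq=new_tl)
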