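"""Point-substitution re-annotation: how leader mutations reshape ORF architecture.

Mimics in software the classic leader-mutagenesis designs: knocking out an
upstream initiation codon (start loss destroys the call), or mutating a
termination codon so the ORF runs on to the next in-frame stop
(stop-loss extension). Calls are matched across the edit by their start
coordinate — a stop mutation preserves the start, a start mutation destroys
the call.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

from .orf_scanner import UpstreamOrfCall, scan_transcript
from .records import TranscriptLeaderRecord

_SUB_RE = re.compile(r"^([+-]?\d+)([ACGT])>([ACGT])$")


@dataclass(frozen=True)
class Substitution:
    """A single-base substitution in relative coordinates (no position 0)."""

    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.pos:+d}{self.ref}>{self.alt}"


def parse_substitution(spec: str) -> Substitution:
    """Parse ``<relpos><ref>><alt>`` syntax, e.g. ``-13A>T`` or ``+4A>C``."""
    m = _SUB_RE.match(spec.strip())
    if not m:
        raise ValueError(f"cannot parse substitution {spec!r} (expected e.g. -13A>T)")
    pos = int(m.group(1))
    if pos == 0:
        raise ValueError("no position 0: CDS first base is +1, last TL base is -1")
    return Substitution(pos=pos, ref=m.group(2), alt=m.group(3))


def apply_substitution(
    record: TranscriptLeaderRecord, pos: int, alt: str, ref: str | None = None
) -> TranscriptLeaderRecord:
    """Replace one base at a relative position; all other bases unchanged.

    Positions >= +1 edit the downstream (CDS-side) sequence and are
    permitted but flagged with a warning. If ``ref`` is given it is checked
    against the record. Substituting a base for itself warns
    ("synonymous with reference") and returns the record unchanged.
    """
    if alt not in "ACGT":
        raise ValueError(f"alt must be one of A/C/G/T, got {alt!r}")
    idx = record.rel_to_index(pos)  # raises on pos == 0 / out of range
    L = record.tl_length
    current = (record.tl_seq + record.downstream_seq)[idx]
    if ref is not None and ref != current:
        raise ValueError(
            f"{record.gene_id}: reference mismatch at {pos:+d}: record has {current}, "
            f"substitution expects {ref}"
        )
    if alt == current:
        warnings.warn(f"{record.gene_id}: {pos:+d}{current}>{alt} is synonymous with reference")
        return record
    if pos >= 1:
        warnings.warn(f"{record.gene_id}: substitution {pos:+d}{current}>{alt} alters the CDS")
        ds_idx = idx - L
        new_ds = record.downstream_seq[:ds_idx] + alt + record.downstream_seq[ds_idx + 1 :]
        return replace(record, downstream_seq=new_ds)
    new_tl = record.tl_seq[:idx] + alt + record.tl_seq[idx + 1 :]
    return record.with_tl(new_tl)


def apply_substitutions(
    record: TranscriptLeaderRecord, subs: Sequence[Substitution]
) -> TranscriptLeaderRecord:
    """Apply several substitutions left-to-right in one pass."""
    for sub in sorted(subs, key=lambda s: (s.pos > 0, s.pos)):
        record = apply_substitution(record, sub.pos, sub.alt, ref=sub.ref)
    return record


# ---------------------------------------------------------------------------
# architecture diff
# ---------------------------------------------------------------------------

#: verdict tags
START_LOSS = "start_loss"
STOP_LOSS_EXTENSION = "stop_loss_extension"
STOP_GAIN_TRUNCATION = "stop_gain_truncation"
CLASS_CHANGE = "class_change"
START_GAIN = "start_gain"


@dataclass(frozen=True)
class AlteredCall:
    before: UpstreamOrfCall
    after: UpstreamOrfCall
    tags: frozenset[str]


@dataclass(frozen=True)
class ArchitectureDiff:
    """Created/destroyed/altered ORF calls between a reference and an edited leader."""

    destroyed: tuple[UpstreamOrfCall, ...] = ()
    created: tuple[UpstreamOrfCall, ...] = ()
    altered: tuple[AlteredCall, ...] = ()
    unchanged: tuple[UpstreamOrfCall, ...] = ()

    @property
    def is_empty(self) -> bool:
        return not (self.destroyed or self.created or self.altered)


def diff_architecture(
    before: Sequence[UpstreamOrfCall], after: Sequence[UpstreamOrfCall]
) -> ArchitectureDiff:
    """Match calls by start coordinate and classify every change.

    A call whose stop moved downstream (or out of the window) is tagged
    ``stop_loss_extension``; a stop moving upstream is
    ``stop_gain_truncation``; any class change (e.g. a uORF whose stop now
    lies in the CDS becoming an oORF) adds ``class_change``. Destroyed calls
    are tagged start_loss implicitly (their uAUG is gone).
    """
    ids = {c.gene_id for c in before} | {c.gene_id for c in after}
    if len(ids) > 1:
        raise ValueError(f"calls mix gene_ids: {sorted(ids)}")
    bmap = {c.start: c for c in before}
    amap = {c.start: c for c in after}
    if len(bmap) != len(before) or len(amap) != len(after):
        raise ValueError("duplicate start coordinates within one call list")

    destroyed = tuple(bmap[s] for s in sorted(bmap.keys() - amap.keys()))
    created = tuple(amap[s] for s in sorted(amap.keys() - bmap.keys()))
    altered: list[AlteredCall] = []
    unchanged: list[UpstreamOrfCall] = []
    for s in sorted(bmap.keys() & amap.keys()):
        b, a = bmap[s], amap[s]
        if b == a:
            unchanged.append(b)
            continue
        tags: set[str] = set()
        if b.stop_third_base != a.stop_third_base:
            b_stop = b.stop_third_base if b.stop_third_base is not None else float("inf")
            a_stop = a.stop_third_base if a.stop_third_base is not None else float("inf")
            tags.add(STOP_LOSS_EXTENSION if a_stop > b_stop else STOP_GAIN_TRUNCATION)
        if b.orf_class != a.orf_class:
            tags.add(CLASS_CHANGE)
        altered.append(AlteredCall(before=b, after=a, tags=frozenset(tags)))
    return ArchitectureDiff(
        destroyed=destroyed, created=created, altered=tuple(altered),
        unchanged=tuple(unchanged),
    )


def annotate_variant(
    record: TranscriptLeaderRecord,
    subs: Sequence[Substitution],
    window: int | None = None,
) -> tuple[TranscriptLeaderRecord, ArchitectureDiff]:
    """Apply substitutions and diff the scan output before vs after."""
    before = scan_transcript(record, window=window)
    mutated = apply_substitutions(record, subs)
    after = scan_transcript(mutated, window=window)
    return mutated, diff_architecture(before, after)
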