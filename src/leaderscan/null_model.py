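"""Null models for uORF/oORF occurrence in transcript leaders.

Two nulls are provided:

1. A per-leader permutation null: each TL is shuffled (a uniform random
   permutation of its own bases, preserving mononucleotide composition) and
   rescanned against its *real* downstream sequence. This is the empirical
   "expected" arm of the observed-vs-expected comparison.
2. An exact analytic model for i.i.d. random leaders of a given length and
   base composition: the probability that a leader contains at least one
   uORF, at least one oORF, and at least one in-frame open uAUG (N-terminal
   extension) is computed by a product-automaton dynamic program, without
   simulation. A brute-force enumerator over all 4^L leaders serves as the
   independent oracle for small L.

The permutation null conditions on each leader's realized composition; the
analytic model assumes i.i.d. draws. Over cohorts whose leaders were
themselves generated i.i.d. the two agree in expectation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .orf_scanner import OrfClass, scan_transcript, summarize_gene, GeneOrfSummary
from .records import TranscriptLeaderRecord

BASES = "ACGT"
UNIFORM = {b: 0.25 for b in BASES}

#: Default downstream context for enumeration oracles: begins with ATG and
#: contains a stop codon in all three downstream reading frames, so no
#: out-of-frame open uAUG is ever left without a stop in the window.
DEFAULT_ORACLE_DOWNSTREAM = "ATGAAGGGTTAACCTAAGGG"


@dataclass(frozen=True)
class NullConfig:
    """Configuration of the randomization / analytic null.

    n_randomizations defaults to 1, mirroring a single-permutation design;
    >= 10 replicates with mean +/- sd are recommended for stable expected
    fractions.
    """

    n_randomizations: int = 1
    seed: int | None = None
    base_probs: dict[str, float] = field(default_factory=lambda: dict(UNIFORM))
    window: int | None = None

    def __post_init__(self):
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be a positive integer")
        _validate_probs(self.base_probs)


def _validate_probs(base_probs: dict[str, float]) -> None:
    if set(base_probs) != set(BASES):
        raise ValueError(f"base_probs must have keys exactly {set(BASES)}")
    vals = list(base_probs.values())
    if any(p < 0 or p > 1 for p in vals):
        raise ValueError("base probabilities must lie in [0, 1]")
    if abs(sum(vals) - 1.0) > 1e-12:
        raise ValueError(f"base probabilities sum to {sum(vals)!r}, not 1")


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


def shuffle_leader(
    record: TranscriptLeaderRecord, rng: np.random.Generator
) -> TranscriptLeaderRecord:
    """Return the record with its TL replaced by a uniform random permutation.

    The downstream (CDS-side) sequence is never shuffled: oORF stop search
    must run into genuine CDS sequence.
    """
    bases = np.frombuffer(record.tl_seq.encode(), dtype="S1").copy()
    shuffled = rng.permutation(bases)
    return record.with_tl(shuffled.tobytes().decode())


def randomized_summaries(
    records: list[TranscriptLeaderRecord], cfg: NullConfig
) -> list[list[GeneOrfSummary]]:
    """Shuffle every TL once per replicate and rescan; one summary list per replicate."""
    if not records:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(cfg.seed)
    out = []
    for _ in range(cfg.n_randomizations):
        rep = []
        for rec in records:
            shuf = shuffle_leader(rec, rng)
            assert sorted(shuf.tl_seq) == sorted(rec.tl_seq)  # composition preserved
            calls = scan_transcript(shuf, window=cfg.window)
            rep.append(
                summarize_gene(calls, shuf.tl_length, gene_id=shuf.gene_id, tl_has_n=shuf.tl_has_n)
            )
        out.append(rep)
    return out


@dataclass(frozen=True)
class ExpectedFractions:
    """Shuffle-expected cohort fractions: per-replicate values, mean and sd."""

    n_genes: int
    n_randomizations: int
    frac_uORF_reps: tuple[float, ...]
    frac_oORF_reps: tuple[float, ...]

    @property
    def frac_uORF_mean(self) -> float:
        return float(np.mean(self.frac_uORF_reps))

    @property
    def frac_oORF_mean(self) -> float:
        return float(np.mean(self.frac_oORF_reps))

    @property
    def frac_uORF_sd(self) -> float:
        return float(np.std(self.frac_uORF_reps, ddof=1)) if self.n_randomizations > 1 else 0.0

    @property
    def frac_oORF_sd(self) -> float:
        return float(np.std(self.frac_oORF_reps, ddof=1)) if self.n_randomizations > 1 else 0.0


def expected_fractions(
    records: list[TranscriptLeaderRecord], cfg: NullConfig
) -> ExpectedFractions:
    """Fraction of genes with >= 1 uORF / oORF after per-TL randomization."""
    reps = randomized_summaries(records, cfg)
    n = len(records)
    return ExpectedFractions(
        n_genes=n,
        n_randomizations=cfg.n_randomizations,
        frac_uORF_reps=tuple(sum(s.has_uORF for s in rep) / n for rep in reps),
        frac_oORF_reps=tuple(sum(s.has_oORF for s in rep) / n for rep in reps),
    )


# ---------------------------------------------------------------------------
# exact analytic model (product-automaton dynamic program)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PresenceProbs:
    """P(>=1 uORF), P(>=1 oORF), P(>=1 N-terminal-extension) for an i.i.d. TL."""

    p_uORF: float
    p_oORF: float
    p_nte: float


def analytic_presence_prob(L: int, base_probs: dict[str, float] | None = None) -> PresenceProbs:
    """Exact class-presence probabilities for an i.i.d. random TL of length L.

    The leader is read base by base while three codon-phase automata (one per
    reading frame) run jointly. Each phase tracks (a) the informative prefix
    of its pending codon — enough to recognize ATG and TAA/TAG/TGA on
    completion — and (b) whether an ORF opened by an earlier in-phase ATG is
    still open (no in-phase stop seen since). A global flag records whether
    any ORF has been closed by a stop lying wholly within the leader (a
    uORF). At the end of the leader, an open phase whose frame offset
    relative to the CDS is nonzero contributes an oORF — the downstream CDS
    region is modeled as containing an in-frame stop with probability 1, and
    whether that stop straddles the boundary or not, the class is oORF — and
    an open in-frame phase contributes an N-terminal extension.

    The joint state space stays below a few hundred states, so the program
    is exact (no sampling) and O(L * states) time.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    probs = dict(UNIFORM) if base_probs is None else base_probs
    _validate_probs(probs)

    # per-phase state: (prefix_token, open_flag); global: completed_uORF flag
    init = ((("", False),) * 3, False)
    dp: dict[tuple, float] = {init: 1.0}

    for t in range(L):
        nxt: dict[tuple, float] = {}
        for (phases, completed), p in dp.items():
            for b, pb in probs.items():
                if pb == 0.0:
                    continue
                new_phases = list(phases)
                new_completed = completed
                for phi in range(3):
                    if t < phi:
                        continue  # phase phi's first codon starts at index phi
                    prefix, is_open = new_phases[phi]
                    if (t - phi) % 3 < 2:
                        new_phases[phi] = (_extend_prefix(prefix, b), is_open)
                    else:
                        if prefix == "AT" and b == "G":
                            is_open = True
                        elif (prefix == "TA" and b in "AG") or (prefix == "TG" and b == "A"):
                            if is_open:
                                is_open = False
                                new_completed = True
                        new_phases[phi] = ("", is_open)
                key = (tuple(new_phases), new_completed)
                nxt[key] = nxt.get(key, 0.0) + p * pb
        dp = nxt

    p_u = p_o = p_n = 0.0
    for (phases, completed), p in dp.items():
        if completed:
            p_u += p
        open_frames = {(L - phi) % 3 for phi, (_, is_open) in enumerate(phases) if is_open}
        if open_frames - {0}:
            p_o += p
        if 0 in open_frames:
            p_n += p
    return PresenceProbs(p_uORF=p_u, p_oORF=p_o, p_nte=p_n)


def _extend_prefix(prefix: str, b: str) -> str:
    if prefix == "":
        return b if b in "AT" else "."
    if len(prefix) == 1:
        two = prefix + b
        return two if two in ("AT", "TA", "TG") else ".."
    raise AssertionError("prefix already complete")


def enumerate_presence_prob(
    L: int,
    base_probs: dict[str, float] | None = None,
    downstream: str = DEFAULT_ORACLE_DOWNSTREAM,
) -> PresenceProbs:
    """Brute-force oracle: exact class-presence probabilities by enumerating 4^L leaders.

    Every possible leader of length L is scanned with the real classifier
    (orf_scanner) against a fixed downstream context carrying stops in all
    three frames, and the probability mass of leaders containing each class
    is summed. Ground truth for :func:`analytic_presence_prob`; L <= 10.
    """
    if L > 10:
        raise ValueError("enumeration limited to L <= 10")
    probs = dict(UNIFORM) if base_probs is None else base_probs
    _validate_probs(probs)

    logs = {b: (math.log(probs[b]) if probs[b] > 0 else None) for b in BASES}
    p_u = p_o = p_n = 0.0
    for tl in itertools.product(BASES, repeat=L):
        if any(logs[b] is None for b in tl):
            continue
        mass = math.exp(sum(logs[b] for b in tl))
        rec = TranscriptLeaderRecord("enum", "".join(tl), downstream)
        classes = {c.orf_class for c in scan_transcript(rec)}
        if OrfClass.UORF in classes:
            p_u += mass
        if OrfClass.OORF in classes:
            p_o += mass
        if OrfClass.NTE in classes:
            p_n += mass
    return PresenceProbs(p_uORF=p_u, p_oORF=p_o, p_nte=p_n)
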