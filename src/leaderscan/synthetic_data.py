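"""Synthetic cohorts and fixtures with known ground truth.

Generates transcript-leader cohorts whose uORF/oORF content is known by
construction, so every pipeline stage can be tested end to end without any
external sequence retrieval:

* ``iid`` cohorts — leaders drawn base-by-base from a composition, lengths
  from a lognormal parameterized by its median (yeast-like 49 nt and
  human-like 173 nt presets). Under this mode there is no selection, so
  observed fractions must match shuffle-expected fractions.
* ``planted`` cohorts — a chosen share of genes carries a uORF and/or an
  oORF at known coordinates, all other upstream AUGs scrubbed; the recorded
  truth is computed with the generator's own coordinate arithmetic
  (independent of the scanner) and verified by re-scan with bounded retries.
* ``depleted`` cohorts — i.i.d. leaders rejection-sampled against oORF
  carriers, creating a known negative-selection signal for O/E analyses.

Also provides deterministic STN1-style fixtures: a yeast-like leader with a
16-sense-codon uORF plus a 6-sense-codon oORF terminating just inside the
CDS, its start- and stop-codon point-mutant variants, and a human-like
leader with two overlapping oORFs (15 and 19 sense codons) sharing a stop
codon whose third base is the first CDS base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .orf_scanner import (
    GeneOrfSummary,
    OrfClass,
    UpstreamOrfCall,
    scan_transcript,
)
from .records import TranscriptLeaderRecord
from .variant_effects import Substitution

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")

#: TL length presets: lognormal medians reported for yeast and human cohorts
LENGTH_PRESETS = {
    "yeast": {"median": 49, "sigma": 0.6},
    "human": {"median": 173, "sigma": 0.6},
}


@dataclass(frozen=True)
class GeneTruth:
    """Planted calls (possibly empty) for one synthetic gene; None = unconstrained."""

    gene_id: str
    tl_length: int
    planted_calls: tuple[UpstreamOrfCall, ...] | None


@dataclass(frozen=True)
class SyntheticTruth:
    """Cohort-level ground truth and the parameters that generated it."""

    mode: str
    seed: int | None
    length_model: dict
    composition: dict[str, float]
    prevalence_uORF: float
    prevalence_oORF: float
    rejection_factor: float
    genes: tuple[GeneTruth, ...] = ()


def _draw_length(length_model, rng: np.random.Generator, minimum: int = 0) -> int:
    if isinstance(length_model, Mapping):
        mu = math.log(length_model["median"])
        sigma = length_model.get("sigma", 0.6)
        for _ in range(1000):
            L = int(round(rng.lognormal(mean=mu, sigma=sigma)))
            if L >= minimum:
                return L
        raise RuntimeError("could not draw a TL length satisfying the minimum")
    # empirical list of lengths
    pool = [int(x) for x in length_model if int(x) >= minimum]
    if not pool:
        raise ValueError("no empirical TL length satisfies the minimum")
    return int(rng.choice(pool))


def _draw_bases(n: int, probs: dict[str, float], rng: np.random.Generator) -> str:
    p = np.array([probs[b] for b in BASES])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def _random_downstream(window: int, probs: dict[str, float], rng: np.random.Generator) -> str:
    """ATG + random codons with no premature CDS-frame stop, terminated by a stop."""
    n_codons = max(window // 3, 3)
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        while True:
            c = _draw_bases(3, probs, rng)
            if c not in STOPS:
                codons.append(c)
                break
    codons.append(STOPS[rng.integers(len(STOPS))])
    return "".join(codons)


def _sense_codon(probs, rng, forbid_atg=True) -> str:
    while True:
        c = _draw_bases(3, probs, rng)
        if c in STOPS or (forbid_atg and c == "ATG"):
            continue
        return c


def _scrub_uaugs(tl: str, ds: str, rng: np.random.Generator) -> str | None:
    """Remove every upstream AUG by point edits; None if it fails to converge."""
    for _ in range(100):
        rec = TranscriptLeaderRecord("scrub", tl, ds)
        calls = scan_transcript(rec)
        if not calls:
            return tl
        idx = rec.rel_to_index(calls[0].start)
        repl = "C" if tl[idx] != "C" else "G"
        tl = tl[:idx] + repl + tl[idx + 1 :]
    return None


def _first_stop_from(combined: str, orf_start_idx: int) -> int | None:
    """Generator-side stop search (kept independent of the scanner)."""
    j = orf_start_idx + 3
    while j + 3 <= len(combined):
        if combined[j : j + 3] in STOPS:
            return j + 2
        j += 3
    return None


def _rel(idx: int, L: int) -> int:
    return idx - L if idx < L else idx - L + 1


def generate_cohort(
    n: int,
    length_model: Mapping | Sequence[int] | str = "yeast",
    composition: dict[str, float] | None = None,
    mode: str = "iid",
    prevalence_uORF: float = 0.0,
    prevalence_oORF: float = 0.0,
    rejection_factor: float = 0.8,
    window: int = 300,
    seed: int | None = None,
    max_retries: int = 50,
) -> tuple[list[TranscriptLeaderRecord], SyntheticTruth]:
    """Generate ``n`` synthetic transcript records plus their ground truth.

    ``length_model`` is a preset name ("yeast"/"human"), a
    {"median": .., "sigma": ..} lognormal spec, or an explicit length list.
    In ``planted`` mode each gene independently receives a uORF and/or an
    oORF with the given prevalences at known coordinates; the scan truth is
    verified by re-scan and colliding draws are regenerated (bounded by
    ``max_retries`` per gene). In ``depleted`` mode leaders carrying an oORF
    are rejected with probability ``rejection_factor``, emulating negative
    selection.
    """
    if mode not in ("iid", "planted", "depleted"):
        raise ValueError(f"unknown mode {mode!r}")
    if not (0.0 <= prevalence_uORF <= 1.0 and 0.0 <= prevalence_oORF <= 1.0):
        raise ValueError("prevalences must lie in [0, 1]")
    if isinstance(length_model, str):
        length_model = LENGTH_PRESETS[length_model]
    probs = composition or {b: 0.25 for b in BASES}
    rng = np.random.default_rng(seed)

    records: list[TranscriptLeaderRecord] = []
    gene_truths: list[GeneTruth] = []
    for g in range(n):
        gene_id = f"synth{g:05d}"
        if mode == "iid":
            L = _draw_length(length_model, rng)
            rec = TranscriptLeaderRecord(
                gene_id, _draw_bases(L, probs, rng), _random_downstream(window, probs, rng)
            )
            truth = GeneTruth(gene_id, L, None)
        elif mode == "depleted":
            while True:
                L = _draw_length(length_model, rng)
                rec = TranscriptLeaderRecord(
                    gene_id, _draw_bases(L, probs, rng), _random_downstream(window, probs, rng)
                )
                if any(c.orf_class == OrfClass.OORF for c in scan_transcript(rec)):
                    if rng.random() < rejection_factor:
                        continue
                break
            truth = GeneTruth(gene_id, rec.tl_length, None)
        else:
            want_u = bool(rng.random() < prevalence_uORF)
            want_o = bool(rng.random() < prevalence_oORF)
            rec, planted = _generate_planted_gene(
                gene_id, length_model, probs, want_u, want_o, window, rng, max_retries
            )
            truth = GeneTruth(gene_id, rec.tl_length, planted)
        records.append(rec)
        gene_truths.append(truth)

    truth = SyntheticTruth(
        mode=mode,
        seed=seed,
        length_model=dict(length_model) if isinstance(length_model, Mapping) else {"empirical": True},
        composition=dict(probs),
        prevalence_uORF=prevalence_uORF,
        prevalence_oORF=prevalence_oORF,
        rejection_factor=rejection_factor if mode == "depleted" else 0.0,
        genes=tuple(gene_truths),
    )
    return records, truth


def _generate_planted_gene(
    gene_id, length_model, probs, want_u, want_o, window, rng, max_retries
):
    # a planted uORF needs room for ATG + >=2 sense codons + stop within the
    # leader; a planted oORF needs an out-of-frame uAUG at distance >= 4
    k_u = int(rng.integers(2, 9)) if want_u else 0
    min_len = (3 * (k_u + 1) + 6 if want_u else 0) + (10 if want_o else 0)
    for _ in range(max_retries):
        L = _draw_length(length_model, rng, minimum=max(min_len, 1))
        ds = _random_downstream(window, probs, rng)
        tl = _scrub_uaugs(_draw_bases(L, probs, rng), ds, rng)
        if tl is None:
            continue
        planted: list[UpstreamOrfCall] = []
        if want_o:
            tl, call = _plant_oorf(tl, ds, probs, rng)
            if call is None:
                continue
            planted.append(call)
        if want_u:
            tl, call = _plant_uorf(tl, k_u, planted, probs, rng, gene_id)
            if call is None:
                continue
            planted.append(call)
        planted = [
            UpstreamOrfCall(gene_id, c.start, c.stop_third_base, c.length_aa,
                            c.frame_offset, c.orf_class)
            for c in sorted(planted, key=lambda c: c.start)
        ]
        rec = TranscriptLeaderRecord(gene_id, tl, ds)
        if scan_transcript(rec) == planted:
            return rec, tuple(planted)
    raise RuntimeError(
        f"{gene_id}: could not realize planted architecture "
        f"(want_u={want_u}, k_u={k_u}, want_o={want_o}) within {max_retries} retries"
    )


def _plant_oorf(tl, ds, probs, rng):
    """Write an out-of-frame uAUG near the 3' end of the leader, keep its frame
    open through the boundary, and derive the resulting call arithmetically."""
    L = len(tl)
    choices = [d for d in range(4, min(L, 60) + 1) if d % 3 != 0]
    if not choices:
        return tl, None
    d = int(rng.choice(choices))
    i = L - d
    tl = tl[:i] + "ATG" + tl[i + 3 :]
    # force every in-frame codon wholly within the leader to be sense
    j = i + 3
    while j + 3 <= L:
        if tl[j : j + 3] in STOPS or tl[j : j + 3] == "ATG":
            tl = tl[:j] + _sense_codon(probs, rng) + tl[j + 3 :]
        j += 3
    stop_end = _first_stop_from(tl + ds, i)
    if stop_end is None or stop_end < L:
        return tl, None
    call = UpstreamOrfCall(
        gene_id="",
        start=i - L,
        stop_third_base=_rel(stop_end, L),
        length_aa=(stop_end - 2 - i) // 3,
        frame_offset=d % 3,
        orf_class=OrfClass.OORF,
    )
    return tl, call


def _plant_uorf(tl, k, existing, probs, rng, gene_id):
    """Write a complete ORF (ATG + k sense codons incl. Met + stop) wholly
    within the leader, upstream of any already-planted architecture."""
    L = len(tl)
    span = 3 * (k + 1)
    limit = min((min(c.start for c in existing) + L) if existing else L, L)
    if limit - span < 0:
        return tl, None
    i = int(rng.integers(0, limit - span + 1))
    codons = ["ATG"] + [_sense_codon(probs, rng) for _ in range(k - 1)]
    codons.append(STOPS[rng.integers(len(STOPS))])
    tl = tl[:i] + "".join(codons) + tl[i + span :]
    call = UpstreamOrfCall(
        gene_id=gene_id,
        start=i - L,
        stop_third_base=i + span - 1 - L,
        length_aa=k,
        frame_offset=(L - i) % 3,
        orf_class=OrfClass.UORF,
    )
    return tl, call


# ---------------------------------------------------------------------------
# STN1-style fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stn1Fixture:
    """A deterministic STN1-like record with its expected calls.

    ``substitutions`` are the point edits that turn the corresponding
    wild-type fixture into this variant (empty for the wild types).
    """

    kind: str
    record: TranscriptLeaderRecord
    expected_calls: tuple[UpstreamOrfCall, ...]
    substitutions: tuple[Substitution, ...] = ()


def _yeast_wt_sequences() -> tuple[str, str]:
    # TL (90 nt): uORF at -78 (ATG + 15 sense codons + TAA, stop third base
    # -28) and a 6-sense-codon oORF at -17 whose stop TGA occupies +2..+4,
    # straddling into a CDS that begins ATGA.
    tl = "C" * 12 + "ATG" + "GCC" * 15 + "TAA" + "C" * 10 + "ATG" + "GCC" * 4 + "GC"
    # downstream (120 nt): CDS ATG A..., oORF-frame TGA ending at +82 (the
    # s111 extended stop), CDS-frame TAA at +85..+87.
    ds = "ATGA" + "C" * 75 + "TGA" + "CC" + "TAA" + "C" * 33
    assert len(tl) == 90 and len(ds) == 120
    return tl, ds


def _human_wt_sequences() -> tuple[str, str]:
    # TL (70 nt): overlapping oORFs of 19 and 15 sense codons in one frame,
    # sharing a stop codon TAA whose third base is the first CDS base (+1).
    tl = "C" * 11 + "ATG" + "GCC" * 3 + "ATG" + "GCC" * 14 + "TA"
    ds = "ATG" + "C" * 84 + "TAA" + "C" * 30
    assert len(tl) == 70 and len(ds) == 120
    return tl, ds


def stn1_fixture(kind: str) -> Stn1Fixture:
    """Deterministic fixtures: yeastWT / u1 / u2 / s111 / humanWT / human_no_oORF.

    u1 knocks out the oORF initiation codon, u2 the uORF initiation codon,
    s111 the oORF termination codon (extending the oORF from 6 to 32 sense
    codons); human_no_oORF knocks out both human oORF initiation codons.
    """
    ytl, yds = _yeast_wt_sequences()
    htl, hds = _human_wt_sequences()

    y_uorf = UpstreamOrfCall("STN1", -78, -28, 16, 0, OrfClass.UORF)
    y_oorf = UpstreamOrfCall("STN1", -17, +4, 6, 2, OrfClass.OORF)
    y_oorf_ext = UpstreamOrfCall("STN1", -17, +82, 32, 2, OrfClass.OORF)
    h_outer = UpstreamOrfCall("STN1", -59, +1, 19, 2, OrfClass.OORF)
    h_inner = UpstreamOrfCall("STN1", -47, +1, 15, 2, OrfClass.OORF)

    if kind == "yeastWT":
        return Stn1Fixture(kind, TranscriptLeaderRecord("STN1", ytl, yds, "yeast"),
                           (y_uorf, y_oorf))
    if kind == "u1":  # oORF start knockout
        sub = Substitution(-17, "A", "T")
        tl = ytl[:73] + "T" + ytl[74:]
        return Stn1Fixture(kind, TranscriptLeaderRecord("STN1", tl, yds, "yeast"),
                           (y_uorf,), (sub,))
    if kind == "u2":  # uORF start knockout
        sub = Substitution(-78, "A", "T")
        tl = ytl[:12] + "T" + ytl[13:]
        return Stn1Fixture(kind, TranscriptLeaderRecord("STN1", tl, yds, "yeast"),
                           (y_oorf,), (sub,))
    if kind == "s111":  # oORF stop knockout: TGA at +2..+4 -> TGC
        sub = Substitution(+4, "A", "C")
        ds = yds[:3] + "C" + yds[4:]
        return Stn1Fixture(kind, TranscriptLeaderRecord("STN1", ytl, ds, "yeast"),
                           (y_uorf, y_oorf_ext), (sub,))
    if kind == "humanWT":
        return Stn1Fixture(kind, TranscriptLeaderRecord("STN1", htl, hds, "human"),
                           (h_outer, h_inner))
    if kind == "human_no_oORF":
        subs = (Substitution(-59, "A", "C"), Substitution(-47, "A", "C"))
        tl = htl[:11] + "C" + htl[12:23] + "C" + htl[24:]
        return Stn1Fixture(kind, TranscriptLeaderRecord("STN1", tl, hds, "human"),
                           (), subs)
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# synthetic protein abundance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbundanceTruth:
    base_log10_mean: float
    sd: float
    delta_oORF: float
    seed: int | None
    group_by_gene: dict[str, str] = field(repr=False, default_factory=dict)


def generate_abundance(
    summaries: Sequence[GeneOrfSummary],
    base_log10_mean: float = 2.5,
    sd: float = 0.6,
    delta_oORF: float = 0.5,
    seed: int | None = None,
) -> tuple[dict[str, float], AbundanceTruth]:
    """Log-normal abundances with a planted decrement for oORF-only genes.

    Each gene's log10 abundance is N(base_log10_mean, sd); genes whose group
    is oORF_only have their mean shifted by -delta_oORF.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    groups: dict[str, str] = {}
    for s in summaries:
        mu = base_log10_mean - (delta_oORF if s.group == "oORF_only" else 0.0)
        out[s.gene_id] = float(10.0 ** rng.normal(mu, sd))
        groups[s.gene_id] = s.group
    truth = AbundanceTruth(base_log10_mean, sd, delta_oORF, seed, groups)
    return out, truth
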