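"""Cohort-level selection statistics for uORFs and oORFs.

Observed cohort fractions (share of genes carrying >= 1 uORF / oORF) are
compared with the per-TL-permutation expectation, overall and stratified by
transcript-leader length; observed/expected ratios below 1 indicate
depletion consistent with negative selection. Protein abundance is compared
between uORF-only and oORF-only genes with an unpaired t-test and Tukey
box statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .null_model import ExpectedFractions, NullConfig, expected_fractions
from .orf_scanner import GeneOrfSummary, scan_cohort
from .records import TranscriptLeaderRecord


@dataclass(frozen=True)
class CohortFractions:
    """Observed (and optionally shuffle-expected) cohort fractions."""

    n_genes: int
    frac_uORF_obs: float
    frac_oORF_obs: float
    expected: ExpectedFractions | None = None
    stratified: pd.DataFrame | None = None

    def __post_init__(self):
        for f in (self.frac_uORF_obs, self.frac_oORF_obs):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def observed_fractions(summaries: Sequence[GeneOrfSummary]) -> CohortFractions:
    """Fraction of genes with >= 1 uORF and >= 1 oORF (a gene with both counts in both)."""
    if not summaries:
        raise ValueError("empty cohort")
    n = len(summaries)
    return CohortFractions(
        n_genes=n,
        frac_uORF_obs=sum(s.has_uORF for s in summaries) / n,
        frac_oORF_obs=sum(s.has_oORF for s in summaries) / n,
    )


def cohort_fractions(
    records: list[TranscriptLeaderRecord], cfg: NullConfig
) -> CohortFractions:
    """Observed and shuffle-expected fractions for one cohort of records."""
    _, summaries = scan_cohort(records, window=cfg.window)
    obs = observed_fractions(summaries)
    exp = expected_fractions(records, cfg)
    return CohortFractions(
        n_genes=obs.n_genes,
        frac_uORF_obs=obs.frac_uORF_obs,
        frac_oORF_obs=obs.frac_oORF_obs,
        expected=exp,
    )


def length_stratified_fractions(
    obs: Sequence[GeneOrfSummary],
    exp_replicates: Sequence[Sequence[GeneOrfSummary]],
    bin_width: int = 25,
    min_bin_n: int = 20,
) -> pd.DataFrame:
    """Per-TL-length-bin observed and expected uORF/oORF fractions.

    Both arms must cover the same gene set; expected fractions are averaged
    over replicates. Bins with fewer than ``min_bin_n`` genes are flagged
    ``low_support``.
    """
    obs_ids = [s.gene_id for s in obs]
    for rep in exp_replicates:
        rep_ids = [s.gene_id for s in rep]
        if sorted(rep_ids) != sorted(obs_ids):
            diff = set(obs_ids) ^ set(rep_ids)
            raise ValueError(f"observed and expected gene sets differ: {sorted(diff)[:10]}")

    df = pd.DataFrame(
        {
            "gene_id": obs_ids,
            "tl_length": [s.tl_length for s in obs],
            "u_obs": [s.has_uORF for s in obs],
            "o_obs": [s.has_oORF for s in obs],
        }
    )
    exp_u = pd.DataFrame(0.0, index=obs_ids, columns=range(len(exp_replicates)))
    exp_o = exp_u.copy()
    for r, rep in enumerate(exp_replicates):
        for s in rep:
            exp_u.loc[s.gene_id, r] = float(s.has_uORF)
            exp_o.loc[s.gene_id, r] = float(s.has_oORF)
    df["u_exp"] = exp_u.mean(axis=1).to_numpy(dtype=float)
    df["o_exp"] = exp_o.mean(axis=1).to_numpy(dtype=float)

    df["bin_left"] = (df["tl_length"] // bin_width) * bin_width
    grouped = df.groupby("bin_left", sort=True)
    out = grouped.agg(
        n=("gene_id", "size"),
        frac_uORF_obs=("u_obs", "mean"),
        frac_oORF_obs=("o_obs", "mean"),
        frac_uORF_exp=("u_exp", "mean"),
        frac_oORF_exp=("o_exp", "mean"),
    ).reset_index()
    out["bin_right"] = out["bin_left"] + bin_width
    out["low_support"] = out["n"] < min_bin_n
    assert int(out["n"].sum()) == len(obs)
    return out


def oe_curve(
    stratified: pd.DataFrame, length_threshold: int = 50
) -> tuple[pd.DataFrame, bool]:
    """Observed/expected ratio per length bin for uORFs and oORFs.

    Ratios are NA where the expected fraction is 0. Returns the ratio table
    and a flag that is True when, in every supported bin wholly beyond
    ``length_threshold``, the oORF ratio lies below the uORF ratio — the
    qualitative signature of stronger selection against oORFs in longer
    leaders.
    """
    out = stratified.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        for which in ("uORF", "oORF"):
            o = out[f"frac_{which}_obs"].to_numpy(dtype=float)
            e = out[f"frac_{which}_exp"].to_numpy(dtype=float)
            out[f"oe_{which}"] = np.where(e > 0, o / np.where(e > 0, e, 1.0), np.nan)
    sel = out[(out["bin_left"] >= length_threshold) & ~out["low_support"]]
    sel = sel.dropna(subset=["oe_uORF", "oe_oORF"])
    oorf_more_depleted = bool(len(sel) > 0 and (sel["oe_oORF"] < sel["oe_uORF"]).all())
    return out, oorf_more_depleted


# ---------------------------------------------------------------------------
# protein-abundance comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxStats:
    """Tukey box statistics: quartiles, IQR and 1.5*IQR-fence whiskers."""

    n: int
    q1: float
    median: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float


def box_stats(values: Sequence[float]) -> BoxStats:
    """Quartiles by linear interpolation; whiskers at the most extreme data
    points within 1.5 x IQR of the nearer quartile (Tukey convention)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    hi_candidates = arr[arr <= q3 + 1.5 * iqr]
    lo_candidates = arr[arr >= q1 - 1.5 * iqr]
    return BoxStats(
        n=arr.size,
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(lo_candidates.min()),
        whisker_high=float(hi_candidates.max()),
    )


def compare_groups(
    a: Sequence[float], b: Sequence[float], test: str = "student"
) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; returns (t, df, p).

    ``student`` is the pooled-variance test, ``welch`` drops the
    equal-variance assumption.
    """
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                          equal_var=(test == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass(frozen=True)
class AbundanceComparison:
    """uORF-only vs oORF-only protein-abundance contrast."""

    box_uORF: BoxStats
    box_oORF: BoxStats
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    transform: str
    test: str
    n_missing_abundance: int

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def abundance_association(
    summaries: Sequence[GeneOrfSummary],
    abundance: Mapping[str, float],
    transform: str = "none",
    test: str = "student",
) -> AbundanceComparison:
    """Compare protein abundance between uORF-only and oORF-only genes.

    Genes in group "both" or "none" are excluded from the contrast; genes
    with no abundance measurement are dropped and counted.
    """
    if transform not in ("none", "log10"):
        raise ValueError(f"unknown transform {transform!r}")
    groups: dict[str, list[float]] = {"uORF_only": [], "oORF_only": []}
    missing = 0
    for s in summaries:
        if s.group not in groups:
            continue
        if s.gene_id not in abundance:
            missing += 1
            continue
        val = float(abundance[s.gene_id])
        if transform == "log10":
            val = float(np.log10(val))
        groups[s.group].append(val)
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name} has fewer than 2 genes with abundance")
    t, dof, p = compare_groups(groups["uORF_only"], groups["oORF_only"], test=test)
    return AbundanceComparison(
        box_uORF=box_stats(groups["uORF_only"]),
        box_oORF=box_stats(groups["oORF_only"]),
        t_statistic=t,
        degrees_of_freedom=dof,
        p_value=p,
        transform=transform,
        test=test,
        n_missing_abundance=missing,
    )
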