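"""Optional matplotlib views of the cohort statistics."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .selection_analysis import AbundanceComparison


def plot_stratified_fractions(stratified: pd.DataFrame, ax=None, which: str = "uORF"):
    """Observed vs expected fraction of genes with a uORF/oORF per TL-length bin."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = stratified["bin_left"] + (stratified["bin_right"] - stratified["bin_left"]) / 2
    ax.plot(x, stratified[f"frac_{which}_obs"], "o-", label=f"{which} observed")
    ax.plot(x, stratified[f"frac_{which}_exp"], "s--", label=f"{which} expected")
    ax.set_xlabel("TL length (nt)")
    ax.set_ylabel(f"fraction of genes with ≥ 1 {which}")
    ax.legend()
    return ax


def plot_abundance_boxes(cmp: AbundanceComparison, groups: dict[str, Sequence[float]], ax=None):
    """Tukey box plot of abundances for uORF-only vs oORF-only genes (outliers hidden)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.boxplot(
        [groups["uORF_only"], groups["oORF_only"]],
        tick_labels=[f"uORF only (n={cmp.box_uORF.n})", f"oORF only (n={cmp.box_oORF.n})"],
        whis=1.5,
        showfliers=False,
    )
    ax.set_ylabel("protein abundance" + (" (log10)" if cmp.transform == "log10" else ""))
    ax.set_title(f"t = {cmp.t_statistic:.2f}, p = {cmp.p_value:.2g}")
    return ax
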