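"""Cohort fractions, length stratification, O/E ratios and the abundance contrast."""

import numpy as np
import pandas as pd
import pytest

from leaderscan import (
    GeneOrfSummary,
    abundance_association,
    box_stats,
    compare_groups,
    generate_abundance,
    generate_cohort,
    length_stratified_fractions,
    observed_fractions,
    oe_curve,
    scan_cohort,
)


def _summary(gene_id, n_u=0, n_o=0, tl_length=50):
    return GeneOrfSummary(gene_id=gene_id, tl_length=tl_length, n_uORF=n_u, n_oORF=n_o)


class TestObservedFractions:
    def test_counting(self):
        summaries = [
            _summary("a", n_u=1),          # uORF_only
            _summary("b", n_o=1),          # oORF_only
            _summary("c", n_u=2, n_o=1),   # both: counts in both numerators
            _summary("d"),                 # none
        ]
        cf = observed_fractions(summaries)
        assert cf.n_genes == 4
        assert cf.frac_uORF_obs == 0.5
        assert cf.frac_oORF_obs == 0.5

    def test_all_none_and_empty(self):
        cf = observed_fractions([_summary("a"), _summary("b")])
        assert cf.frac_uORF_obs == 0.0 and cf.frac_oORF_obs == 0.0
        with pytest.raises(ValueError):
            observed_fractions([])

    def test_planted_prevalence_recovered_exactly(self):
        records, truth = generate_cohort(
            400, mode="planted", prevalence_uORF=0.3, prevalence_oORF=0.15, seed=7
        )
        _, summaries = scan_cohort(records)
        cf = observed_fractions(summaries)
        planted_u = sum(
            any(c.orf_class.value == "uORF" for c in g.planted_calls) for g in truth.genes
        )
        planted_o = sum(
            any(c.orf_class.value == "oORF" for c in g.planted_calls) for g in truth.genes
        )
        assert cf.frac_uORF_obs == planted_u / 400
        assert cf.frac_oORF_obs == planted_o / 400


class TestStratified:
    def test_single_bin_matches_unstratified(self):
        summaries = [_summary(f"g{i}", n_u=i % 2, tl_length=10 + i) for i in range(10)]
        strat = length_stratified_fractions(summaries, [summaries], bin_width=1000)
        assert len(strat) == 1
        cf = observed_fractions(summaries)
        assert strat.loc[0, "frac_uORF_obs"] == cf.frac_uORF_obs
        assert strat.loc[0, "frac_uORF_exp"] == cf.frac_uORF_obs  # same arm passed
        assert strat.loc[0, "n"] == 10

    def test_mismatched_gene_sets_rejected(self):
        obs = [_summary("a"), _summary("b")]
        exp = [[_summary("a"), _summary("zzz")]]
        with pytest.raises(ValueError, match="zzz"):
            length_stratified_fractions(obs, exp)

    def test_low_support_flag_and_bin_sums(self):
        summaries = [_summary(f"g{i}", tl_length=(i % 3) * 30) for i in range(30)]
        strat = length_stratified_fractions(summaries, [summaries], bin_width=25, min_bin_n=11)
        assert int(strat["n"].sum()) == 30
        assert strat["low_support"].tolist() == [True, True, True]


class TestOECurve:
    def test_ratio_one_when_obs_equals_exp(self):
        summaries = [_summary(f"g{i}", n_u=1, n_o=i % 2, tl_length=40 + i) for i in range(40)]
        strat = length_stratified_fractions(summaries, [summaries], bin_width=25, min_bin_n=1)
        curve, _ = oe_curve(strat)
        assert np.allclose(curve["oe_uORF"].dropna(), 1.0)
        assert np.allclose(curve["oe_oORF"].dropna(), 1.0)

    def test_zero_expected_gives_na(self):
        strat = pd.DataFrame(
            {
                "bin_left": [0], "bin_right": [25], "n": [30],
                "frac_uORF_obs": [0.1], "frac_oORF_obs": [0.0],
                "frac_uORF_exp": [0.2], "frac_oORF_exp": [0.0],
                "low_support": [False],
            }
        )
        curve, flag = oe_curve(strat)
        assert np.isnan(curve.loc[0, "oe_oORF"])
        assert curve.loc[0, "oe_uORF"] == pytest.approx(0.5)
        assert flag is False

    def test_depleted_cohort_flags_oorf_depletion(self):
        records, _ = generate_cohort(
            1200, length_model="human", mode="depleted", rejection_factor=0.85, seed=19
        )
        from leaderscan import NullConfig, randomized_summaries

        _, summaries = scan_cohort(records)
        reps = randomized_summaries(records, NullConfig(n_randomizations=3, seed=5))
        strat = length_stratified_fractions(summaries, reps, bin_width=50, min_bin_n=40)
        curve, oorf_more_depleted = oe_curve(strat, length_threshold=50)
        assert oorf_more_depleted


class TestBoxStats:
    def test_outlier_excluded_from_whisker(self):
        b = box_stats([1, 2, 3, 4, 100])
        assert (b.q1, b.median, b.q3, b.iqr) == (2, 3, 4, 2)
        assert b.whisker_high == 4  # 100 lies beyond Q3 + 1.5*IQR = 7
        assert b.whisker_low == 1

    def test_constant_sample(self):
        b = box_stats([5, 5, 5])
        assert (b.q1, b.median, b.q3, b.whisker_low, b.whisker_high) == (5, 5, 5, 5, 5)

    def test_whiskers_within_data_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=rng.integers(1, 50))
            b = box_stats(x)
            assert x.min() <= b.whisker_low <= b.q1 <= b.median <= b.q3 <= b.whisker_high <= x.max()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            box_stats([])


class TestTTest:
    def test_textbook_pooled_t(self):
        # pooled-variance oracle: mean diff -1, pooled var 1, se sqrt(2/3)
        t, df, p = compare_groups([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == 4
        assert p == pytest.approx(0.2878, abs=1e-3)

    def test_identical_groups(self):
        t, _, p = compare_groups([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_welch_differs_under_unequal_variance(self):
        a = [0.0, 0.1, -0.1, 0.05, -0.05]
        b = [1.0, 5.0, -3.0, 8.0, -6.0]
        _, df_s, _ = compare_groups(a, b, test="student")
        _, df_w, _ = compare_groups(a, b, test="welch")
        assert df_s == 8 and df_w < 8


@pytest.fixture(scope="module")
def planted_cohort():
    records, _ = generate_cohort(
        900, mode="planted", prevalence_uORF=0.5, prevalence_oORF=0.5, seed=23
    )
    _, summaries = scan_cohort(records)
    return summaries


class TestAbundanceAssociation:

    def test_planted_decrement_detected(self, planted_cohort):
        abundance, _ = generate_abundance(planted_cohort, delta_oORF=1.0, seed=3)
        cmp = abundance_association(planted_cohort, abundance, transform="log10")
        assert cmp.box_uORF.n >= 100 and cmp.box_oORF.n >= 100
        assert cmp.p_value < 1e-3
        assert cmp.box_oORF.median < cmp.box_uORF.median
        assert cmp.t_statistic > 0  # uORF group higher

    def test_missing_abundance_dropped_and_counted(self, planted_cohort):
        abundance, _ = generate_abundance(planted_cohort, delta_oORF=1.0, seed=3)
        some_gene = next(
            s.gene_id for s in planted_cohort if s.group == "uORF_only"
        )
        del abundance[some_gene]
        cmp = abundance_association(planted_cohort, abundance)
        assert cmp.n_missing_abundance == 1

    def test_small_group_rejected(self):
        summaries = [_summary("a", n_u=1), _summary("b", n_o=1), _summary("c", n_o=1)]
        abundance = {"a": 1.0, "b": 2.0, "c": 3.0}
        with pytest.raises(ValueError, match="uORF_only"):
            abundance_association(summaries, abundance)
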