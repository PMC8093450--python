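"""Statistical harness: accuracy scores, normality gate, rank tests, RM-ANOVA.

Every rank test is cross-checked against the scipy / pingouin reference
implementations on random tables (the dual-route oracle).
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from cogload.errors import DegenerateInputError
from cogload.stats import (
    ConfusionCounts,
    accuracy_arithmetic,
    accuracy_nback,
    anderson_darling_normal,
    friedman,
    rm_anova_oneway,
    spearman,
    wilcoxon_signed_rank,
)


class TestAccuracy:
    @pytest.mark.parametrize(
        "counts, expected",
        [((8, 1, 0, 1), 0.8), ((5, 0, 5, 0), 1.0), ((0, 3, 0, 2), 0.0)],
    )
    def test_nback(self, counts, expected):
        assert accuracy_nback(ConfusionCounts(*counts)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "correct, wrong, expected", [(3, 1, 0.75), (0, 4, 0.0), (7, 0, 1.0)]
    )
    def test_arithmetic(self, correct, wrong, expected):
        assert accuracy_arithmetic(ConfusionCounts(correct, wrong)) == pytest.approx(
            expected
        )

    def test_zero_denominators(self):
        with pytest.raises(DegenerateInputError):
            accuracy_nback(ConfusionCounts(0, 0, 0, 0))
        with pytest.raises(DegenerateInputError):
            accuracy_arithmetic(ConfusionCounts(0, 0, 5, 5))

    def test_negative_counts_rejected(self):
        with pytest.raises(DegenerateInputError):
            ConfusionCounts(-1, 0, 0, 0)


class TestAndersonDarling:
    def test_normal_sample_accepted(self):
        x = np.random.default_rng(11).normal(size=1000)
        assert anderson_darling_normal(x).p_value > 0.05

    def test_uniform_sample_rejected(self):
        x = np.random.default_rng(11).uniform(size=1000)
        assert anderson_darling_normal(x).p_value < 0.01

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            anderson_darling_normal(np.full(20, 1.0))

    def test_small_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            anderson_darling_normal(np.arange(5.0))

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.normal(2.0, 3.0, rng.integers(20, 200))
            mine = anderson_darling_normal(x).statistic
            ref = ss.anderson(x).statistic
            assert mine == pytest.approx(ref, abs=1e-10)


class TestFriedman:
    def test_perfect_concordance_closed_form(self):
        # 4 rows ranking 3 conditions identically: chi2(2) = 8.0 exactly
        rep = friedman(np.array([[1.0, 2.0, 3.0]] * 4))
        assert rep.statistic == pytest.approx(8.0)
        assert rep.df == 2

    def test_all_equal_cells_zero(self):
        rep = friedman(np.full((6, 3), 2.5))
        assert rep.statistic == 0.0
        assert rep.p_value == 1.0

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            tbl = rng.normal(size=(12, 3))
            mine = friedman(tbl)
            ref = ss.friedmanchisquare(*tbl.T)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_rows_with_missing_cells_dropped(self):
        tbl = np.array([[1.0, 2.0, 3.0], [np.nan, 1.0, 2.0]] + [[2.0, 1.0, 3.0]] * 3)
        assert friedman(tbl).n == 4

    def test_null_calibration(self):
        """Type-I error at alpha=0.05 stays within 5% +/- 2% under the null."""
        rng = np.random.default_rng(42)
        rej = sum(
            friedman(rng.normal(size=(12, 3))).p_value < 0.05 for _ in range(2000)
        )
        assert 0.03 <= rej / 2000 <= 0.07

    def test_monotone_transform_invariance(self):
        tbl = np.random.default_rng(1).normal(size=(10, 3))
        a = friedman(tbl).statistic
        b = friedman(np.exp(tbl)).statistic
        assert a == pytest.approx(b, abs=1e-12)


class TestWilcoxon:
    def test_six_positive_pairs_exact(self):
        # all 2^6 sign assignments: P(W <= 0) = 1/64 per tail
        rep = wilcoxon_signed_rank(np.array([1.0, 2, 3, 4, 5, 6]), np.zeros(6))
        assert rep.statistic == 0.0
        assert rep.p_value == pytest.approx(2 / 2**6)
        assert rep.extras["exact"]

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=12), rng.normal(size=12)
        assert wilcoxon_signed_rank(a, b).p_value == pytest.approx(
            wilcoxon_signed_rank(b, a).p_value
        )

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank(np.ones(6), np.ones(6))

    def test_oracle_equivalence_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = rng.normal(size=12), rng.normal(size=12)
            mine = wilcoxon_signed_rank(a, b)
            ref = ss.wilcoxon(a, b, mode="exact")
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.5, 1, 40)
        b = rng.normal(0.0, 1, 40)
        mine = wilcoxon_signed_rank(a, b)
        ref = ss.wilcoxon(a, b, mode="approx", correction=True)
        assert not mine.extras["exact"]
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        a, b = rng.uniform(1, 2, 10), rng.uniform(1, 2, 10)
        p1 = wilcoxon_signed_rank(a, b).p_value
        p2 = wilcoxon_signed_rank(np.log(a), np.log(b)).p_value
        # ranks of |d| change under nonlinear maps, but signs do not; use a
        # strictly increasing affine map for exact invariance
        p3 = wilcoxon_signed_rank(3 * a + 1, 3 * b + 1).p_value
        assert p1 == pytest.approx(p3, abs=1e-12)
        assert p2 > 0  # sanity: still a valid p-value


class TestSpearman:
    def test_reversed_ranks(self):
        assert spearman(np.array([1.0, 2, 3]), np.array([3.0, 2, 1])).statistic == -1.0

    def test_monotone_increasing(self):
        x = np.array([1.0, 4.0, 9.0, 16.0, 30.0])
        assert spearman(x, np.exp(x / 10)).statistic == 1.0

    def test_self_correlation(self):
        x = np.random.default_rng(0).normal(size=20)
        assert spearman(x, x).statistic == 1.0
        assert spearman(x, -x).statistic == -1.0

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman(np.ones(10), np.arange(10.0))

    def test_tied_data_matches_rank_pearson(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            x = rng.integers(0, 6, 25).astype(float)
            y = rng.integers(0, 6, 25).astype(float)
            if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
                continue
            mine = spearman(x, y).statistic
            ref = ss.spearmanr(x, y).statistic
            assert mine == pytest.approx(ref, abs=1e-12)


class TestRMAnova:
    def test_no_condition_effect(self):
        rng = np.random.default_rng(7)
        col = rng.normal(size=10)
        tbl = np.column_stack([col, col, col])  # identical across conditions
        rep = rm_anova_oneway(tbl)
        assert rep.statistic == 0.0
        assert rep.effect_size == 0.0

    def test_perfectly_additive_shift_degenerate(self):
        col = np.random.default_rng(8).normal(size=10)
        tbl = np.column_stack([col, col + 1.0, col + 2.0])
        rep = rm_anova_oneway(tbl)
        assert np.isinf(rep.statistic)
        assert rep.extras["degenerate"]

    def test_missing_cells_rejected(self):
        tbl = np.random.default_rng(9).normal(size=(6, 3))
        tbl[0, 0] = np.nan
        with pytest.raises(DegenerateInputError, match="missing"):
            rm_anova_oneway(tbl)

    def test_oracle_equivalence_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        for _ in range(20):
            tbl = rng.normal(size=(20, 3))
            mine = rm_anova_oneway(tbl)
            long = (
                pd.DataFrame(tbl)
                .reset_index()
                .melt(id_vars="index", var_name="cond", value_name="v")
            )
            ref = pg.rm_anova(
                data=long, dv="v", within="cond", subject="index", effsize="np2"
            )
            assert mine.statistic == pytest.approx(float(ref["F"][0]), abs=1e-9)
            assert mine.effect_size == pytest.approx(float(ref["np2"][0]), abs=1e-9)
            assert mine.p_value == pytest.approx(float(ref["p_unc"][0]), abs=1e-9)
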