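"""Statistical tests against independent oracles and their invariances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from calmito.stats import (
    bonferroni,
    chi2_2x2,
    paired_wilcoxon,
    shapiro_gate,
    spearman_corr,
)


def wilcoxon_enumeration_oracle(d):
    """Exact two-sided signed-rank p by explicit 2^n sign enumeration."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = [
        np.asarray(signs).dot(ranks)
        for signs in itertools.product([0, 1], repeat=n)
    ]
    w_all = np.asarray(w_all)
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestPairedWilcoxon:
    def test_all_positive_differences_n6(self):
        """d = [1..6]: only 1 of 64 sign assignments reaches W+ = 21, so
        the exact two-sided p is 2/64."""
        x = np.array([1.0, 2, 3, 4, 5, 6]) + 10.0
        y = np.full(6, 10.0)
        res = paired_wilcoxon(x, y)
        assert res.p_value == pytest.approx(2 / 64)
        assert res.statistic == 21.0

    def test_identical_samples_rejected(self):
        x = np.arange(6, dtype=float)
        with pytest.raises(ValueError, match="all differences zero"):
            paired_wilcoxon(x, x)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        x = rng.normal(0, 1, n)
        y = x + rng.normal(0.3, 1, n)
        # occasional exact ties in |d| via rounding
        y = np.round(y, 1)
        x = np.round(x, 1)
        if np.all(x == y):
            return
        res = paired_wilcoxon(x, y)
        assert res.p_value == pytest.approx(wilcoxon_enumeration_oracle(x - y), abs=1e-12)

    def test_zero_differences_dropped_from_n(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7])
        y = np.array([1.0, 2, 1, 2, 3, 4, 5])  # two zero differences
        res = paired_wilcoxon(x, y)
        assert res.n == 5

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0.5, 1, 30)
        res = paired_wilcoxon(x, y)
        ref = sps.wilcoxon(x - y, correction=False, method="approx")
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)


class TestChi2:
    def test_printed_gender_table(self):
        """The cohort's gender 2x2 table [[4,11],[11,4]]: chi2 = 6.533,
        p ~ 0.0106, printed as 0.01."""
        res = chi2_2x2([[4, 11], [11, 4]])
        assert res.statistic == pytest.approx(6.533, abs=1e-3)
        assert res.p_value == pytest.approx(0.0106, abs=5e-4)
        assert round(res.p_value, 2) == 0.01

    def test_no_association(self):
        res = chi2_2x2([[5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_expected_counts_formula(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 30, (2, 2)).astype(float)
        res = chi2_2x2(t)
        row, col, n = t.sum(1), t.sum(0), t.sum()
        expected = np.outer(row, col) / n
        oracle = ((t - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(oracle, rel=1e-12)

    def test_symmetries(self):
        t = np.array([[3.0, 9], [14, 2]])
        base = chi2_2x2(t).statistic
        for variant in (t[::-1], t[:, ::-1], t.T):
            assert chi2_2x2(variant).statistic == pytest.approx(base, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_2x2([[0, 0], [5, 5]])


class TestSpearman:
    def test_perfect_linear(self):
        x = np.arange(10, dtype=float)
        res = spearman_corr(x, 2 * x + 1)
        assert res.statistic == 1.0
        assert res.p_value == 0.0

    def test_perfect_decreasing_monotone(self):
        x = np.linspace(-2, 2, 12)
        res = spearman_corr(x, -(x**3))
        assert res.statistic == -1.0

    def test_matches_rank_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(8)
        x = np.round(rng.normal(0, 1, 20), 1)  # forces ties
        y = np.round(x + rng.normal(0, 1, 20), 1)
        res = spearman_corr(x, y)
        oracle_rho = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
        assert res.statistic == pytest.approx(oracle_rho, abs=1e-12)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(float(ref.statistic), abs=1e-12)
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-8)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 15)
        y = rng.normal(0, 1, 15)
        base = spearman_corr(x, y).statistic
        assert spearman_corr(np.exp(x), y).statistic == pytest.approx(base, abs=1e-12)
        assert spearman_corr(x, y**3).statistic == pytest.approx(base, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman_corr(np.ones(8), np.arange(8, dtype=float))


class TestShapiroGate:
    def test_identical_values_recommend_nonparametric(self):
        p, family = shapiro_gate(np.full(10, 3.0))
        assert family == "nonparametric"

    def test_type_I_rate_near_alpha(self):
        rng = np.random.default_rng(10)
        rejections = sum(
            shapiro_gate(rng.normal(0, 1, 30))[1] == "nonparametric"
            for _ in range(1000)
        )
        assert rejections / 1000 == pytest.approx(0.05, abs=0.02)

    def test_power_against_lognormal(self):
        rng = np.random.default_rng(11)
        rejections = sum(
            shapiro_gate(rng.lognormal(0, 1, 30))[1] == "nonparametric"
            for _ in range(200)
        )
        assert rejections / 200 > 0.5

    @pytest.mark.parametrize("n", [2, 51])
    def test_out_of_range_n_rejected(self, n):
        with pytest.raises(ValueError):
            shapiro_gate(np.arange(n, dtype=float))


class TestBonferroni:
    def test_simple_and_capped(self):
        assert bonferroni([0.01], m=4) == [0.04]
        assert bonferroni([0.5], m=4) == [1.0]

    @settings(deadline=None, max_examples=50)
    @given(
        ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10),
        extra=st.integers(0, 5),
    )
    def test_elementwise_oracle_and_monotonicity(self, ps, extra):
        m = len(ps) + extra
        out = bonferroni(ps, m)
        assert out == [min(1.0, m * p) for p in ps]
        assert all(o >= p for o, p in zip(out, ps))
        assert all(o <= 1.0 for o in out)

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError, match="family"):
            bonferroni([0.1, 0.2, 0.3], m=2)
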