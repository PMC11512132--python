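import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as hst

import searchtrend as st


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def rank_sum_p_oracle(a, b):
    """Exact two-sided permutation p for the midrank U via scipy's machinery.

    scipy.stats.permutation_test with infinite resamples enumerates every
    two-sample split of the pooled data, an independent route from the
    implementation's own enumeration.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    n_a, n_b = len(a), len(b)

    def deviation(x, y):
        ranks = scipy.stats.rankdata(np.concatenate([x, y]))
        u = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0
        return abs(u - n_a * n_b / 2.0)

    res = scipy.stats.permutation_test(
        (a, b),
        deviation,
        permutation_type="independent",
        n_resamples=np.inf,
        alternative="greater",
    )
    return float(res.pvalue)


def anova_interaction_oracle(y, g, t):
    """Direct sums-of-squares interaction F for a balanced two-way layout."""
    y, g, t = np.asarray(y, float), np.asarray(g), np.asarray(t)
    groups, times = np.unique(g), np.unique(t)
    grand = y.mean()
    ss_int = ss_err = 0.0
    for gi in groups:
        for ti in times:
            cell = y[(g == gi) & (t == ti)]
            expected = y[g == gi].mean() + y[t == ti].mean() - grand
            ss_int += cell.size * (cell.mean() - expected) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    df_int = (len(groups) - 1) * (len(times) - 1)
    df_err = y.size - len(groups) * len(times)
    return (ss_int / df_int) / (ss_err / df_err)


def welch_oracle(a, b):
    """Welch t and Satterthwaite df straight from the formulas."""
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_identical_multisets_give_p_one(self):
        res = st.wilcoxon_rank_sum([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.statistic == pytest.approx(8.0)  # null mean n_a*n_b/2
        assert res.p_raw == pytest.approx(1.0)

    def test_two_vs_two_enumeration(self):
        # all C(4,2)=6 assignments; only U=0 and U=4 are as extreme
        res = st.wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(2 / 6)

    def test_four_vs_four_enumeration(self):
        res = st.wilcoxon_rank_sum([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.p_raw == pytest.approx(2 / 70)

    @pytest.mark.parametrize("n_a,n_b", [(2, 3), (3, 3), (4, 5), (5, 5), (6, 6)])
    def test_exact_path_matches_brute_force(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(3):
            # integers induce ties, exercising the midrank permutation null
            a = rng.integers(0, 4, n_a).astype(float)
            b = rng.integers(0, 4, n_b).astype(float)
            res = st.wilcoxon_rank_sum(a, b)
            assert res.p_raw == pytest.approx(rank_sum_p_oracle(a, b))

    @pytest.mark.parametrize("n_a,n_b", [(3, 3), (4, 4), (6, 6)])
    def test_exact_path_matches_scipy_without_ties(self, n_a, n_b):
        rng = np.random.default_rng(n_a + 100 * n_b)
        a = rng.normal(size=n_a)
        b = rng.normal(size=n_b) + 0.5
        res = st.wilcoxon_rank_sum(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p_raw == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_exact_at_n12(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=6)
        b = rng.normal(size=6) + 1.0
        exact = st.wilcoxon_rank_sum(a, b).p_raw
        approx = scipy.stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert abs(exact - approx) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(st.StatsError):
            st.wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# two-way ANOVA interaction
# ---------------------------------------------------------------------------

class TestAnovaInteraction:
    @staticmethod
    def balanced_design(rng, n_groups=2, n_times=4, n_cell=5):
        y, g, t = [], [], []
        for gi in range(n_groups):
            for ti in range(n_times):
                y.extend(rng.normal(loc=gi + 0.5 * ti, size=n_cell))
                g.extend([f"g{gi}"] * n_cell)
                t.extend([f"t{ti}"] * n_cell)
        return np.array(y), g, t

    def test_additive_cell_means_give_zero_F(self):
        # zero within-cell noise, exactly additive row+column means
        y, g, t = [], [], []
        for gi, geff in enumerate([0.0, 1.0]):
            for ti, teff in enumerate([0.0, 0.3, 0.6]):
                y.extend([geff + teff] * 3)
                g.extend([f"g{gi}"] * 3)
                t.extend([f"t{ti}"] * 3)
        # perturb within cells symmetrically so SS_err > 0 but means unchanged
        y = np.array(y) + np.tile([-0.01, 0.0, 0.01], 6)
        res = st.two_way_anova_interaction(y, g, t)
        assert res.F == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sums_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y, g, t = self.balanced_design(rng)
        res = st.two_way_anova_interaction(y, g, t)
        f_oracle = anova_interaction_oracle(y, g, t)
        assert res.F == pytest.approx(f_oracle, rel=1e-9)
        assert res.df == (3, 32)
        assert res.p == pytest.approx(float(scipy.stats.f.sf(f_oracle, 3, 32)), rel=1e-9)

    def test_invariant_to_shuffling_within_cells_and_shift(self):
        rng = np.random.default_rng(9)
        y, g, t = self.balanced_design(rng)
        res = st.two_way_anova_interaction(y, g, t)
        order = np.arange(len(y))
        for gi in set(g):
            for ti in set(t):
                cell = np.where((np.array(g) == gi) & (np.array(t) == ti))[0]
                order[cell] = rng.permutation(cell)
        shuffled = st.two_way_anova_interaction(
            y[order] + 17.0, np.array(g)[order], np.array(t)[order]
        )
        assert shuffled.F == pytest.approx(res.F, rel=1e-9)

    def test_empty_or_singleton_cell_named(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        g = ["a", "a", "a", "a", "b", "b", "b"]
        t = ["x", "x", "y", "y", "x", "x", "y"]  # cell (b, y) singleton
        with pytest.raises(st.DesignError, match="b.*y"):
            st.two_way_anova_interaction(y, g, t)

    def test_too_few_levels_rejected(self):
        with pytest.raises(st.DesignError):
            st.two_way_anova_interaction([1, 2, 3, 4], ["a"] * 4, ["x", "x", "y", "y"])

    def test_cell_means_variant_reproduces_coarse_df(self):
        rng = np.random.default_rng(3)
        y, g, t = [], [], []
        for gi in range(2):
            for ti in range(12):
                y.extend(rng.normal(loc=gi, size=30))
                g.extend([f"g{gi}"] * 30)
                t.extend([f"t{ti:02d}"] * 30)
        res = st.two_way_anova_interaction(np.array(y), g, t, cell_means=True)
        assert res.df == (1, 22)


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------

class TestWelchT:
    def test_identical_samples(self):
        res = st.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(st.StatsError):
            st.welch_t([0.0, 0.0], [1.0, 1.0])

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.8, 2, 10)
        res = st.welch_t(a, b)
        t_ref, df_ref = welch_oracle(a, b)
        assert res.statistic == pytest.approx(t_ref, rel=1e-12)
        assert res.p_raw == pytest.approx(
            2 * float(scipy.stats.t.sf(abs(t_ref), df_ref)), rel=1e-12
        )


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------

class TestBonferroni:
    def test_basic_values(self):
        np.testing.assert_allclose(st.bonferroni([0.01], 36), [0.36])
        np.testing.assert_allclose(st.bonferroni([0.05], 1), [0.05])
        np.testing.assert_allclose(st.bonferroni([1.0], 99), [1.0])

    def test_family_smaller_than_count_rejected(self):
        with pytest.raises(st.StatsError):
            st.bonferroni([0.1, 0.2, 0.3], 2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        p=hst.floats(min_value=0.0, max_value=1.0),
        m1=hst.integers(min_value=1, max_value=100),
        m2=hst.integers(min_value=1, max_value=100),
    )
    def test_monotone_in_family_size(self, p, m1, m2):
        lo, hi = sorted((m1, m2))
        assert st.bonferroni([p], lo)[0] <= st.bonferroni([p], hi)[0]
        assert st.bonferroni([p], 1)[0] == pytest.approx(p)

    def test_with_correction_on_results(self):
        res = st.wilcoxon_rank_sum([1, 2], [3, 4]).with_correction(36)
        assert res.p_corrected == pytest.approx(min(1.0, 36 * res.p_raw))


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------

class TestTukeyHSD:
    def test_identical_levels_give_p_one(self):
        base = [1.0, 2.0, 3.0, 4.0]
        y = base * 3
        levels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        for res in st.tukey_hsd(y, levels):
            assert res.p_corrected == pytest.approx(1.0, abs=1e-9)

    def test_well_separated_levels(self):
        rng = np.random.default_rng(21)
        y = np.concatenate(
            [rng.normal(0, 0.1, 10), rng.normal(10, 0.1, 10), rng.normal(20, 0.1, 10)]
        )
        levels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        results = st.tukey_hsd(y, levels)
        assert len(results) == 3
        for res in results:
            assert res.p_corrected < 1e-6

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(22)
        y = np.concatenate([rng.normal(m, 1.0, 8) for m in (0.0, 0.4, 0.8, 1.2)])
        levels = sum([[l] * 8 for l in "abcd"], [])
        for res in st.tukey_hsd(y, levels):
            assert res.p_corrected >= res.p_raw - 1e-12

    def test_fewer_than_three_levels_rejected(self):
        with pytest.raises(st.DesignError):
            st.tukey_hsd([1, 2, 3, 4], ["a", "a", "b", "b"])
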