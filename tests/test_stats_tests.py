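from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from cctpipe.stats import (
    anova_two_way,
    correlation,
    ks_two_sample,
    mann_whitney_u,
    normality_omnibus,
    pooled_t_summary,
    power_two_sample_t,
    variance_homogeneity,
    welch_t_summary,
)


class TestWelchSummary:
    def test_published_summaries_reproduce_printed_interval(self):
        res = welch_t_summary(4.87, 1.27, 80, 2.78, 0.51, 44)
        assert res.estimate == pytest.approx(2.09, abs=1e-12)
        assert round(res.ci95[0], 2) == 1.77
        assert round(res.ci95[1], 2) == 2.41
        assert res.statistic == pytest.approx(12.88, rel=0.01)
        assert res.df == pytest.approx(115.22, rel=0.01)
        assert res.p_value < 0.001

    def test_identical_groups(self):
        res = welch_t_summary(3.0, 1.0, 30, 3.0, 1.0, 30)
        assert res.statistic == 0.0
        assert res.ci95[0] == pytest.approx(-res.ci95[1])

    def test_satterthwaite_collapses_for_equal_groups(self):
        # s1 = s2 and n1 = n2 makes the df formula algebraically n1 + n2 - 2
        res = welch_t_summary(1.0, 2.0, 25, 4.0, 2.0, 25)
        assert res.df == pytest.approx(48.0, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            welch_t_summary(1, 0.0, 10, 2, 1.0, 10)
        with pytest.raises(ValueError):
            welch_t_summary(1, 1.0, 1, 2, 1.0, 10)


class TestPooledSummary:
    def test_df_and_symmetry(self):
        res = pooled_t_summary(5.0, 1.0, 12, 5.0, 1.0, 8)
        assert res.df == 18.0
        assert res.statistic == 0.0

    def test_matches_scipy_on_raw_data(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 1, 25)
        res = pooled_t_summary(
            x.mean(), x.std(ddof=1), 20, y.mean(), y.std(ddof=1), 25
        )
        t, p = sps.ttest_ind(x, y)
        assert res.statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(p)


class TestNormalityOmnibus:
    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            normality_omnibus(rng.normal(size=10))

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_omnibus(np.full(50, 2.0))

    def test_power_against_exponential(self):
        rng = np.random.default_rng(7)
        pvals = [normality_omnibus(rng.exponential(size=500)).p_value for _ in range(20)]
        assert all(p < 0.01 for p in pvals)

    def test_df_is_two(self, rng):
        assert normality_omnibus(rng.normal(size=100)).df == 2.0


def bf_oracle(*groups):
    """Hand-rolled one-way ANOVA on |x - group median|."""
    devs = [np.abs(np.asarray(g, float) - np.median(g)) for g in groups]
    allv = np.concatenate(devs)
    grand = allv.mean()
    ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in devs)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in devs)
    k, n = len(devs), allv.size
    return (ss_between / (k - 1)) / (ss_within / (n - k))


class TestVarianceHomogeneity:
    def test_identical_groups_give_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        assert variance_homogeneity(g, g).statistic == 0.0

    def test_matches_definitional_oracle(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0, 3, 12)
        c = rng.normal(0, 2, 9)
        res = variance_homogeneity(a, b, c)
        assert res.statistic == pytest.approx(bf_oracle(a, b, c), rel=1e-10)

    def test_shift_invariance(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0, 2, 15)
        f0 = variance_homogeneity(a, b).statistic
        f1 = variance_homogeneity(a + 100.0, b).statistic
        assert f0 == pytest.approx(f1, rel=1e-10)


def anova_ss_oracle(y, a, b):
    """Balanced two-way SS decomposition by direct group means."""
    y = np.asarray(y, float)
    la, lb = np.unique(a), np.unique(b)
    grand = y.mean()
    r = y.size / (len(la) * len(lb))
    ss_a = sum(
        (y[a == i].size) * (y[a == i].mean() - grand) ** 2 for i in la
    )
    ss_b = sum(
        (y[b == j].size) * (y[b == j].mean() - grand) ** 2 for j in lb
    )
    ss_cells = sum(
        y[(a == i) & (b == j)].size
        * (y[(a == i) & (b == j)].mean() - grand) ** 2
        for i in la
        for j in lb
    )
    return ss_a, ss_b, ss_cells - ss_a - ss_b


class TestAnovaTwoWay:
    def test_balanced_matches_closed_form(self, rng):
        a = np.repeat(["x", "y"], 12)
        b = np.tile(np.repeat(["u", "v"], 6), 2)
        y = rng.normal(size=24) + (a == "y") * 1.5 + (b == "v") * 0.7
        res = anova_two_way(y, a, b)
        ss_a, ss_b, ss_ab = anova_ss_oracle(y, a, b)
        assert res["a"].notes["ss"] == pytest.approx(ss_a, rel=1e-10)
        assert res["b"].notes["ss"] == pytest.approx(ss_b, rel=1e-10)
        assert res["interaction"].notes["ss"] == pytest.approx(ss_ab, abs=1e-8)

    def test_only_factor_a_varies(self):
        a = np.repeat(["x", "y"], 8)
        b = np.tile(np.repeat(["u", "v"], 4), 2)
        y = np.where(a == "y", 2.0, 1.0) + 0.0
        res = anova_two_way(y, a, b)
        assert res["b"].notes["ss"] == pytest.approx(0.0, abs=1e-12)
        assert res["interaction"].notes["ss"] == pytest.approx(0.0, abs=1e-12)

    def test_single_level_factor_rejected(self, rng):
        with pytest.raises(ValueError):
            anova_two_way(rng.normal(size=8), ["x"] * 8, ["u", "v"] * 4)

    def test_unbalanced_uses_type_ii(self, rng):
        a = np.array(["x"] * 10 + ["y"] * 6)
        b = np.array(["u", "v"] * 5 + ["u", "v", "u", "u", "v", "v"])
        y = rng.normal(size=16) + (a == "y") * 1.0
        res = anova_two_way(y, a, b)
        assert res["a"].notes["type"] == "II"
        # Type-II oracle: SS(A | B) from residuals of nested least squares
        def design(cols):
            mats = {"1": np.ones_like(y)[:, None], "a": (a == "y").astype(float)[:, None],
                    "b": (b == "v").astype(float)[:, None]}
            return np.hstack([mats[c] for c in cols])

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return ((y - X @ beta) ** 2).sum()

        ss_a_given_b = rss(design(["1", "b"])) - rss(design(["1", "a", "b"]))
        assert res["a"].notes["ss"] == pytest.approx(ss_a_given_b, rel=1e-8)


def mw_oracle(x, y):
    """U and exact two-sided p by direct pair counting over all splits."""
    x, y = np.asarray(x, float), np.asarray(y, float)

    def u_of(xx, yy):
        u1 = sum((xi > yj) + 0.5 * (xi == yj) for xi in xx for yj in yy)
        return min(u1, len(xx) * len(yy) - u1)

    u_obs = u_of(x, y)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        if u_of(pooled[mask], pooled[~mask]) <= u_obs + 1e-9:
            hits += 1
        total += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0

    def test_identical_samples_give_half(self):
        x = [1.0, 2.0, 3.0]
        assert mann_whitney_u(x, x).statistic == pytest.approx(9 / 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=6).astype(float)  # ties likely
        y = rng.integers(0, 6, size=5).astype(float)
        res = mann_whitney_u(x, y)
        u, p = mw_oracle(x, y)
        assert res.statistic == pytest.approx(u)
        assert res.p_value == pytest.approx(p, abs=1e-12)
        assert res.notes["method"] == "exact_enumeration"

    def test_large_sample_uses_normal_approximation(self, rng):
        res = mann_whitney_u(rng.normal(size=45), rng.normal(size=35))
        assert res.notes["method"] == "normal_tie_corrected"
        assert 0.0 <= res.p_value <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKsTwoSample:
    def test_identical_samples(self):
        x = np.arange(30.0)
        res = ks_two_sample(x, x)
        assert res.statistic == 0.0

    def test_disjoint_supports(self):
        res = ks_two_sample(np.arange(10.0), np.arange(100.0, 110.0))
        assert res.statistic == 1.0

    def test_matches_ecdf_scan_oracle(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(0.8, 1.2, size=9)
        grid = np.sort(np.concatenate([x, y]))
        d = max(
            abs((x <= v).mean() - (y <= v).mean()) for v in grid
        )
        assert ks_two_sample(x, y).statistic == pytest.approx(d)


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert correlation(x, 2 * x + 1).statistic == pytest.approx(1.0)

    def test_monotone_map_spearman_one(self):
        x = np.array([-3.0, -1.0, 0.5, 1.0, 2.0, 4.0])
        y = x**3
        assert correlation(x, y, "spearman").statistic == pytest.approx(1.0)
        assert correlation(x, y, "pearson").statistic < 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation(np.ones(5), np.arange(5.0))

    def test_p_close_to_permutation_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        res = correlation(x, y)
        r_obs = abs(res.statistic)
        perms = np.array(
            [abs(np.corrcoef(x, rng.permutation(y))[0, 1]) for _ in range(100_000)]
        )
        p_perm = (perms >= r_obs - 1e-12).mean()
        assert res.p_value == pytest.approx(p_perm, abs=0.02)


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert power_two_sample_t(30, 30, 0.0, alpha=0.05) == pytest.approx(0.05)

    def test_huge_samples_saturate(self):
        assert power_two_sample_t(10_000, 10_000, 0.5) > 0.999

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(23)
        n1, n2, d = 80, 44, 0.5
        reps = 100_000
        x = rng.standard_normal((reps, n1)) + d
        y = rng.standard_normal((reps, n2))
        v1 = x.var(axis=1, ddof=1)
        v2 = y.var(axis=1, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        crit = sps.t.ppf(0.975, n1 + n2 - 2)
        mc = (np.abs(t) > crit).mean()
        assert power_two_sample_t(n1, n2, d) == pytest.approx(mc, abs=0.01)

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            power_two_sample_t(10, 10, -0.2)
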