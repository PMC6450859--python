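import itertools

import numpy as np
import pytest
from scipy import stats as sps

from clamptrace.stats import (
    Route,
    adjusted_group_effect,
    compare_variable,
    geometric_ratio_ci,
    interaction_test,
    mann_whitney,
    mean_difference_ci,
    mean_difference_from_summary,
    pearson_r,
    route_variable,
)


class TestRouting:
    def test_normal_samples_routed_normal(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(500):
            a, b = rng.normal(10, 2, 18), rng.normal(10, 2, 15)
            if route_variable(a, b)[0] is Route.NORMAL:
                hits += 1
        assert hits / 500 >= 0.90  # ~0.95^2 expected under exact normality

    def test_lognormal_samples_routed_lognormal(self):
        rng = np.random.default_rng(11)
        counts = {r: 0 for r in Route}
        for _ in range(500):
            a = np.exp(rng.normal(0, 1.2, 18))
            b = np.exp(rng.normal(0, 1.2, 15))
            counts[route_variable(a, b)[0]] += 1
        assert counts[Route.LOGNORMAL] > 250

    def test_zero_value_skips_lognormal(self):
        rng = np.random.default_rng(12)
        a = np.concatenate([np.exp(rng.normal(0, 2, 17)), [0.0]])
        b = np.exp(rng.normal(0, 2, 15))
        # force non-normal raw scale: huge skew; zero forbids the log route
        route, _ = route_variable(a ** 3, b ** 3)
        assert route is Route.NONPARAMETRIC

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            route_variable([1.0, 2.0], [1.0, 2.0, 3.0])


class TestMeanDifference:
    def test_identical_groups(self):
        d, ci, p = mean_difference_ci([1, 2, 3, 4], [1, 2, 3, 4])
        assert d == 0.0
        assert p == pytest.approx(1.0)
        assert ci[0] < 0 < ci[1]

    def test_summary_reconstruction_matches_raw(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(4.5, 2, 18), rng.normal(4.0, 1.7, 15)
        d1, ci1, p1 = mean_difference_ci(a, b)
        d2, ci2, p2 = mean_difference_from_summary(
            18, a.mean(), a.std(ddof=1), 15, b.mean(), b.std(ddof=1)
        )
        assert d1 == pytest.approx(d2)
        assert ci1[0] == pytest.approx(ci2[0]) and ci1[1] == pytest.approx(ci2[1])
        assert p1 == pytest.approx(p2)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 1, 12)
        d0, ci0, _ = mean_difference_ci(a, b)
        d1, ci1, _ = mean_difference_ci(a + 5.0, b)
        assert d1 == pytest.approx(d0 + 5.0)
        assert ci1[0] == pytest.approx(ci0[0] + 5.0)
        assert ci1[1] == pytest.approx(ci0[1] + 5.0)


class TestGeometricRatio:
    def test_identical_groups_ratio_one(self):
        x = [1.0, 2.0, 4.0, 8.0]
        r, ci, p = geometric_ratio_ci(x, x)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        a = np.exp(rng.normal(0.3, 0.4, 15))
        b = np.exp(rng.normal(0.5, 0.4, 12))
        r0, ci0, p0 = geometric_ratio_ci(a, b)
        r1, ci1, p1 = geometric_ratio_ci(3.7 * a, 3.7 * b)
        assert r1 == pytest.approx(r0)
        assert ci1[0] == pytest.approx(ci0[0]) and p1 == pytest.approx(p0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            geometric_ratio_ci([1.0, -1.0, 2.0], [1.0, 2.0, 3.0])


class TestMannWhitney:
    def test_extreme_separation_exact_p(self):
        """Independent enumeration oracle: with n=m=3 and complete
        separation, U = 0 and the two-sided exact p is 2 * 2/20 = 0.1."""
        a, b = [1, 2, 3], [4, 5, 6]
        # enumerate all C(6,3)=20 label assignments of the pooled ranks
        pooled = a + b
        u_obs = sum(1 for x in a for y in b if x > y)
        us = []
        for combo in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(6) if i not in combo]
            us.append(sum(1 for x in ga for y in gb if x > y))
        # two-sided: as or more extreme in either tail
        n1n2 = len(a) * len(b)
        p_enum = sum(1 for u in us if min(u, n1n2 - u) <= min(u_obs, n1n2 - u_obs)) / len(us)
        assert p_enum == pytest.approx(0.1)
        assert mann_whitney(a, b) == pytest.approx(p_enum, abs=1e-12)

    def test_identical_samples(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 9), rng.normal(0.5, 1, 11)
        assert mann_whitney(a, b) == pytest.approx(mann_whitney(b, a))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, p = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_recovers_population_correlation(self):
        rng = np.random.default_rng(6)
        rho = 0.78
        rs = []
        for _ in range(1000):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=12)
            rs.append(pearson_r(z[:, 0], z[:, 1])[0])
        assert np.mean(rs) == pytest.approx(rho, abs=0.05)


class TestAdjustedEffect:
    def test_outcome_equal_covariate_gives_zero_group_effect(self):
        rng = np.random.default_rng(7)
        g = np.repeat([0.0, 1.0], 10)
        cov = rng.normal(0, 1, 20)
        eff, ci, p = adjusted_group_effect(cov, g, cov)
        assert eff == pytest.approx(0.0, abs=1e-10)

    def test_uncorrelated_covariate_keeps_difference(self):
        rng = np.random.default_rng(8)
        n = 4000
        g = np.repeat([1.0, 0.0], n // 2)
        y = 2.0 * g + rng.normal(0, 1, n)
        cov = rng.normal(0, 1, n)  # independent of both
        eff, ci, p = adjusted_group_effect(y, g, cov)
        raw = y[g == 1].mean() - y[g == 0].mean()
        assert eff == pytest.approx(raw, abs=0.05)

    def test_duplicated_covariate_rank_error(self):
        rng = np.random.default_rng(9)
        g = np.repeat([0.0, 1.0], 10)
        cov = rng.normal(0, 1, 20)
        with pytest.raises(ValueError, match="collinear"):
            adjusted_group_effect(rng.normal(0, 1, 20), g, np.column_stack([cov, cov]))


class TestInteraction:
    def test_null_p_uniform(self):
        """Equal slopes in both groups: interaction p should be U(0,1)."""
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(500):
            x = rng.normal(0, 1, 33)
            g = np.concatenate([np.zeros(18), np.ones(15)])
            y = 1.0 + 0.5 * x + 0.3 * g + rng.normal(0, 1, 33)
            ps.append(interaction_test(y, x, g))
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_strong_interaction(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, 200)
        g = (np.arange(200) % 2).astype(float)
        y = x * (1.0 + 3.0 * g) + rng.normal(0, 0.5, 200)
        assert interaction_test(y, x, g) < 1e-6

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            interaction_test([1.0, 2.0], [0.1, 0.2], [1.0, 1.0])

    def test_power_at_study_scale_is_low(self):
        """Slopes like the reported within-group correlations (0.78 vs 0.25)
        at n = 15/12 rarely yield a significant interaction -- consistent
        with the study's null interaction finding."""
        rng = np.random.default_rng(15)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            x1, x2 = rng.normal(0, 1, 15), rng.normal(0, 1, 12)
            y1 = 0.25 * x1 + rng.normal(0, np.sqrt(1 - 0.25 ** 2), 15)
            y2 = 0.78 * x2 + rng.normal(0, np.sqrt(1 - 0.78 ** 2), 12)
            y = np.concatenate([y1, y2])
            x = np.concatenate([x1, x2])
            g = np.concatenate([np.zeros(15), np.ones(12)])
            hits += interaction_test(y, x, g) < 0.05
        assert hits / n_rep < 0.8  # power well below certainty


class TestCompareVariable:
    def test_routes_and_reports_normal(self):
        rng = np.random.default_rng(16)
        c = compare_variable("m_value", rng.normal(4.5, 2, 18), rng.normal(4.0, 1.7, 15))
        assert c.route is Route.NORMAL
        assert c.test.startswith("Student t")
        assert c.ci95[0] < c.contrast < c.ci95[1]

    def test_contrast_order_is_first_minus_second(self):
        rng = np.random.default_rng(17)
        a = rng.normal(10, 1, 15)
        b = rng.normal(5, 1, 15)
        c = compare_variable("x", a, b)
        assert c.contrast > 0
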