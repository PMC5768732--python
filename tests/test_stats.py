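"""Between-site statistics: oracles computed by hand or brute force, plus
invariance properties."""

import numpy as np
import pytest
from scipy import stats as sps

from acoustica import (
    ComparisonPlan,
    dunn_posthoc,
    kruskal_wallis,
    pearson_ols,
    percent_difference,
    route_and_compare,
    transform_guard,
    tukey_hsd,
    two_sample,
    welch_anova,
)


class TestTransformGuard:
    def test_log10(self):
        np.testing.assert_allclose(transform_guard([1, 10, 100], "log10"), [0, 1, 2])

    def test_nonpositive_under_log10_raises_with_indices(self):
        with pytest.raises(ValueError, match=r"\[0\]"):
            transform_guard([0.0, 1.0], "log10")

    def test_identity(self):
        v = np.array([3.0, -2.0])
        np.testing.assert_array_equal(transform_guard(v, "none"), v)


class TestWelchAnova:
    def test_hand_computed_fixture(self):
        # groups {1,2,3},{2,3,4},{10,11,12}: all s²=1, n=3 → weights 3 each,
        # weighted grand mean 16/3, numerator 73.0, denominator 7/6 → F 62.571,
        # df2 = 8/(3·(3·(2/3)²/2)) = 4
        f, df1, df2, p = welch_anova([[1, 2, 3], [2, 3, 4], [10, 11, 12]])
        assert f == pytest.approx(62.5714, rel=1e-4)
        assert df1 == 2
        assert df2 == pytest.approx(4.0, rel=1e-9)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(0)
        groups = [rng.normal(i, 1 + i, 12) for i in range(3)]
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [len(g) for g in groups]),
            }
        )
        ref = pg.welch_anova(data=df, dv="y", between="g").iloc[0]
        f, df1, df2, p = welch_anova(groups)
        assert f == pytest.approx(ref["F"], rel=1e-9)
        assert df2 == pytest.approx(ref["ddof2"], rel=1e-9)
        assert p == pytest.approx(ref["p_unc"], rel=1e-9)

    def test_identical_groups_give_zero_f(self):
        f, _, _, p = welch_anova([[1, 1, 1], [1, 1, 1]])
        assert f == 0.0 and p == 1.0

    def test_two_groups_reduce_to_welch_t_squared(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 3, 15)
        f, _, df2, _ = welch_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=False)
        assert f == pytest.approx(t.statistic**2, rel=1e-9)
        assert df2 == pytest.approx(t.df, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([[1.0], [2.0, 3.0]])


class TestTukey:
    def test_identical_groups_all_p_near_one(self):
        pairs = tukey_hsd([[1, 2, 3]] * 3)
        assert all(p["p"] > 0.99 for p in pairs)

    def test_permutation_invariance(self, rng):
        g = [rng.normal(i, 1, 8) for i in range(3)]
        t1 = {frozenset((p["a"], p["b"])): p["p"] for p in tukey_hsd(g, "ABC")}
        t2 = {
            frozenset((p["a"], p["b"])): p["p"]
            for p in tukey_hsd([g[2], g[0], g[1]], "CAB")
        }
        for k in t1:
            assert t1[k] == pytest.approx(t2[k], rel=1e-9)

    def test_separated_pair_has_smallest_p(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 10)
        c = rng.normal(10, 1, 10)
        pairs = {(p["a"], p["b"]): p["p"] for p in tukey_hsd([a, b, c], "abc")}
        assert pairs[("a", "c")] < pairs[("a", "b")]


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857, abs=0.001)
        assert df == 1

    def test_identical_groups(self):
        h, _, p = kruskal_wallis([[2, 2, 2], [2, 2, 2]])
        assert h == 0.0 and p == 1.0

    def test_shift_invariance(self, rng):
        g = [rng.normal(i, 1, 9) for i in range(3)]
        h1, _, _ = kruskal_wallis(g)
        h2, _, _ = kruskal_wallis([x + 100.0 for x in g])
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        g = [rng.lognormal(i * 0.2, 0.5, 11) for i in range(3)]
        h1, _, _ = kruskal_wallis(g)
        h2, _, _ = kruskal_wallis([np.log(x) for x in g])
        assert h1 == pytest.approx(h2, rel=1e-12)


class TestDunn:
    def test_brute_force_rank_oracle(self):
        # {1..3},{4..6},{7..9}: mean ranks 2, 5, 8; pooled var N(N+1)/12 = 7.5,
        # SE = sqrt(7.5·(2/3)) = sqrt(5) → Z = −1.3416, −2.6833, −1.3416
        pairs = dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]], "abc")
        zs = {(p["a"], p["b"]): p["z"] for p in pairs}
        assert zs[("a", "b")] == pytest.approx(-3 / np.sqrt(5), rel=1e-9)
        assert zs[("a", "c")] == pytest.approx(-6 / np.sqrt(5), rel=1e-9)
        assert zs[("b", "c")] == pytest.approx(-3 / np.sqrt(5), rel=1e-9)

    def test_identical_groups_zero_z(self):
        pairs = dunn_posthoc([[1, 2, 3]] * 3)
        assert all(p["z"] == pytest.approx(0.0, abs=1e-12) for p in pairs)

    def test_antisymmetry_under_pair_swap(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        z_ab = dunn_posthoc([a, b])[0]["z"]
        z_ba = dunn_posthoc([b, a])[0]["z"]
        assert z_ab == pytest.approx(-z_ba, rel=1e-12)

    def test_bonferroni_scales_p(self, rng):
        g = [rng.normal(i, 1, 8) for i in range(3)]
        raw = dunn_posthoc(g)
        adj = dunn_posthoc(g, adjust="bonferroni")
        for r, a in zip(raw, adj):
            assert a["p"] == pytest.approx(min(1.0, 3 * r["p"]), rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        g = [rng.lognormal(i * 0.3, 0.4, 10) for i in range(3)]
        z1 = [p["z"] for p in dunn_posthoc(g)]
        z2 = [p["z"] for p in dunn_posthoc([np.sqrt(x) for x in g])]
        np.testing.assert_allclose(z1, z2)


class TestTwoSample:
    def test_ks_examples(self):
        d, _ = two_sample([1, 2, 3], [1, 2, 3], "ks")
        assert d == 0.0
        d, _ = two_sample([1, 2, 3], [10, 11, 12], "ks")
        assert d == 1.0

    def test_mann_whitney_complete_separation(self):
        u, _ = two_sample([1, 2], [3, 4], "mann_whitney")
        assert u == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            two_sample([], [1.0], "t")


class TestPearsonOls:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = pearson_ols(x, 2 * x + 1)
        assert fit["r"] == pytest.approx(1.0)
        assert fit["slope"] == pytest.approx(2.0)
        assert fit["intercept"] == pytest.approx(1.0)

    def test_r_squared_is_r_times_r(self):
        assert 0.936**2 == pytest.approx(0.876, abs=5e-4)
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        fit = pearson_ols(x, x + rng.normal(size=30))
        assert fit["r_squared"] == pytest.approx(fit["r"] ** 2, rel=1e-12)

    def test_sign_flip(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        y = x + rng.normal(scale=0.3, size=20)
        f1, f2 = pearson_ols(x, y), pearson_ols(-x, y)
        assert f2["r"] == pytest.approx(-f1["r"], rel=1e-12)
        assert f2["r_squared"] == pytest.approx(f1["r_squared"], rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_ols([1, 1, 1], [1, 2, 3])


class TestPercentDifference:
    @pytest.mark.parametrize("a,b,expected", [(4, 1, 300.0), (1, 1, 0.0), (2, 1, 100.0)])
    def test_examples(self, a, b, expected):
        assert percent_difference(a, b) == expected

    def test_nonpositive_outside_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)


class TestRouting:
    def test_normal_data_routes_to_welch_tukey(self, rng):
        g = [rng.normal(i, 1, 20) for i in range(3)]
        rep = route_and_compare(g, "abc", ComparisonPlan(metric="density"))
        assert rep["route"] == "anova_tukey"
        assert "F" in rep["omnibus"]

    def test_heavy_tailed_data_falls_back_to_kw(self, rng):
        g = [rng.standard_cauchy(40) ** 2 for _ in range(3)]
        rep = route_and_compare(g, "abc", ComparisonPlan(metric="density"))
        assert rep["route"] == "kw_dunn"
        assert rep["gates"]  # gate results recorded

    def test_explicit_path_bypasses_gates(self, rng):
        g = [rng.normal(0, 1, 10), rng.normal(1, 1, 10)]
        rep = route_and_compare(
            g, "ab", ComparisonPlan(metric="density", test_path="mann_whitney")
        )
        assert rep["omnibus"]["test"] == "mann_whitney"

    def test_all_p_values_in_unit_interval(self, rng):
        g = [rng.normal(i * 0.2, 1, 12) for i in range(4)]
        rep = route_and_compare(g, "abcd", ComparisonPlan(metric="density"))
        assert 0.0 <= rep["omnibus"]["p"] <= 1.0
        for pair in rep["posthoc"]["pairs"]:
            assert 0.0 <= pair["p"] <= 1.0
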