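import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from histoquant.loadstats import (
    StatsConfig,
    age_effect_by_region,
    age_effect_test,
    bh_fdr,
    classify_gene,
    classify_genes,
    corr_age_adjusted,
    corr_unadjusted,
    correlate_expression_with_load,
    filter_genes,
    method_difference_by_region,
    method_difference_test,
)


def brute_force_bh(pvalues):
    """Independent step-up oracle straight from the definition."""
    p = list(pvalues)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [None] * n
    running_min = float("inf")
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        val = p[i] * n / (rank_idx + 1)
        running_min = min(running_min, val)
        q[i] = min(running_min, 1.0)
    return q


class TestFilterGenes:
    def frame(self, rows):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])

    def test_exactly_ten_everywhere_removed(self):
        counts = self.frame([[10] * 6])
        assert len(filter_genes(counts)) == 0

    def test_eleven_in_exactly_half_removed(self):
        counts = self.frame([[11, 11, 11, 0, 0, 0]])
        assert len(filter_genes(counts)) == 0

    def test_eleven_everywhere_kept(self):
        counts = self.frame([[11] * 6])
        assert len(filter_genes(counts)) == 1

    def test_eleven_in_majority_kept(self):
        counts = self.frame([[11, 11, 11, 11, 0, 0]])
        assert len(filter_genes(counts)) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            filter_genes(pd.DataFrame())


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.4]), [0.4])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    def test_monotone_in_rank_and_capped(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q <= 1.0)

    def test_matches_brute_force_on_grids(self):
        rng = np.random.default_rng(2)
        grid = np.arange(0, 101) / 100.0
        for length in range(1, 9):
            for _ in range(100):
                p = rng.choice(grid, size=length)
                np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.random(200)
        np.testing.assert_allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1])


class TestCorrUnadjusted:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = corr_unadjusted(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = corr_unadjusted(x, -x + 7)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        # oracle: explicit sum formulas + t transform at n = 30
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, p = corr_unadjusted(x, y)
        n = 30
        sx, sy = x - x.mean(), y - y.mean()
        r_ref = np.sum(sx * sy) / np.sqrt(np.sum(sx**2) * np.sum(sy**2))
        t_ref = r_ref * np.sqrt((n - 2) / (1 - r_ref**2))
        p_ref = 2 * sps.t.sf(abs(t_ref), n - 2)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=25), rng.normal(size=25)
        r, p = corr_unadjusted(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_flagged_nan(self):
        r, p = corr_unadjusted(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            corr_unadjusted([1.0, 2.0], [3.0, 4.0])


class TestCorrAgeAdjusted:
    def test_group_offsets_removed(self):
        # expr = load + group-specific constants: adjusted r = 1, pooled r < 1
        rng = np.random.default_rng(6)
        load = rng.normal(5, 1, 20)
        group = np.array(["a"] * 10 + ["b"] * 10)
        expr = load + np.where(group == "a", 0.0, -8.0)
        r_pooled, _ = corr_unadjusted(expr, load)
        r_adj, p_adj = corr_age_adjusted(expr, load, group)
        assert r_adj == pytest.approx(1.0)
        assert abs(r_pooled) < 1.0
        assert p_adj == pytest.approx(0.0, abs=1e-9)

    def test_single_group_reduces_to_unadjusted_r(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=15), rng.normal(size=15)
        r_adj, _ = corr_age_adjusted(x, y, np.array(["a"] * 15))
        r_un, _ = corr_unadjusted(x - x.mean(), y - y.mean())
        assert r_adj == pytest.approx(r_un, abs=1e-12)

    def test_small_group_dropped_with_warning(self):
        x = np.arange(7.0)
        y = 2 * x
        g = np.array(["a"] * 6 + ["b"])
        with pytest.warns(UserWarning):
            r, _ = corr_age_adjusted(x, y, g)
        assert r == pytest.approx(1.0)

    def test_df_is_n_minus_groups_minus_one(self):
        rng = np.random.default_rng(8)
        n = 24
        x, y = rng.normal(size=n), rng.normal(size=n)
        g = np.array(["a", "b"]).repeat(n // 2)
        r, p = corr_age_adjusted(x, y, g)
        df = n - 2 - 1
        t = r * np.sqrt(df / (1 - r**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), df), abs=1e-12)


class TestClassify:
    @pytest.mark.parametrize(
        "p_un,p_adj,expected",
        [
            (0.01, 0.20, "age_dependent"),
            (0.20, 0.01, "age_independent"),
            (0.01, 0.01, "both"),
            (0.20, 0.20, "ns"),
            (0.05, 0.05, "ns"),  # threshold itself is not significant
        ],
    )
    def test_rule(self, p_un, p_adj, expected):
        assert classify_gene(p_un, p_adj, alpha=0.05) == expected

    def test_vectorized(self):
        res = pd.DataFrame(
            {"p_unadjusted": [0.01, 0.2], "p_adjusted": [0.2, 0.01]}, index=["g1", "g2"]
        )
        cats = classify_genes(res)
        assert list(cats) == ["age_dependent", "age_independent"]


class TestAgeEffect:
    def test_identical_means_f_near_zero(self):
        df = pd.DataFrame(
            {
                "load": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0] * 2,
                "age_group": ["6m"] * 6 + ["14m"] * 6,
                "strain": ["a", "a", "b", "b", "c", "c"] * 2,
            }
        )
        f, p = age_effect_test(df)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_one_factor_f_equals_squared_t(self):
        # algebraic identity: two-group one-way ANOVA F = t² (equal-variance t)
        rng = np.random.default_rng(9)
        load = np.concatenate([rng.normal(0, 1, 12), rng.normal(1, 1, 12)])
        df = pd.DataFrame(
            {"load": load, "age_group": ["6m"] * 12 + ["14m"] * 12, "strain": ["s"] * 24}
        )
        f, p = age_effect_test(df)
        t = sps.ttest_ind(load[:12], load[12:], equal_var=True)
        assert f == pytest.approx(t.statistic**2, rel=1e-9)
        assert p == pytest.approx(t.pvalue, rel=1e-9)

    def test_confounded_design_flagged(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "load": rng.normal(size=8),
                "age_group": ["6m"] * 4 + ["14m"] * 4,
                "strain": ["a"] * 4 + ["b"] * 4,
            }
        )
        with pytest.raises(ValueError):
            age_effect_test(df)

    def test_single_age_group_rejected(self):
        df = pd.DataFrame(
            {"load": [1.0, 2.0], "age_group": ["6m", "6m"], "strain": ["a", "b"]}
        )
        with pytest.raises(ValueError):
            age_effect_test(df)

    def test_power_at_large_shift(self):
        # Δ = 3·SD at n = 17/20 detects the age effect in ≥95% of replicates
        rng = np.random.default_rng(11)
        strains = [f"s{i}" for i in range(8)]
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            n6, n14 = 17, 20
            df = pd.DataFrame(
                {
                    "load": np.concatenate(
                        [rng.normal(0, 1, n6), rng.normal(3, 1, n14)]
                    ),
                    "age_group": ["6m"] * n6 + ["14m"] * n14,
                    "strain": list(rng.choice(strains, n6 + n14)),
                }
            )
            try:
                _, p = age_effect_test(df)
            except ValueError:
                continue
            if p < 0.05:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_by_region_applies_fdr(self):
        rng = np.random.default_rng(12)
        rows = []
        for region in range(5):
            shift = 2.0 if region == 0 else 0.0
            for i in range(20):
                age = "6m" if i < 10 else "14m"
                rows.append(
                    {
                        "region_id": region,
                        "load": rng.normal(shift if age == "14m" else 0, 1),
                        "age_group": age,
                        "strain": "s" + str(i % 3),
                    }
                )
        out = age_effect_by_region(pd.DataFrame(rows))
        assert set(out.columns) == {"F", "p", "q", "flag"}
        np.testing.assert_allclose(out["q"], bh_fdr(out["p"].to_numpy()))


class TestMethodDifference:
    def test_identical_pairs_p_one(self):
        assert method_difference_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_n6_all_positive_exact(self):
        # oracle: enumerate all 2^6 sign assignments of the rank sum
        lin = np.zeros(6)
        nonlin = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        stat, p = method_difference_test(lin, nonlin)
        ranks = np.arange(1, 7)
        w_obs = 0.0  # min(W+, W-) with all positive diffs -> W- = 0
        count = 0
        for signs in itertools.product([0, 1], repeat=6):
            w_minus = sum(r for r, s in zip(ranks, signs) if s == 0)
            w_plus = sum(r for r, s in zip(ranks, signs) if s == 1)
            if min(w_plus, w_minus) <= w_obs:
                count += 1
        assert stat == w_obs
        assert p == pytest.approx(count / 64)
        assert p == pytest.approx(2 / 64)

    def test_antisymmetric_statistic_at_center(self):
        lin = np.zeros(6)
        nonlin = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        stat, p = method_difference_test(lin, nonlin)
        assert stat == pytest.approx(6 * 7 / 4)  # n(n+1)/4 null center
        assert p > 0.9

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            method_difference_test([1.0], [1.0, 2.0])

    def test_by_region_applies_fdr(self):
        rng = np.random.default_rng(13)
        rows = []
        for region in range(4):
            lin = rng.normal(5, 1, 10)
            shift = 1.0 if region == 0 else 0.0
            for l in lin:
                rows.append(
                    {
                        "region_id": region,
                        "load_linear": l,
                        "load_nonlinear": l + shift + rng.normal(0, 0.2),
                    }
                )
        out = method_difference_by_region(pd.DataFrame(rows))
        np.testing.assert_allclose(out["q"], bh_fdr(out["p"].to_numpy()))
        assert out.loc[0, "p"] < 0.05


class TestIntegrationPipeline:
    def test_columns_and_categories(self):
        rng = np.random.default_rng(14)
        n = 20
        ages = np.array(["6m"] * 10 + ["14m"] * 10)
        load = rng.normal(5, 1, n) + (ages == "14m") * 2
        expr = pd.DataFrame(
            {f"sample_{i}": rng.normal(size=3) for i in range(n)},
            index=["g1", "g2", "g3"],
        )
        res = correlate_expression_with_load(expr, load, ages)
        assert set(res.columns) >= {
            "r_unadjusted",
            "p_unadjusted",
            "q_unadjusted",
            "r_adjusted",
            "p_adjusted",
            "q_adjusted",
            "category",
        }
        assert res["category"].isin(["age_dependent", "age_independent", "both", "ns"]).all()

    def test_alpha_config_respected(self):
        with pytest.raises(ValueError):
            StatsConfig(alpha=0.0)
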