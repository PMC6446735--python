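"""Group statistics: trend contrast, Hotelling tests, Mann-Whitney U,
quasi-Poisson GLM, and covariate balance."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from cuelpp.cluster import ipsatize_table
from cuelpp.config import CATEGORIES
from cuelpp.data_model import ValidationError
from cuelpp.stats import (
    arousal_contrast,
    covariate_balance,
    group_by_category_test,
    hotelling_two_sample,
    mann_whitney_u,
    one_sample_t,
    pairwise_bonferroni,
    pairwise_group_comparisons,
    quadratic_trend_test,
    quasipoisson_fit,
)
from cuelpp.synth import CohortSpec, simulate_lpp_cohort


def _lpp_df_from_contrast(contrasts):
    """LPP rows whose quadratic arousal contrast equals the given values."""
    rows = {}
    for i, c in enumerate(contrasts):
        row = {f"lpp_{cat}": 0.0 for cat in CATEGORIES}
        row["lpp_erotica"] = row["lpp_mutilation"] = float(c)
        rows[f"p{i:03d}"] = row
    return pd.DataFrame.from_dict(rows, orient="index")


class TestQuadraticTrend:
    def test_hand_computed_t(self):
        df = _lpp_df_from_contrast([1.0, 2.0, 3.0])
        np.testing.assert_allclose(arousal_contrast(df), [1.0, 2.0, 3.0])
        res = quadratic_trend_test(df, list(df.index))
        assert res.statistic == pytest.approx(2.0 / (1.0 / math.sqrt(3.0)), abs=1e-6)
        assert res.df == 2

    def test_all_zero_contrasts(self):
        df = _lpp_df_from_contrast([0.0, 0.0, 0.0])
        res = quadratic_trend_test(df, list(df.index))
        assert res.statistic == 0.0
        assert res.p_raw == 1.0

    def test_group_too_small(self):
        df = _lpp_df_from_contrast([1.0])
        with pytest.raises(ValidationError):
            quadratic_trend_test(df, list(df.index))


class TestHotelling:
    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(0)
        X1 = rng.normal(0, 1, size=(12, 2))
        X2 = rng.normal(0.5, 1, size=(15, 2))
        res = hotelling_two_sample(X1, X2, "group")
        n1, n2 = 12, 15
        d = X1.mean(axis=0) - X2.mean(axis=0)
        S = ((n1 - 1) * np.cov(X1.T) + (n2 - 1) * np.cov(X2.T)) / (n1 + n2 - 2)
        t2 = n1 * n2 / (n1 + n2) * d @ np.linalg.inv(S) @ d
        assert res.statistic == pytest.approx(t2, rel=1e-10)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(1)
        rejections = np.zeros(3)
        n_sim = 300
        for _ in range(n_sim):
            X = rng.normal(size=(40, 8))
            g = np.array(["a"] * 20 + ["b"] * 20)
            res = group_by_category_test(X, g)
            rejections += [
                res["group"].p_raw < 0.05,
                res["category"].p_raw < 0.05,
                res["interaction"].p_raw < 0.05,
            ]
        for rate in rejections / n_sim:
            assert 0.02 <= rate <= 0.09

    def test_interaction_detected_on_profile_cohort(self):
        lpp_df, truth = simulate_lpp_cohort(CohortSpec(seed=21))
        g = np.array([truth.profile_of(p) for p in lpp_df.index])
        X = lpp_df[[f"lpp_{c}" for c in CATEGORIES]].to_numpy()
        res = group_by_category_test(X, g)
        assert res["interaction"].p_raw < 0.001
        assert res["category"].p_raw < 0.001

    def test_rank_deficiency_error(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 8))
        with pytest.raises(ValidationError):
            group_by_category_test(X, np.array(["a"] * 4 + ["b"] * 4))


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [(0.01, 8, 0.08), (0.5, 3, 1.0), (0.2, 1, 0.2)])
    def test_examples(self, p, m, expected):
        assert pairwise_bonferroni([p], m) == [pytest.approx(expected)]

    def test_family_too_small_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_bonferroni([0.1, 0.2], 1)


def brute_force_mw(x, y):
    """Oracle: pair-count U and exact p by enumerating all labelings."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)

    def u_stat(a, b):
        return sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in a for yi in b)

    u_obs = u_stat(x, y)
    pooled = x + y
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu) - 1e-12
    hits = total = 0
    for idx in combinations(range(n1 + n2), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(n1 + n2) if i not in set(idx)]
        total += 1
        if abs(u_stat(a, b) - mu) >= dev:
            hits += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_disjoint_samples_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], method="exact")
        assert res.u_x == 0.0
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(0.1)

    def test_midranks_with_ties(self):
        res = mann_whitney_u([0, 0, 1], [0, 2, 2])
        assert res.u_x == pytest.approx(2.0)
        assert res.u_y == pytest.approx(7.0)

    def test_u_sum_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.integers(0, 6, size=rng.integers(2, 9))
            y = rng.integers(0, 6, size=rng.integers(2, 9))
            res = mann_whitney_u(x, y, method="normal")
            assert res.u_x + res.u_y == pytest.approx(len(x) * len(y))

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            x = rng.integers(0, 5, size=int(rng.integers(2, 8)))
            y = rng.integers(0, 5, size=int(rng.integers(2, 8)))
            res = mann_whitney_u(x, y, method="exact")
            u_oracle, p_oracle = brute_force_mw(x, y)
            assert res.u_x == pytest.approx(u_oracle)
            assert res.p_raw == pytest.approx(p_oracle)

    def test_exact_and_normal_agree_moderate_n(self):
        # The 0.5 continuity correction is exact-spaced for tie-free data;
        # with ties U moves in half-steps and the approximation is coarser in
        # the mid-p range, so there agreement is only asserted in the
        # decision region (p <= 0.2).
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            pe = mann_whitney_u(x, y, method="exact").p_raw
            pn = mann_whitney_u(x, y, method="normal").p_raw
            assert abs(pe - pn) < 0.015
        for _ in range(30):
            x = rng.integers(0, 10, size=8)
            y = rng.integers(0, 10, size=8)
            pe = mann_whitney_u(x, y, method="exact").p_raw
            pn = mann_whitney_u(x, y, method="normal").p_raw
            if pe <= 0.2:
                assert abs(pe - pn) < 0.02

    def test_group_swap(self):
        x, y = [3, 5, 8, 1], [2, 9, 4]
        a = mann_whitney_u(x, y)
        b = mann_whitney_u(y, x)
        assert a.u_x == pytest.approx(b.u_y)
        assert a.p_raw == pytest.approx(b.p_raw)
        assert a.statistic == pytest.approx(b.statistic)

    def test_all_identical_degenerate(self):
        with pytest.warns(UserWarning):
            res = mann_whitney_u([2, 2], [2, 2, 2])
        assert res.p_raw == 1.0


class TestQuasiPoisson:
    def _two_group(self):
        counts = np.array([2, 4, 6, 6])
        design = pd.DataFrame({"group": [0.0, 0.0, 1.0, 1.0]})
        return counts, design

    def test_saturated_two_group_closed_form(self):
        counts, design = self._two_group()
        fit = quasipoisson_fit(counts, design)
        assert fit.rate_ratio["group"] == pytest.approx(2.0, rel=1e-8)
        np.testing.assert_allclose(fit.fitted_means, [3, 3, 6, 6], rtol=1e-8)

    def test_pearson_dispersion_hand_computed(self):
        counts, design = self._two_group()
        fit = quasipoisson_fit(counts, design)
        # Pearson X² = (2-3)²/3 + (4-3)²/3 = 2/3, df = 2
        assert fit.dispersion == pytest.approx(1.0 / 3.0, rel=1e-8)

    def test_covariance_is_phi_times_poisson(self):
        counts, design = self._two_group()
        fit = quasipoisson_fit(counts, design)
        # textbook Poisson variance of the group log-rate-ratio: 1/6 + 1/12
        poisson_var = 1.0 / 6.0 + 1.0 / 12.0
        assert fit.covariance.loc["group", "group"] == pytest.approx(
            fit.dispersion * poisson_var, rel=1e-8
        )

    def test_group_swap_reciprocal_rate_ratio(self):
        counts, design = self._two_group()
        fit = quasipoisson_fit(counts, design)
        flipped = pd.DataFrame({"group": 1.0 - design["group"]})
        fit2 = quasipoisson_fit(counts, flipped)
        assert fit2.rate_ratio["group"] == pytest.approx(
            1.0 / fit.rate_ratio["group"], rel=1e-8
        )
        lo, hi = fit.conf_int.loc["group"]
        lo2, hi2 = fit2.conf_int.loc["group"]
        assert lo2 == pytest.approx(1.0 / hi, rel=1e-8)
        assert hi2 == pytest.approx(1.0 / lo, rel=1e-8)

    def test_rank_deficient_design_rejected(self):
        counts = np.array([1, 2, 3, 4])
        design = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0]})   # collinear with intercept
        with pytest.raises(ValidationError):
            quasipoisson_fit(counts, design)

    def test_categorical_covariates_encoded(self):
        rng = np.random.default_rng(6)
        design = pd.DataFrame(
            {
                "group": rng.integers(0, 2, 40).astype(float),
                "gender": rng.choice(["female", "male"], 40),
            }
        )
        counts = rng.poisson(5.0, 40)
        fit = quasipoisson_fit(counts, design)
        assert "gender[male]" in fit.coefficients.index


class TestCovariateBalance:
    def test_identical_groups_t_zero(self):
        cov = pd.DataFrame({"x": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                           index=[f"p{i}" for i in range(6)])
        labels = {f"p{i}": ("a" if i < 3 else "b") for i in range(6)}
        res = covariate_balance(cov, labels)[0]
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)

    def test_chi_square_hand_computed(self):
        cov = pd.DataFrame(
            {"gender": ["f"] * 10 + ["m"] * 10},
            index=[f"p{i}" for i in range(20)],
        )
        labels = {f"p{i}": ("a" if i < 10 else "b") for i in range(20)}
        res = covariate_balance(cov, labels)[0]
        assert res.stat_name == "chi2"
        assert res.statistic == pytest.approx(20.0)
        assert res.p_raw < 0.001

    def test_zero_variance_not_testable(self):
        cov = pd.DataFrame({"x": [2.0] * 6}, index=[f"p{i}" for i in range(6)])
        labels = {f"p{i}": ("a" if i < 3 else "b") for i in range(6)}
        res = covariate_balance(cov, labels)[0]
        assert "not testable" in res.note

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        hits = total = 0
        for _ in range(200):
            cov = pd.DataFrame({"x": rng.normal(size=30)},
                               index=[f"p{i}" for i in range(30)])
            labels = {f"p{i}": ("a" if i < 15 else "b") for i in range(30)}
            hits += covariate_balance(cov, labels)[0].p_raw < 0.05
            total += 1
        assert 0.01 <= hits / total <= 0.10


class TestPairwiseGroupComparisons:
    def test_adjustment_applied(self):
        lpp_df, truth = simulate_lpp_cohort(CohortSpec(seed=22))
        labels = {p: truth.profile_of(p) for p in lpp_df.index}
        results = pairwise_group_comparisons(lpp_df, labels)
        assert len(results) == len(CATEGORIES)
        for r in results:
            assert r.adjustment == "bonferroni"
            assert r.p_adjusted >= r.p_raw - 1e-12
        by_name = {r.name: r for r in results}
        # the profiles differ in food-paired reactivity, not in neutral
        assert by_name["between_food_paired"].p_adjusted < 0.001
        assert by_name["between_neutral"].p_adjusted > 0.05


def test_one_sample_t_anchor():
    res = one_sample_t([1.0, 2.0, 3.0], popmean=2.0)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    res = one_sample_t([4.0, 5.0, 6.0], popmean=0.0)
    assert res.p_raw < 0.05
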