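"""Test battery for the chi-square/Mann-Whitney/GLM/GLMM/VIF/SMI layer."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from numpy.polynomial.hermite_e import hermegauss
from scipy import integrate, special
from scipy import stats as sps

from cavityepp.stats import (
    _glmm_loglik,
    chi_square_2x2,
    compute_vif,
    glm_binomial,
    glmm_binomial,
    mann_whitney_u,
    scaled_mass_index,
    zscale,
)


class TestChiSquare:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((11, 19, 17, 20), 0.267),
            ((12, 20, 16, 10), 2.427),
            ((16, 181, 28, 209), 1.230),
            ((20, 159, 30, 159), 1.352),
        ],
    )
    def test_published_statistics_reproduce(self, table, expected):
        res = chi_square_2x2(*table, continuity=True)
        assert res.statistic == pytest.approx(expected, abs=5e-4)
        assert res.df == 1

    def test_proportional_table_zero_without_correction(self):
        res = chi_square_2x2(10, 10, 20, 20, continuity=False)
        assert res.statistic == 0.0

    @given(
        a=st.integers(1, 50), b=st.integers(1, 50),
        c=st.integers(1, 50), d=st.integers(1, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_yates_closed_form(self, a, b, c, d):
        res = chi_square_2x2(a, b, c, d, continuity=True)
        n = a + b + c + d
        num = n * max(abs(a * d - b * c) - n / 2, 0) ** 2
        den = (a + b) * (c + d) * (a + c) * (b + d)
        assert res.statistic == pytest.approx(num / den, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(0, 0, 5, 5)

    def test_type_one_error_calibrated(self):
        """Null rejection rate near nominal 0.05 at the study's margins."""
        rng = np.random.default_rng(0)
        n1, n2, p = 30, 37, 0.4
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a = rng.binomial(n1, p)
            c = rng.binomial(n2, p)
            if a in (0, n1) or c in (0, n2):
                continue
            res = chi_square_2x2(a, n1 - a, c, n2 - c, continuity=False)
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0

    def test_exact_p_matches_enumeration(self):
        x = [1.2, 3.4, 0.5, 7.1, 2.2]
        y = [2.9, 5.5, 6.1, 0.9, 4.4]
        res = mann_whitney_u(x, y)
        assert "exact" in res.notes
        # brute force over all C(10, 5) labelings of the pooled sample
        pooled = np.array(x + y)
        n1 = len(x)
        u_obs = res.statistic

        def u_stat(first_idx):
            first = pooled[list(first_idx)]
            rest = np.delete(pooled, list(first_idx))
            return sum((a > b) + 0.5 * (a == b) for a in first for b in rest)

        us = [
            u_stat(idx)
            for idx in itertools.combinations(range(len(pooled)), n1)
        ]
        mean_u = n1 * (len(pooled) - n1) / 2
        extreme = sum(
            abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9 for u in us
        )
        assert res.p_value == pytest.approx(extreme / len(us), abs=1e-12)

    def test_tie_corrected_variance_matches_textbook(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0]
        y = [2.0, 3.0, 4.0, 4.0, 6.0]
        res = mann_whitney_u(x, y, continuity=False, exact_max_n=0)
        n1 = n2 = 5
        n = n1 + n2
        pooled = np.array(x + y)
        ranks = sps.rankdata(pooled)
        r1 = ranks[:n1].sum()
        u = r1 - n1 * (n1 + 1) / 2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = sum(t**3 - t for t in tie_counts)
        var_u = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
        z = (u - n1 * n2 / 2) / np.sqrt(var_u)
        p = 2 * sps.norm.sf(abs(z))
        assert res.statistic == pytest.approx(u)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_all_tied_degenerate(self):
        with pytest.warns(UserWarning, match="identical"):
            res = mann_whitney_u([2, 2], [2, 2, 2])
        assert res.p_value == 1.0


class TestZScale:
    def test_simple(self):
        np.testing.assert_allclose(zscale([1, 2, 3]), [-1, 0, 1])

    def test_moments(self):
        rng = np.random.default_rng(1)
        z = zscale(rng.normal(3, 7, size=200))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12

    def test_idempotent_on_standardized(self):
        rng = np.random.default_rng(2)
        z = zscale(rng.normal(size=100))
        np.testing.assert_allclose(zscale(z), z, atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            zscale([4.0, 4.0, 4.0])


class TestGlmBinomial:
    def test_null_model_balanced(self):
        y = np.array([0.0, 1.0] * 50)
        fit = glm_binomial(y, pd.DataFrame(index=range(100)))
        assert fit.coef("const") == pytest.approx(0.0, abs=1e-8)

    def test_coefficient_recovery(self):
        rng = np.random.default_rng(3)
        n = 500
        x = rng.normal(size=n)
        eta = -1.0 + 0.8 * x
        y = (rng.uniform(size=n) < special.expit(eta)).astype(float)
        fit = glm_binomial(y, pd.DataFrame({"x": x}))
        assert abs(fit.coef("const") - (-1.0)) < 3 * fit.se_of("const")
        assert abs(fit.coef("x") - 0.8) < 3 * fit.se_of("x")

    def test_lrt_matches_uncorrected_chi_square_asymptotically(self):
        rng = np.random.default_rng(4)
        n = 2000
        group = rng.integers(0, 2, size=n).astype(float)
        p = np.where(group == 1, 0.55, 0.45)
        y = (rng.uniform(size=n) < p).astype(float)
        fit = glm_binomial(y, pd.DataFrame({"g": group}))
        a = int(((group == 0) & (y == 1)).sum())
        b = int(((group == 0) & (y == 0)).sum())
        c = int(((group == 1) & (y == 1)).sum())
        d = int(((group == 1) & (y == 0)).sum())
        chi = chi_square_2x2(a, b, c, d, continuity=False)
        assert abs(fit.p_lrt["g"] - chi.p_value) < 0.01

    def test_separation_flagged(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0] * 5)
        y = (x > 2.5).astype(float)
        fit = glm_binomial(y, pd.DataFrame({"x": x}))
        assert any("separation" in w for w in fit.warnings)

    def test_aliased_column_dropped_and_reported(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=80)
        y = (rng.uniform(size=80) < 0.5).astype(float)
        X = pd.DataFrame({"x": x, "x2": 2 * x, "const_col": np.ones(80)})
        fit = glm_binomial(y, X)
        assert "const_col" in fit.dropped_columns
        assert "x2" in fit.dropped_columns


class TestGlmmBinomial:
    def test_marginal_likelihood_matches_numeric_integration(self):
        """Tiny instance: adaptive quadrature vs brute-force integration."""
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(9), rng.normal(size=9)])
        y = rng.integers(0, 2, size=9).astype(float)
        n = np.ones(9)
        group_idx = [np.arange(0, 3), np.arange(3, 6), np.arange(6, 9)]
        beta = np.array([-0.3, 0.5])
        sigma = 0.8
        nodes, weights = hermegauss(15)
        ll = _glmm_loglik(
            np.append(beta, np.log(sigma)), X, y, n, group_idx, nodes, weights
        )
        brute = 0.0
        for g in group_idx:
            def integrand(u, g=g):
                eta = X[g] @ beta + u
                lik = np.exp(np.sum(y[g] * eta - np.logaddexp(0, eta)))
                return lik * np.exp(-u * u / (2 * sigma**2)) / np.sqrt(
                    2 * np.pi * sigma**2
                )
            val, _ = integrate.quad(integrand, -12, 12, epsabs=1e-13)
            brute += np.log(val)
        assert abs(ll - brute) < 1e-6

    def test_zero_variance_truth_matches_glm(self):
        rng = np.random.default_rng(7)
        n = 400
        x = rng.normal(size=n)
        g = np.repeat(np.arange(40), 10)
        y = (rng.uniform(size=n) < special.expit(0.3 * x)).astype(float)
        glmm = glmm_binomial(y, pd.DataFrame({"x": x}), g)
        glm = glm_binomial(y, pd.DataFrame({"x": x}))
        assert glmm.random_intercept_var is not None
        # finite-sample MLE of a zero variance is small but positive
        # (0.083 here, identical to the lme4 nAGQ=15 estimate on this data)
        assert glmm.random_intercept_var < 0.15
        assert abs(glmm.coef("x") - glm.coef("x")) < 0.02

    def test_recovery_across_replicates(self):
        """60 groups x 8 obs, sigma2=1: fixed effects within 3 SE,
        variance in a sane band, across replicates."""
        ok_beta, sigmas = 0, []
        reps = 5
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            G, m = 60, 8
            g = np.repeat(np.arange(G), m)
            u = rng.normal(0, 1.0, G)[g]
            x = rng.normal(size=G * m)
            eta = -0.5 + 0.7 * x + u
            y = (rng.uniform(size=G * m) < special.expit(eta)).astype(float)
            fit = glmm_binomial(y, pd.DataFrame({"x": x}), g)
            assert fit.converged
            if (
                abs(fit.coef("const") + 0.5) < 3 * fit.se_of("const")
                and abs(fit.coef("x") - 0.7) < 3 * fit.se_of("x")
            ):
                ok_beta += 1
            sigmas.append(fit.random_intercept_var)
        assert ok_beta >= reps - 1
        assert all(0.5 <= s <= 2.0 for s in sigmas)

    def test_proportion_response(self):
        rng = np.random.default_rng(8)
        G = 40
        trials = rng.integers(5, 11, size=G).astype(float)
        x = rng.normal(size=G)
        u = rng.normal(0, 0.7, G)
        p = special.expit(-0.4 + 0.6 * x + u)
        y = rng.binomial(trials.astype(int), p).astype(float)
        fit = glmm_binomial(
            y, pd.DataFrame({"x": x}), np.arange(G), trials=trials
        )
        assert fit.converged
        assert abs(fit.coef("x") - 0.6) < 3 * fit.se_of("x")

    def test_lrt_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(9)
        G, m = 30, 6
        g = np.repeat(np.arange(G), m)
        x = rng.normal(size=G * m)
        u = rng.normal(0, 0.8, G)[g]
        y = (rng.uniform(size=G * m) < special.expit(0.5 * x + u)).astype(float)
        fit1 = glmm_binomial(y, pd.DataFrame({"x": x}), g)
        fit2 = glmm_binomial(y, pd.DataFrame({"x": 100 * x}), g)
        assert fit1.p_lrt["x"] == pytest.approx(fit2.p_lrt["x"], abs=1e-4)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            glmm_binomial(
                np.array([0.0, 1.0]),
                pd.DataFrame({"x": [0.0, 1.0]}),
                ["a", "a"],
            )


class TestVif:
    def test_orthogonal_predictors(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        vif = compute_vif(X)
        assert vif["a"] == pytest.approx(1.0)
        assert vif["b"] == pytest.approx(1.0)

    def test_duplicate_predictor_infinite(self):
        x = np.arange(10.0)
        vif = compute_vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(vif["a"])

    def test_correlated_pair_closed_form(self):
        # construct an exactly r=0.8 pair
        rng = np.random.default_rng(10)
        a = rng.normal(size=5000)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=5000)
        vif = compute_vif(pd.DataFrame({"a": a, "b": b}))
        r2 = np.corrcoef(a, b)[0, 1] ** 2
        assert vif["a"] == pytest.approx(1 / (1 - r2), rel=1e-6)
        assert vif["a"] == pytest.approx(2.78, abs=0.15)


class TestScaledMassIndex:
    def test_identical_individuals_keep_mass(self):
        smi = scaled_mass_index([10.0] * 4, [16.0] * 4)
        np.testing.assert_allclose(smi, 10.0)

    def test_synthetic_allometry_slope_two(self):
        rng = np.random.default_rng(11)
        n = 500
        tarsus = rng.normal(16.5, 0.8, n)
        # scatter small relative to the allometric range: the SMA slope's
        # deliberate overcorrection (b = b_OLS / r) then stays negligible
        mass = np.exp(2.0 * np.log(tarsus) + rng.normal(0, 0.01, n))
        smi = scaled_mass_index(mass, tarsus)
        r = np.corrcoef(smi, tarsus)[0, 1]
        assert abs(r) < 0.1

    def test_hand_computed_fixture(self):
        mass = np.array([10.0, 11.0, 12.0, 13.0])
        tarsus = np.array([15.0, 16.0, 17.0, 18.0])
        lm, lt = np.log(mass), np.log(tarsus)
        b_ols = np.cov(lm, lt, ddof=1)[0, 1] / np.var(lt, ddof=1)
        r = np.corrcoef(lm, lt)[0, 1]
        b_sma = b_ols / r
        L0 = tarsus.mean()
        expected = mass * (L0 / tarsus) ** b_sma
        np.testing.assert_allclose(
            scaled_mass_index(mass, tarsus), expected, rtol=1e-12
        )

    def test_uncorrelated_rejected(self):
        rng = np.random.default_rng(12)
        mass = rng.uniform(9, 12, 100)
        # tarsus constant -> slope undefined, mass varies
        with pytest.raises(ValueError, match="undefined"):
            scaled_mass_index(mass, np.full(100, 16.0))
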