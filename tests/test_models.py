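"""Regression suite: OLS fits, the saturating logistic, and AIC selection."""

import numpy as np
import pandas as pd
import pytest

from coralhue.models import (
    SingularDesignError,
    compare_aic,
    family_ranking,
    fit_family_models,
    fit_linear,
    fit_poly2_plus_hue,
    fit_quadratic,
    fit_regional_models,
    fit_saturating,
    ortho_poly,
)
from coralhue.synth import SynthConfig, make_regression_table


def normal_equations(X, y):
    """Closed-form OLS oracle: beta = (XᵀX)⁻¹Xᵀy with explicit intercept."""
    Xd = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xd.T @ Xd, Xd.T @ y)


class TestLinear:
    def test_exact_line_r2_one(self):
        x = np.arange(10.0)
        fit = fit_linear(x, 3.0 + 2.0 * x)
        assert fit.adjusted_r2 == pytest.approx(1.0)
        assert fit.coefficients["x"] == pytest.approx(2.0)

    def test_null_case_r2_near_zero(self, rng):
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        assert abs(fit_linear(x, y).adjusted_r2) < 0.05

    def test_hand_dataset_matches_normal_equations(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 3.0, 3.5, 6.0, 10.0])
        beta = normal_equations(x[:, None], y)
        fit = fit_linear(x, y)
        assert fit.coefficients["intercept"] == pytest.approx(beta[0], abs=1e-10)
        assert fit.coefficients["x"] == pytest.approx(beta[1], abs=1e-10)

    def test_constant_predictor_rejected(self):
        with pytest.raises(SingularDesignError):
            fit_linear(np.ones(10), np.arange(10.0))

    def test_coefficients_match_normal_equations_up_to_n50(self, rng):
        for n in (5, 12, 50):
            x = rng.normal(size=n) * 10
            y = 1.5 + 0.7 * x + rng.normal(size=n)
            beta = normal_equations(x[:, None], y)
            fit = fit_linear(x, y)
            assert fit.coefficients["intercept"] == pytest.approx(beta[0], abs=1e-8)
            assert fit.coefficients["x"] == pytest.approx(beta[1], abs=1e-8)

    def test_adjusted_r2_identity(self, rng):
        """adj R² = 1 - (1-R²)(n-1)/(n-p-1) with R² from brute-force residuals."""
        n = 30
        x = rng.normal(size=n)
        y = 2 + x + rng.normal(size=n)
        fit = fit_linear(x, y)
        beta = normal_equations(x[:, None], y)
        resid = y - beta[0] - beta[1] * x
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        expected = 1 - (1 - r2) * (n - 1) / (n - 1 - 1)
        assert fit.adjusted_r2 == pytest.approx(expected, abs=1e-10)


class TestQuadratic:
    def test_exact_parabola(self):
        x = np.linspace(-3, 5, 20)
        fit = fit_quadratic(x, 1 - 2 * x + 0.5 * x**2)
        assert fit.adjusted_r2 == pytest.approx(1.0)
        assert fit.raw_coefficients["x2"] == pytest.approx(0.5, abs=1e-8)

    def test_degrees_of_freedom_at_n74(self, rng):
        x = rng.normal(size=74)
        y = x + rng.normal(size=74)
        fit = fit_quadratic(x, y)
        assert (fit.df_model, fit.df_residual) == (2, 71)

    def test_hand_dataset_matches_normal_equations(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 5.0, 8.0])
        y = np.array([1.0, 0.5, 2.0, 4.5, 11.0, 30.0])
        beta = normal_equations(np.column_stack([x, x**2]), y)
        fit = fit_quadratic(x, y)
        assert fit.raw_coefficients["raw_intercept"] == pytest.approx(beta[0], abs=1e-8)
        assert fit.raw_coefficients["x"] == pytest.approx(beta[1], abs=1e-8)
        assert fit.raw_coefficients["x2"] == pytest.approx(beta[2], abs=1e-8)


class TestOrthoPoly:
    def test_columns_orthonormal_and_span(self, rng):
        x = rng.uniform(0, 600, size=40)
        Z, C = ortho_poly(x, 2)
        assert Z.T @ Z == pytest.approx(np.eye(2), abs=1e-8)
        V = np.vander(x, 3, increasing=True)
        assert V @ C == pytest.approx(Z, abs=1e-8)


class TestPoly2PlusHue:
    def test_zero_noise_recovery(self):
        cfg = SynthConfig(seed=1)
        df, truth = make_regression_table(cfg, zero_noise=True)
        fit = fit_poly2_plus_hue(df.coral_richness, df.hue_diversity, df.fish_total)
        b0, bh, b1, b2 = truth["regression_truth"]
        assert fit.raw_coefficients["raw_intercept"] == pytest.approx(b0, abs=1e-8)
        assert fit.raw_coefficients["hue"] == pytest.approx(bh, abs=1e-8)
        assert fit.raw_coefficients["coral"] == pytest.approx(b1, abs=1e-8)
        assert fit.raw_coefficients["coral2"] == pytest.approx(b2, abs=1e-8)
        assert fit.adjusted_r2 == pytest.approx(1.0)

    def test_degrees_of_freedom_at_n74(self):
        df, _ = make_regression_table(SynthConfig(seed=2))
        fit = fit_poly2_plus_hue(df.coral_richness, df.hue_diversity, df.fish_total)
        assert fit.n == 74
        assert (fit.df_model, fit.df_residual) == (3, 70)

    def test_noisy_recovery_within_3_empirical_se(self):
        """Estimates fall within 3 simulation SDs of truth in >= 95% of replicates."""
        cfg = SynthConfig(seed=0)
        b_true = np.array(cfg.regression_truth)
        n_rep = 200
        est = np.empty((n_rep, 4))
        for r in range(n_rep):
            df, _ = make_regression_table(cfg, seed=1000 + r)
            fit = fit_poly2_plus_hue(df.coral_richness, df.hue_diversity, df.fish_total)
            est[r] = [
                fit.raw_coefficients["raw_intercept"],
                fit.raw_coefficients["hue"],
                fit.raw_coefficients["coral"],
                fit.raw_coefficients["coral2"],
            ]
        se = est.std(axis=0, ddof=1)
        covered = (np.abs(est - b_true) <= 3 * se).all(axis=1)
        assert covered.mean() >= 0.95


class TestSaturating:
    def test_zero_noise_parameter_recovery(self):
        x = np.linspace(0, 800, 60)
        A, k, x0 = 180.0, 0.015, 150.0
        y = A / (1 + np.exp(-k * (x - x0)))
        fit = fit_saturating(x, y)
        assert fit.coefficients["A"] == pytest.approx(A, abs=1e-6)
        assert fit.coefficients["k"] == pytest.approx(k, abs=1e-6)
        assert fit.coefficients["x0"] == pytest.approx(x0, abs=1e-6)

    def test_noisy_asymptote_within_3_empirical_se(self):
        cfg = SynthConfig(seed=0)
        A_true = cfg.logistic_truth[0]
        est = []
        for r in range(60):
            df, _ = make_regression_table(cfg, seed=5000 + r)
            est.append(fit_saturating(df.coral_richness, df.hue_diversity).coefficients["A"])
        est = np.array(est)
        assert abs(est.mean() - A_true) <= 3 * est.std(ddof=1)

    def test_negative_hue_rejected(self):
        with pytest.raises(ValueError):
            fit_saturating(np.arange(10.0), np.arange(10.0) - 5)


class TestCompareAic:
    def test_duplicate_fits_tie_break_to_first(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        f1 = fit_linear(x, y, label="first")
        f2 = fit_linear(x, y, label="second")
        comp = compare_aic([f1, f2])
        assert comp.best == "first"
        assert comp.delta_aic == {"first": 0.0, "second": 0.0}

    def test_mismatched_n_rejected(self, rng):
        f1 = fit_linear(np.arange(10.0), rng.normal(size=10), response="y")
        f2 = fit_linear(np.arange(12.0), rng.normal(size=12), response="y")
        with pytest.raises(ValueError):
            compare_aic([f1, f2])

    def test_deltas_match_statsmodels_loglik_aic(self, rng):
        """The least-squares AIC differs from the Gaussian-likelihood AIC by a
        constant in n only, so deltas between same-n models agree."""
        import statsmodels.api as sm

        n = 40
        x = rng.normal(size=n)
        y = 1 + 2 * x + rng.normal(size=n)
        f_lin = fit_linear(x, y, response="y")
        f_quad = fit_quadratic(x, y, response="y")
        m1 = sm.OLS(y, sm.add_constant(x)).fit()
        m2 = sm.OLS(y, sm.add_constant(np.column_stack([x, x**2]))).fit()
        assert f_quad.aic - f_lin.aic == pytest.approx(m2.aic - m1.aic, abs=1e-6)

    def test_pure_noise_term_penalized_in_majority(self):
        wins = 0
        n_rep = 100
        for r in range(n_rep):
            rng = np.random.default_rng(r)
            x = rng.uniform(-3, 3, size=200)
            y = 1 + 2 * x + rng.normal(size=200)
            simple = fit_linear(x, y, label="linear", response="y")
            complex_ = fit_quadratic(x, y, label="quadratic", response="y")
            if compare_aic([simple, complex_]).best == "linear":
                wins += 1
        assert wins > n_rep / 2

    def test_combined_wins_when_both_effects_present(self):
        hits = 0
        cfg = SynthConfig(seed=0, noise_sd=60.0)
        for r in range(25):
            df, _ = make_regression_table(cfg, seed=200 + r)
            lin = fit_linear(df.coral_richness, df.fish_total, label="coral", response="f")
            quad = fit_quadratic(df.hue_diversity, df.fish_total, label="hue", response="f")
            comb = fit_poly2_plus_hue(
                df.coral_richness, df.hue_diversity, df.fish_total,
                label="combined", response="f",
            )
            if compare_aic([lin, quad, comb]).best == "combined":
                hits += 1
        assert hits >= 20


class TestFamilyModels:
    def _table(self, seed=4):
        rng = np.random.default_rng(seed)
        df, _ = make_regression_table(SynthConfig(seed=seed))
        # two families: tight (low noise) and loose (high noise) copies of the signal
        df["fish_tight"] = 0.1 * df.fish_total + rng.normal(0, 5, len(df))
        df["fish_loose"] = 0.1 * df.fish_total + rng.normal(0, 120, len(df))
        return df

    def test_ranking_recovers_noise_ordering(self):
        table = self._table()
        comps = fit_family_models(table, ["tight", "loose"])
        ranking = family_ranking(comps)
        assert ranking.family.tolist() == ["tight", "loose"]

    def test_degenerate_family_flagged_not_crashed(self):
        table = self._table()
        table["fish_zero"] = 0.0
        comps = fit_family_models(table, ["zero"])
        combined = comps["zero"].fit("combined")
        assert "degenerate response (constant)" in combined.notes
        assert np.isnan(combined.adjusted_r2)

    def test_missing_family_key_error(self):
        with pytest.raises(KeyError):
            fit_family_models(self._table(), ["ghost"])


class TestRegionalModels:
    def test_regions_share_global_coefficients(self):
        cfg = SynthConfig(seed=0, noise_sd=40.0)
        df, truth = make_regression_table(cfg, seed=31)
        fits = fit_regional_models(df)
        b_hue = truth["regression_truth"][1]
        usable = [f for f in fits.values() if not f.notes and np.isfinite(f.adjusted_r2)]
        assert len(usable) >= 2
        # regional hue slopes scatter around the global truth
        slopes = [f.coefficients["hue"] for f in usable]
        assert min(slopes) < b_hue < max(slopes) or all(
            abs(s - b_hue) < 3.0 for s in slopes
        )

    def test_tiny_region_flagged_degenerate(self):
        df, _ = make_regression_table(SynthConfig(seed=3, n_ecoregions=20))
        df.loc[:, "ocean_region"] = "Big"
        df.iloc[:4, df.columns.get_loc("ocean_region")] = "Tiny"
        fits = fit_regional_models(df)
        assert any("degenerate" in n for n in fits["Tiny"].notes)
        assert np.isnan(fits["Tiny"].adjusted_r2)

    def test_underpowered_region_still_fitted(self):
        df, _ = make_regression_table(SynthConfig(seed=3, n_ecoregions=20))
        df.loc[:, "ocean_region"] = "Big"
        df.iloc[:5, df.columns.get_loc("ocean_region")] = "Small"
        fits = fit_regional_models(df)
        assert "underpowered" in fits["Small"].notes
        assert np.isfinite(fits["Small"].f_statistic) or np.isnan(fits["Small"].f_statistic)
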