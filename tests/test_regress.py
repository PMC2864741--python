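import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import landuse_enm as le
from landuse_enm.niche import SuitabilitySurface


class TestTransform:
    def test_known_values(self):
        np.testing.assert_allclose(le.log10p1(np.array([0.0, 99.0])), [0.0, 2.0])

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1e6, 100)
        np.testing.assert_allclose(le.inv_log10p1(le.log10p1(x)), x, rtol=1e-10)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            le.log10p1(np.array([-1.0]))


class TestLinearFit:
    def test_exact_line(self):
        x = np.linspace(0, 1, 20)
        fit = le.linear_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0) and fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_independent_response_r2_near_zero(self):
        rng = np.random.default_rng(1)
        fit = le.linear_fit(rng.uniform(0, 1, 2000), rng.standard_normal(2000))
        assert fit.r2 < 0.01

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-3, 3, 50)
        y = 0.7 * x - 1.2 + rng.standard_normal(50)
        fit = le.linear_fit(x, y)
        X = np.column_stack([np.ones(50), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0]) and fit.slope == pytest.approx(beta[1])

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            le.linear_fit(np.ones(10), np.arange(10.0))


class TestBreakpointFit:
    def test_noise_free_exact_recovery(self):
        p = le.PopulationParams(a=0.2, b=6.0, c=0.3, d=0.5, sigma=0.0)
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 500)
        y = p.mean_log10(x)
        fit = le.breakpoint_fit(x, y)
        assert abs(fit.c - 0.3) <= 0.005 + 1e-12  # grid resolution
        # a,b,d absorb the knot quantization: tolerance ~ |b| * grid step
        assert fit.a == pytest.approx(0.2, abs=0.04)
        assert fit.b == pytest.approx(6.0, abs=0.05)
        assert fit.d == pytest.approx(0.5, abs=0.05)
        assert fit.r2 > 0.9999

    def test_linear_data_prefers_linear_by_aic(self):
        rng = np.random.default_rng(4)
        wins = 0
        for _ in range(20):
            x = rng.uniform(0, 1, 300)
            y = 1.0 + 2.0 * x + rng.normal(0, 0.5, 300)
            lin = le.linear_fit(x, y)
            brk = le.breakpoint_fit(x, y, resolution=0.01)
            wins += lin.aic < brk.aic
            assert brk.r2 >= lin.r2 - 1e-12  # nesting
        assert wins >= 15

    def test_recovers_knot_under_noise(self):
        p = le.PopulationParams(a=0.2, b=6.0, c=0.3, d=0.5, sigma=0.4)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s = rng.uniform(0, 1, (40, 50))
            pop = le.synth_population(le.Grid(s), p, seed=seed + 100)
            y = le.log10p1(pop.values.ravel())
            fit = le.breakpoint_fit(s.ravel(), y)
            hits += 0.25 <= fit.c <= 0.35
        assert hits >= 18

    def test_tie_breaks_to_smallest_candidate(self):
        # perfectly linear noise-free data: every knot fits exactly
        x = np.linspace(0, 1, 50)
        fit = le.breakpoint_fit(x, 2 * x, resolution=0.1)
        lo = np.quantile(x, 0.05)
        first_valid = next(c for c in np.arange(lo, 1, 0.1) if (x < c).sum() >= 3)
        assert fit.c == pytest.approx(first_valid)

    def test_unidentifiable_rejected(self):
        x = np.concatenate([np.zeros(2), np.ones(10)])
        with pytest.raises(ValueError, match="identifiable"):
            le.breakpoint_fit(x, x, c_grid=np.array([0.5]))


class TestCompareAIC:
    def test_single_fit_delta_zero(self):
        x = np.linspace(0, 1, 30)
        fit = le.linear_fit(x, x + 0.1 * np.sin(x))
        tab = le.compare_aic([fit])
        assert tab["delta_aic"].tolist() == [0.0]

    def test_ranking_invariant_to_order(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 200)
        y = 1 + x + rng.normal(0, 0.3, 200)
        lin, brk = le.linear_fit(x, y), le.breakpoint_fit(x, y, resolution=0.02)
        t1 = le.compare_aic([lin, brk])
        t2 = le.compare_aic([brk, lin])
        assert t1["model"].tolist() == t2["model"].tolist()

    def test_mismatched_n_rejected(self):
        f1 = le.linear_fit(np.arange(10.0), np.arange(10.0) + 0.01 * np.random.default_rng(0).standard_normal(10))
        f2 = le.linear_fit(np.arange(12.0), np.arange(12.0) ** 1.1)
        with pytest.raises(ValueError, match="sample sizes"):
            le.compare_aic([f1, f2])


class TestLogisticFit:
    def test_two_by_two_closed_form_log_odds(self):
        # single binary predictor: coefficient = log odds ratio, exactly
        x = np.repeat([0, 0, 1, 1], [30, 10, 8, 32]).astype(float)
        y = np.concatenate([np.zeros(30), np.ones(10), np.zeros(8), np.ones(32)])
        fit = le.logistic_fit(pd.DataFrame({"x": x}), y)
        lor = np.log((32 / 8) / (10 / 30))
        assert fit.params["x"] == pytest.approx(lor, abs=1e-6)
        assert fit.params["const"] == pytest.approx(np.log(10 / 30), abs=1e-6)

    def test_independent_predictor_small_chi2(self):
        rng = np.random.default_rng(6)
        y = (rng.random(400) < 0.3).astype(float)
        fit = le.logistic_fit(pd.DataFrame({"x": rng.standard_normal(400)}), y)
        assert fit.chi2 < 10
        assert abs(fit.accuracy - max((y == 0).mean(), (y == 1).mean())) < 0.05

    def test_matches_direct_likelihood_optimum(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(20)
        y = (rng.random(20) < 1 / (1 + np.exp(-(0.5 + 1.5 * x)))).astype(float)
        fit = le.logistic_fit(pd.DataFrame({"x": x}), y)

        def nll(b):
            eta = b[0] + b[1] * x
            return np.sum(np.log1p(np.exp(eta)) - y * eta)

        # independent oracle: coarse grid then Nelder-Mead polish
        grid = [(b0, b1) for b0 in np.linspace(-3, 3, 25) for b1 in np.linspace(-3, 5, 33)]
        b0, b1 = min(grid, key=lambda b: nll(b))
        res = minimize(nll, [b0, b1], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12})
        assert fit.params["const"] == pytest.approx(res.x[0], abs=1e-3)
        assert fit.params["x"] == pytest.approx(res.x[1], abs=1e-3)

    def test_perfect_separation_flagged_not_fatal(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = x.copy()
        fit = le.logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.separation_flag
        assert fit.accuracy == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            le.logistic_fit(pd.DataFrame({"x": np.arange(5.0)}), np.zeros(5))


class TestSurfaces:
    def make_fit(self):
        p = le.PopulationParams(a=0.2, b=6.0, c=0.3, d=0.5, sigma=0.0)
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 200)
        return le.breakpoint_fit(x, p.mean_log10(x))

    def test_constant_grid_gives_constant_surface(self):
        fit = self.make_fit()
        g = le.Grid(np.full((4, 4), 0.6))
        pred = le.predict_surface(fit, SuitabilitySurface(g, "logistic"))
        assert np.ptp(pred.valid_values()) < 1e-9

    def test_value_at_knot(self):
        fit = self.make_fit()
        g = le.Grid(np.full((2, 2), fit.c))
        pred = le.predict_surface(fit, SuitabilitySurface(g, "logistic"))
        np.testing.assert_allclose(pred.values, 10 ** (fit.a + fit.b * fit.c) - 1,
                                   rtol=1e-9)

    def test_matches_pointwise_formula(self):
        fit = self.make_fit()
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 1, (6, 7))
        pred = le.predict_surface(fit, SuitabilitySurface(le.Grid(vals), "logistic"))
        expected = np.maximum(10 ** fit.predict(vals) - 1, 0)
        np.testing.assert_allclose(pred.values, expected, rtol=1e-12)

    def test_residual_map_basics(self):
        obs = le.Grid(np.full((3, 3), 10.0))
        pred = le.Grid(np.full((3, 3), 10.0))
        np.testing.assert_allclose(le.residual_map(obs, pred).values, 0.0)
        obs5 = le.Grid(np.full((3, 3), 15.0))
        np.testing.assert_allclose(le.residual_map(obs5, pred).values, 5.0)

    def test_residuals_unbiased_on_log_scale_skewed_on_natural(self):
        p = le.PopulationParams(a=0.2, b=6.0, c=0.3, d=0.5, sigma=0.4)
        rng = np.random.default_rng(10)
        s = le.Grid(rng.uniform(0, 1, (40, 50)))
        pop = le.synth_population(s, p, seed=11)
        y = le.log10p1(pop.values.ravel())
        fit = le.breakpoint_fit(s.values.ravel(), y)
        assert abs(fit.residuals.mean()) < 0.02          # log scale: centered
        pred = le.predict_surface(fit, s)
        resid = le.residual_map(pop, pred).values.ravel()
        from scipy.stats import skew
        assert skew(resid) > 1.0                          # natural scale: heavy right tail
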