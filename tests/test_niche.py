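import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

import landuse_enm as le
from landuse_enm.niche import auc_score


def two_state_tables(m=20):
    """One continuous feature taking values 0 and 1; presences all at 1."""
    bg = pd.DataFrame({"v": [0.0, 1.0]})
    pres = pd.DataFrame({"v": np.ones(m)})
    return pres, bg


def objective(model, pres, bg):
    """Recompute the regularized objective from a fitted model (oracle for
    the convexity check)."""
    Fp = model.expansion.transform(pres)
    Fb = model.expansion.transform(bg)
    s = Fb.std(axis=0)
    pen = model.beta * np.maximum(s, 1e-3) / np.sqrt(len(pres))
    lam = model.lam
    return float(-(Fp.mean(axis=0) @ lam) + logsumexp(Fb @ lam) + pen @ np.abs(lam))


class TestFit:
    def test_two_state_closed_form(self):
        # With a single 0/1 feature (after expansion, linear == quadratic, so
        # only the total weight L matters and the cheapest penalty for L is
        # one feature's rate) and every presence in state 1, the optimum has
        # a closed form: sigma(L) = 1 - r with r = beta * s / sqrt(m), s = 0.5,
        # hence fitted q(1) = 1 - r.
        m = 25
        pres, bg = two_state_tables(m)
        model = le.fit_maxent(pres, bg, beta=1.0, categorical_var=None, tol=1e-14)
        r = 1.0 * 0.5 / np.sqrt(m)
        q1 = model.raw_scores(pd.DataFrame({"v": [1.0]}))[0]
        assert abs(q1 - (1 - r)) < 1e-4

    def test_two_state_unregularized_concentrates(self):
        pres, bg = two_state_tables()
        model = le.fit_maxent(pres, bg, beta=0.0, categorical_var=None, tol=1e-14)
        q1 = model.raw_scores(pd.DataFrame({"v": [1.0]}))[0]
        assert q1 > 0.999

    def test_no_signal_limit(self, small_world):
        # presences drawn uniformly from the background itself
        rng = np.random.default_rng(0)
        bg = small_world["background"]
        pres = bg.iloc[rng.choice(len(bg), 100, replace=False)]
        model = le.fit_maxent(pres, bg)
        assert np.abs(model.lam).max() < 2.0
        auc = auc_score(model.raw_scores(pres), model.raw_scores(bg))
        assert abs(auc - 0.5) < 0.05

    def test_background_normalization(self, fitted_model, small_world):
        assert abs(fitted_model["model"].bg_raw_sorted.sum() - 1.0) < 1e-8
        raw = fitted_model["model"].raw_scores(small_world["background"])
        assert abs(raw.sum() - 1.0) < 1e-8

    def test_convexity_restarts_agree(self, small_world):
        pres, bg = small_world["presences"], small_world["background"]
        tol = 1e-9
        m1 = le.fit_maxent(pres, bg, tol=tol)
        rng = np.random.default_rng(3)
        x0 = rng.normal(0, 1, m1.lam.size)
        m2 = le.fit_maxent(pres, bg, tol=tol, x0=x0)
        f1, f2 = objective(m1, pres, bg), objective(m2, pres, bg)
        assert abs(f1 - f2) < max(10 * tol * max(abs(f1), 1.0), 1e-6)

    def test_too_few_presences_rejected(self, small_world):
        with pytest.raises(ValueError, match="5 presence"):
            le.fit_maxent(small_world["presences"].head(3), small_world["background"])


class TestPredict:
    def test_uniform_model_gives_uniform_raw(self, small_world):
        pres, bg = small_world["presences"], small_world["background"]
        model = le.fit_maxent(pres, bg, beta=1e6)  # penalty forces lambda = 0
        assert np.abs(model.lam).max() < 1e-10
        raw = le.predict_raw(model, small_world["stack"])
        np.testing.assert_allclose(raw.grid.valid_values(), 1.0 / len(bg), rtol=1e-10)

    def test_agrees_with_direct_gibbs_formula(self, fitted_model, small_world):
        model, raw = fitted_model["model"], fitted_model["raw"]
        stack = small_world["stack"]
        rows, cols = stack.valid_indices()
        tab = stack.table_at(rows, cols)
        F = model.expansion.transform(tab)
        expected = np.exp(F @ model.lam - model.log_z)
        np.testing.assert_allclose(raw.grid.values[rows, cols], expected, rtol=1e-12)

    def test_nodata_propagated(self, fitted_model, small_world):
        assert np.array_equal(fitted_model["raw"].grid.mask_nodata(),
                              small_world["stack"].mask_nodata())


class TestCumulative:
    def test_max_cell_reaches_one_and_rank_preserved(self, fitted_model):
        raw = fitted_model["raw"]
        cum = le.to_cumulative(raw)
        rv = raw.grid.valid_values()
        cv = cum.grid.valid_values()
        assert np.isclose(cv[np.argmax(rv)], 1.0)
        order = np.argsort(rv)
        assert (np.diff(cv[order]) >= -1e-12).all()
        assert ((cv >= 0) & (cv <= 1)).all()

    def test_uniform_raw_is_all_ties(self, small_world):
        model = le.fit_maxent(small_world["presences"], small_world["background"], beta=1e6)
        raw = le.predict_raw(model, small_world["stack"])
        cum = le.to_cumulative(raw)
        np.testing.assert_allclose(cum.grid.valid_values(), 1.0)

    def test_wrong_flavor_rejected(self, fitted_model):
        cum = le.to_cumulative(fitted_model["raw"])
        with pytest.raises(ValueError, match="raw"):
            le.to_cumulative(cum)


class TestLogistic:
    def test_uniform_model_maps_to_half(self, small_world):
        model = le.fit_maxent(small_world["presences"], small_world["background"], beta=1e6)
        raw = le.predict_raw(model, small_world["stack"])
        logi = le.to_logistic(raw)
        np.testing.assert_allclose(logi.grid.valid_values(), 0.5, rtol=1e-10)

    def test_strictly_increasing_in_raw_and_bounded(self, fitted_model):
        raw = fitted_model["raw"]
        logi = le.to_logistic(raw)
        rv, lv = raw.grid.valid_values(), logi.grid.valid_values()
        order = np.argsort(rv)
        d_r = np.diff(rv[order])
        d_l = np.diff(lv[order])
        assert (d_l[d_r > 0] > 0).all()
        assert ((lv > 0) & (lv < 1)).all()


class TestAUC:
    def test_all_ties_give_half(self):
        assert auc_score(np.ones(10), np.ones(20)) == 0.5

    def test_perfect_separation_gives_one(self):
        assert auc_score(np.arange(10, 20), np.arange(10)) == 1.0

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(8)
        pos = rng.choice([0.0, 0.5, 1.0, 2.0], 12)
        neg = rng.choice([0.0, 0.5, 1.0, 3.0], 18)
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert np.isclose(auc_score(pos, neg), wins / (12 * 18))

    def test_crossval_recovers_signal(self, small_world):
        ev = le.crossval_auc(small_world["presences"], small_world["background"],
                             k=5, seed=1)
        assert len(ev.fold_aucs) == 5
        assert ev.mean_auc > 0.75


class TestContributions:
    def test_informative_variable_ranks_first(self, small_world):
        contrib = le.variable_contributions(small_world["presences"],
                                            small_world["background"],
                                            n_runs=3, seed=2)
        assert abs(sum(contrib.values()) - 1.0) < 1e-12
        # the strong niche loads hardest on precipitation
        assert max(contrib, key=contrib.get) in ("precipitation", "temperature")

    def test_pure_noise_variable_contributes_little(self, small_world):
        rng = np.random.default_rng(3)
        pres = small_world["presences"].copy()
        bg = small_world["background"].copy()
        pres["noise"] = rng.normal(size=len(pres))
        bg["noise"] = rng.normal(size=len(bg))
        contrib = le.variable_contributions(pres, bg, n_runs=3, seed=4)
        assert contrib["noise"] < 0.1

    def test_single_covariate_gets_everything(self):
        rng = np.random.default_rng(5)
        bg = pd.DataFrame({"v": rng.normal(size=300)})
        pres = pd.DataFrame({"v": rng.normal(1.5, 0.5, size=40)})
        contrib = le.variable_contributions(pres, bg, n_runs=2, seed=6,
                                            categorical_var=None)
        assert contrib == {"v": 1.0}


class TestResponseCurve:
    def test_monotone_for_positive_linear_model(self):
        rng = np.random.default_rng(7)
        bg = pd.DataFrame({"v": rng.uniform(0, 10, 500)})
        pres = pd.DataFrame({"v": rng.uniform(7, 10, 50)})
        model = le.fit_maxent(pres, bg, beta=0.5, categorical_var=None)
        curve = le.response_curve(model, "v", n_steps=50)
        assert curve["value"].iloc[0] == bg["v"].min()
        assert curve["value"].iloc[-1] == bg["v"].max()
        assert (np.diff(curve["suitability"]) >= -1e-12).all()

    def test_unimodal_when_quadratic_negative(self, fitted_model):
        model = fitted_model["model"]
        lam = model.lam.copy()
        # force a pure concave response on the varied variable
        names = model.expansion.feature_names
        lam[:] = 0.0
        i_lin = names.index("precipitation:linear")
        i_quad = names.index("precipitation:quadratic")
        lam[i_lin], lam[i_quad] = 4.0, -4.0
        model2 = le.MaxentModel(model.expansion, lam, model.beta, model.log_z,
                                model.entropy, model.n_background, model.bg_raw_sorted)
        curve = le.response_curve(model2, "precipitation", n_steps=101)
        s = curve["suitability"].to_numpy()
        k = np.argmax(s)
        assert 0 < k < 100  # interior vertex: u = -lin/(2*quad) = 0.5
        assert abs(curve["value"].iloc[k] -
                   (model.expansion.mins["precipitation"] +
                    0.5 * (model.expansion.maxs["precipitation"] -
                           model.expansion.mins["precipitation"]))) < \
            0.02 * (model.expansion.maxs["precipitation"] - model.expansion.mins["precipitation"])

    def test_unknown_variable_rejected(self, fitted_model):
        with pytest.raises(ValueError, match="unknown variable"):
            le.response_curve(fitted_model["model"], "nope")


class TestThreshold:
    def test_zero_threshold_all_presence(self, fitted_model):
        cum = le.to_cumulative(fitted_model["raw"])
        b = le.apply_threshold(cum, 0.0)
        assert (b.valid_values() == 1).all()

    def test_cells_below_threshold_absent(self, fitted_model):
        cum = le.to_cumulative(fitted_model["raw"])
        b = le.apply_threshold(cum, 0.18)
        mask = ~cum.grid.mask_nodata()
        assert np.array_equal(b.values[mask] == 0, cum.grid.values[mask] < 0.18)

    def test_unit_threshold_keeps_only_max_tie_class(self, fitted_model):
        cum = le.to_cumulative(fitted_model["raw"])
        b = le.apply_threshold(cum, 1.0)
        cv = cum.grid.valid_values()
        assert (b.valid_values() == 1).sum() == np.isclose(cv, 1.0).sum()

    def test_out_of_range_threshold_rejected(self, fitted_model):
        cum = le.to_cumulative(fitted_model["raw"])
        with pytest.raises(ValueError, match="threshold"):
            le.apply_threshold(cum, 1.5)


def test_model_save_load_round_trip(tmp_path, fitted_model, small_world):
    model = fitted_model["model"]
    p = tmp_path / "model.json"
    model.save(p)
    loaded = le.MaxentModel.load(p)
    np.testing.assert_allclose(loaded.raw_scores(small_world["background"]),
                               model.raw_scores(small_world["background"]), rtol=1e-12)
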