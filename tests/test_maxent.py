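"""Maximum-entropy SDM: oracle equivalence, invariances, output contracts."""

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from palmx.scenarios import BASELINE, ScenarioKey
from palmx.sdm import fit_maxent, fit_gibbs, predict_suitability
from palmx.sdm.features import FeatureSpec
from palmx.sdm.maxent import gibbs_probabilities
from palmx.world import LAYER_NAMES, generate_climate, sample_occurrences


def oracle_gibbs(F, presence_idx, reg):
    """Direct numerical minimisation of the penalised likelihood,
    independent of the package's optimiser."""
    f_emp = F[presence_idx].mean(axis=0)

    def nll(lam):
        lam = np.atleast_1d(lam)
        eta = F @ lam
        return float(-f_emp @ lam + logsumexp(eta)
                     + reg * np.abs(lam).sum())

    p = F.shape[1]
    if p == 1:
        res = minimize_scalar(lambda l: nll([l]), bounds=(-60, 60),
                              method="bounded",
                              options={"xatol": 1e-12})
        lam = np.array([res.x])
    else:
        best = None
        for x0 in (np.zeros(p), np.ones(p), -np.ones(p)):
            r = minimize(nll, x0, method="Nelder-Mead",
                         options={"xatol": 1e-12, "fatol": 1e-14,
                                  "maxiter": 20000, "maxfev": 20000})
            if best is None or r.fun < best.fun:
                best = r
        lam = best.x
    eta = F @ lam
    return np.exp(eta - logsumexp(eta))


class TestGibbsOracle:
    def test_two_cell_single_presence_matches_1d_likelihood(self):
        # universe = {cell0 (background), cell1 (presence)}, one binary
        # feature; the regularised optimum is finite and the fitted Gibbs
        # distribution matches direct 1-D maximisation to 1e-6
        F = np.array([[0.0], [1.0]])
        lam, info = fit_gibbs(F, presence_idx=np.array([1]), regularization=0.1)
        q = np.exp(info["log_gibbs"])
        q_star = oracle_gibbs(F, np.array([1]), 0.1)
        np.testing.assert_allclose(q, q_star, atol=1e-6)
        # analytic optimum of the penalised problem: q(presence) = 1 - beta
        np.testing.assert_allclose(q[1], 0.9, atol=1e-6)

    @pytest.mark.parametrize("n_cells,n_feat", [(2, 1), (3, 1), (3, 2)])
    def test_small_toys_match_numerical_maximisation(self, n_cells, n_feat):
        rng = np.random.default_rng(123)
        for trial in range(8):
            F = rng.normal(size=(n_cells, n_feat))
            for presence in ([0], [n_cells - 1], [0, 1]):
                lam, info = fit_gibbs(F, np.array(presence),
                                      regularization=0.05)
                q = np.exp(info["log_gibbs"])
                q_star = oracle_gibbs(F, np.array(presence), 0.05)
                np.testing.assert_allclose(q, q_star, atol=1e-6)

    def test_gibbs_distribution_normalised(self):
        rng = np.random.default_rng(5)
        F = rng.normal(size=(40, 3))
        lam, info = fit_gibbs(F, np.arange(5), regularization=0.01)
        assert abs(np.exp(info["log_gibbs"]).sum() - 1.0) < 1e-9


class TestFitMaxent:
    def test_constant_features_give_uniform_gibbs(self):
        # zero-information limit: every feature constant across cells
        with pytest.warns(UserWarning, match="constant"):
            m = fit_maxent(np.full((3, 2), 5.0), np.full((7, 2), 5.0))
        q = gibbs_probabilities(m, np.full((10, 2), 5.0))
        np.testing.assert_allclose(q, 0.1, atol=1e-12)

    def test_duplicating_background_leaves_weights_unchanged(self):
        # the Gibbs objective only sees the empirical cell distribution, so
        # uniformly duplicating the universe cannot move the optimum
        rng = np.random.default_rng(77)
        pres = rng.normal(size=(20, 3)) + 0.5
        bg = rng.normal(size=(200, 3))
        bg_universe = np.vstack([bg, pres])
        m1 = fit_maxent(pres, bg_universe, regularization=0.01)
        m2 = fit_maxent(pres, np.vstack([bg_universe, bg_universe, pres]),
                        regularization=0.01)
        np.testing.assert_allclose(m1.lam, m2.lam, atol=1e-6)

    def test_requires_two_occurrences(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_maxent(np.ones((1, 2)), np.zeros((5, 2)))


class TestPrediction:
    def test_point_niche_peak_at_niche_center(self, small_world,
                                              small_baseline):
        # for a sharply concentrated species the predicted suitability
        # argmax coincides with the analytic niche optimum
        from palmx.world import SpeciesSpec, true_suitability
        X = small_baseline.matrix()
        mu = X[300]
        sp = SpeciesSpec("pk", "other", tuple(mu),
                         tuple(1e-3 * np.array([6, 5, 4, 400, 150, 40.0])))
        occ = sample_occurrences(sp, small_baseline, 30, seed=2)
        r, c = small_world.grid.cell_of_xy(occ.x.values, occ.y.values)
        m = fit_maxent(X[r * 24 + c], X)
        surf = predict_suitability(m, small_baseline)
        true_peak = np.argmax(true_suitability(sp, small_baseline))
        assert np.nanargmax(surf.values) == true_peak

    def test_suitability_in_unit_interval(self, small_world, small_baseline):
        sp = small_world.species[0]
        X = small_baseline.matrix()
        occ = sample_occurrences(sp, small_baseline, 60, seed=3)
        r, c = small_world.grid.cell_of_xy(occ.x.values, occ.y.values)
        m = fit_maxent(X[r * 24 + c], X)
        surf = predict_suitability(m, small_baseline)
        assert np.nanmin(surf.values) >= 0 and np.nanmax(surf.values) <= 1

    def test_all_nodata_climate_gives_all_nodata_surface(self, small_world,
                                                         small_baseline):
        from conftest import make_climate
        sp = small_world.species[0]
        X = small_baseline.matrix()
        occ = sample_occurrences(sp, small_baseline, 60, seed=3)
        r, c = small_world.grid.cell_of_xy(occ.x.values, occ.y.values)
        m = fit_maxent(X[r * 24 + c], X)
        nan_layers = [np.full(small_world.grid.shape, np.nan)] * 6
        surf = predict_suitability(m, make_climate(nan_layers,
                                                   grid=small_world.grid))
        assert np.isnan(surf.values).all()

    def test_linear_score_orders_suitability(self):
        # with linear-only features the logistic output is a monotone map of
        # the fitted linear score: cell orderings agree
        rng = np.random.default_rng(9)
        pres = rng.normal(size=(30, 2)) + 1.0
        bg = rng.normal(size=(300, 2))
        m = fit_maxent(pres, bg, feature_spec=FeatureSpec(quadratic=False))
        Xnew = rng.normal(size=(50, 2))
        F = m.transform.transform(Xnew)
        score = m.score(F)
        suit = 1.0 / (1.0 + np.exp(-(score + m.intercept)))
        assert (np.argsort(score) == np.argsort(suit)).all()

    def test_missing_predictor_layer_is_named(self, small_world,
                                              small_baseline):
        from palmx.world import ClimateLayerSet
        sp = small_world.species[0]
        X = small_baseline.matrix()
        occ = sample_occurrences(sp, small_baseline, 60, seed=3)
        r, c = small_world.grid.cell_of_xy(occ.x.values, occ.y.values)
        m = fit_maxent(X[r * 24 + c], X)
        layers = dict(small_baseline.layers)
        layers.pop("wb_2")
        broken = ClimateLayerSet(grid=small_world.grid,
                                 key=ScenarioKey(BASELINE), layers=layers)
        with pytest.raises(KeyError, match="wb_2"):
            predict_suitability(m, broken)


def test_persisted_model_predicts_bit_identically(tmp_path, small_world,
                                                  small_baseline):
    from palmx.sdm import load_model, save_model
    sp = small_world.species[1]
    X = small_baseline.matrix()
    occ = sample_occurrences(sp, small_baseline, 60, seed=4)
    r, c = small_world.grid.cell_of_xy(occ.x.values, occ.y.values)
    m = fit_maxent(X[r * 24 + c], X)
    save_model(m, tmp_path / "m.json")
    m2 = load_model(tmp_path / "m.json")
    a = predict_suitability(m, small_baseline).values
    b = predict_suitability(m2, small_baseline).values
    assert a.tobytes() == b.tobytes()
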