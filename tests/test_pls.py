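"""NIPALS PLS: decomposition, prediction, LOO cross-validation, factor choice."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from uvnitro.pls import (
    Q2_SIGNIFICANCE,
    PLSRegressor,
    cumulative_contribution,
    fit_pls,
    loo_cv,
    select_factors,
)
from uvnitro.reference import REFERENCE_Q2, REFERENCE_SELECTED_FACTORS
from uvnitro.spectra import Composition
from uvnitro.synth import simulate_dataset


def random_system(n=12, m=6, k=3, seed=42):
    r = np.random.default_rng(seed)
    return r.normal(size=(n, m)), r.normal(size=(n, k))


class TestFitPredict:
    def test_single_component_rank1_selfprediction(self, library):
        comps = [Composition(c, 0, 0) for c in (1.0, 5.0, 10.0, 20.0, 40.0)]
        sim = simulate_dataset(comps, lib=library, cdom=None, noise_sd=0.0, seed=0)
        X, y = sim.spectra.X, sim.spectra.Y[:, 0]
        model = fit_pls(X, y, h=1)
        assert np.abs(model.predict(X).ravel() - y).max() < 1e-10

    @pytest.mark.parametrize("mode", ["pls1", "pls2"])
    def test_full_rank_equals_ols(self, mode):
        X, Y = random_system()
        model = PLSRegressor(n_components=6, mode=mode).fit(X, Y)
        Xc = X - X.mean(0)
        B, *_ = np.linalg.lstsq(Xc, Y - Y.mean(0), rcond=None)
        ols = Xc @ B + Y.mean(0)
        np.testing.assert_allclose(model.predict(X), ols, atol=1e-8)

    def test_nipals_matches_sklearn(self):
        X, Y = random_system()
        for h in (1, 2, 4):
            mine = PLSRegressor(n_components=h).fit(X, Y).predict(X)
            sk = PLSRegression(n_components=h, scale=False, tol=1e-12).fit(X, Y)
            np.testing.assert_allclose(mine, sk.predict(X), atol=1e-5)
        # single-response NIPALS is non-iterative: agreement to machine precision
        y1 = Y[:, :1]
        for h in (1, 3, 5):
            mine = PLSRegressor(n_components=h).fit(X, y1).predict(X)
            sk = PLSRegression(n_components=h, scale=False).fit(X, y1)
            np.testing.assert_allclose(mine, sk.predict(X), atol=1e-10)

    def test_response_permutation_symmetry(self):
        X, Y = random_system()
        perm = [2, 0, 1]
        a = PLSRegressor(n_components=3).fit(X, Y)
        b = PLSRegressor(n_components=3).fit(X, Y[:, perm])
        np.testing.assert_allclose(a.coef_[:, perm], b.coef_, atol=1e-10)

    def test_predicting_the_mean_spectrum_returns_mean_response(self):
        X, Y = random_system()
        model = PLSRegressor(n_components=3).fit(X, Y)
        pred = model.predict(np.tile(X.mean(0), (4, 1)))
        np.testing.assert_allclose(pred, np.tile(Y.mean(0), (4, 1)), atol=1e-12)

    def test_wavelength_mismatch_names_window(self):
        X, Y = random_system()
        model = PLSRegressor(n_components=2, window=(215.0, 240.0)).fit(X, Y)
        with pytest.raises(ValueError, match="215.0-240.0"):
            model.predict(np.zeros((2, 4)))

    def test_h_exceeding_rank_reports_maximum(self):
        X, Y = random_system(n=5, m=10)
        with pytest.raises(ValueError, match="min\\(n-1, m\\) = 4"):
            PLSRegressor(n_components=5).fit(X, Y)

    def test_scores_mutually_orthogonal(self):
        X, Y = random_system(n=20, m=10)
        model = PLSRegressor(n_components=6).fit(X, Y)
        G = model.x_scores_.T @ model.x_scores_
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off < 1e-8 * np.diag(G).max()

    def test_json_roundtrip_preserves_predictions(self):
        X, Y = random_system()
        model = PLSRegressor(n_components=3, window=(215.0, 240.0)).fit(X, Y)
        back = PLSRegressor.from_json(model.to_json())
        np.testing.assert_allclose(back.predict(X), model.predict(X), atol=1e-14)
        assert back.window == (215.0, 240.0)


class TestLooCV:
    def test_explicit_loop_oracle(self):
        """LOO PRESS equals a brute-force per-fold refit, and for a single
        response also an sklearn-based fold loop."""
        X, Y = random_system(n=10, m=8, k=2, seed=1)
        h_max = 4
        cv = loo_cv(X, Y, h_max=h_max)
        press = np.zeros(h_max)
        for i in range(X.shape[0]):
            keep = np.arange(X.shape[0]) != i
            for h in range(1, h_max + 1):
                m = fit_pls(X[keep], Y[keep], h=h)
                press[h - 1] += float(np.sum((Y[i] - m.predict(X[i][None, :])) ** 2))
        np.testing.assert_allclose(cv.press, press, rtol=1e-10)

        y1 = Y[:, :1]
        cv1 = loo_cv(X, y1, h_max=h_max, mode="pls1")
        press_sk = np.zeros(h_max)
        for i in range(X.shape[0]):
            keep = np.arange(X.shape[0]) != i
            for h in range(1, h_max + 1):
                sk = PLSRegression(n_components=h, scale=False).fit(X[keep], y1[keep])
                press_sk[h - 1] += float(
                    np.sum((y1[i] - sk.predict(X[i][None, :])) ** 2)
                )
        np.testing.assert_allclose(cv1.press, press_sk, rtol=1e-9)

    def test_q2_identity_and_noiseless_rank3(self, library, design):
        cal, _ = design
        sim = simulate_dataset(cal, lib=library, cdom=None, noise_sd=0.0, seed=0)
        cv = loo_cv(sim.spectra.window(215, 240).X, sim.spectra.Y, h_max=4)
        assert cv.press[2] < 1e-10  # exact rank-3 system
        for h in range(2, 4):
            if np.isfinite(cv.q2[h - 1]):
                assert cv.q2[h - 1] == pytest.approx(
                    1 - cv.press[h - 1] / cv.ress[h - 2]
                )

    def test_pls1_returns_one_result_per_response(self):
        X, Y = random_system(n=10, m=8)
        cvs = loo_cv(X, Y, h_max=3, mode="pls1")
        assert len(cvs) == 3
        pooled = loo_cv(X, Y, h_max=3, mode="pls2")
        np.testing.assert_allclose(
            pooled.per_response_press.sum(axis=1), pooled.press, atol=1e-12
        )

    def test_h_max_clipped_with_warning(self):
        X, Y = random_system(n=6, m=8)
        with pytest.warns(UserWarning, match="clipped"):
            cv = loo_cv(X, Y, h_max=7)
        assert cv.press.size == 4  # n - 2


class TestSelectFactors:
    def test_published_sequences_give_four(self):
        for name, q2 in REFERENCE_Q2.items():
            assert select_factors(q2) == REFERENCE_SELECTED_FACTORS, name

    @pytest.mark.parametrize(
        "q2, expected",
        [
            ((0.5, 0.5, 0.5), 4),  # all significant up to h_max
            ((0.01, 0.01, 0.01), 1),  # never significant
            ((0.0975, 0.0974), 2),  # threshold is inclusive
            ((0.02, 0.48, 0.95, -1.3), 4),  # insignificant start tolerated
            ((0.5, 0.01, 0.9), 2),  # scan stops at first failure after a success
        ],
    )
    def test_boundary_behaviour(self, q2, expected):
        assert select_factors(np.array(q2)) == expected

    def test_threshold_constant(self):
        assert Q2_SIGNIFICANCE == pytest.approx(0.0975)


class TestCumulativeContribution:
    def test_full_rank_reaches_unity(self):
        X, Y = random_system()
        model = PLSRegressor(n_components=6).fit(X, Y)
        cc = cumulative_contribution(model)
        assert np.all(np.diff(cc) >= -1e-12)
        assert cc[-1] == pytest.approx(1.0, abs=1e-10)

    def test_rank_one_first_factor_explains_all(self):
        r = np.random.default_rng(0)
        t = r.normal(size=(10, 1))
        X = t @ r.normal(size=(1, 5))
        Y = t
        model = PLSRegressor(n_components=1).fit(X, Y)
        cc = cumulative_contribution(model)
        assert cc[0] == pytest.approx(1.0, abs=1e-10)

    def test_synthetic_reference_design_four_factors(self, library, design):
        cal, _ = design
        from uvnitro.synth import default_cdom_sampler

        sim = simulate_dataset(cal, lib=library, cdom=default_cdom_sampler, seed=3)
        model = fit_pls(sim.spectra.window(215, 240).X, sim.spectra.Y, h=4)
        cc = cumulative_contribution(model)
        assert cc[-1] >= 0.999
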