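import numpy as np
import pytest

from ramscreen.errors import (DegenerateInputError, RankError, UsageError,
                              ValidationError)
from ramscreen.pls import (PLSModel, cross_validate_grouped, fit_pls,
                           fit_plsda_cocaine, fit_plsr_cocaine, predict_pls)
from ramscreen.preprocess import PLSDA_CHAIN, PLSR_CHAIN, apply_chain_matrix
from ramscreen.synthetic import (NOISELESS_INSTRUMENT, generate_binary_panel)

from conftest import single_spectrum_set


def _random_regression(rng, n=30, p=5, noise=0.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + 3.0 + noise * rng.normal(size=n)
    return X, y


class TestNIPALS:
    def test_perfect_single_column(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        model = fit_pls(y[:, None], y, ncomp=1)
        np.testing.assert_allclose(predict_pls(model, y[:, None]), y,
                                   atol=1e-10)

    def test_hand_run_single_component(self):
        """One NIPALS iteration by hand: w ∝ Xᵀy = [2,0] → w=[1,0],
        t = y, q = 1, so the one-component fit is exact."""
        X = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        y = np.array([1.0, 0.0, -1.0, 0.0])
        model = fit_pls(X, y, ncomp=1)
        np.testing.assert_allclose(np.abs(model.x_weights[:, 0]), [1.0, 0.0],
                                   atol=1e-12)
        np.testing.assert_allclose(predict_pls(model, X), y, atol=1e-12)

    def test_full_rank_equals_ols_oracle(self, rng):
        """At full rank the PLS fit equals the normal-equations OLS fit."""
        X, y = _random_regression(rng, 30, 5)
        model = fit_pls(X, y, ncomp=5)
        Xd = np.column_stack([np.ones(30), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        ols_fit = Xd @ beta
        np.testing.assert_allclose(predict_pls(model, X), ols_fit, atol=1e-6)

    def test_component1_weight_collinear_with_xty(self, rng):
        X, y = _random_regression(rng, 25, 6, noise=0.5)
        model = fit_pls(X, y, ncomp=3)
        v = (X - X.mean(axis=0)).T @ (y - y.mean())
        v = v / np.linalg.norm(v)
        assert min(np.max(np.abs(model.x_weights[:, 0] - v)),
                   np.max(np.abs(model.x_weights[:, 0] + v))) < 1e-9

    def test_scores_orthogonal(self, rng):
        X, y = _random_regression(rng, 40, 8, noise=1.0)
        Xc = X - X.mean(axis=0)
        model = fit_pls(X, y, ncomp=4)
        # reconstruct training scores from weights/loadings
        T = np.zeros((40, 4))
        Xd = Xc.copy()
        for a in range(4):
            T[:, a] = Xd @ model.x_weights[:, a]
            Xd -= np.outer(T[:, a], model.x_loadings[:, a])
        g = T.T @ T
        off = g - np.diag(np.diag(g))
        assert np.max(np.abs(off)) <= 1e-8

    def test_regression_vector_matches_component_form(self, rng):
        """Prediction via accumulated components equals prediction via
        the collapsed regression vector."""
        X, y = _random_regression(rng, 20, 6, noise=0.3)
        model = fit_pls(X, y, ncomp=3)
        Xnew = rng.normal(size=(7, 6))
        # component-wise prediction
        Xd = Xnew - model.x_center
        yhat = np.full(7, model.y_center)
        for a in range(3):
            t = Xd @ model.x_weights[:, a]
            yhat += model.y_loadings[a] * t
            Xd -= np.outer(t, model.x_loadings[:, a])
        np.testing.assert_allclose(predict_pls(model, Xnew), yhat, atol=1e-9)

    def test_centering_invariance(self, rng):
        X, y = _random_regression(rng, 20, 4, noise=0.2)
        m1 = fit_pls(X, y, 2)
        m2 = fit_pls(X, y + 100.0, 2)
        np.testing.assert_allclose(predict_pls(m2, X),
                                   predict_pls(m1, X) + 100.0, atol=1e-8)

    def test_errors(self, rng):
        X, y = _random_regression(rng, 10, 3)
        with pytest.raises(RankError):
            fit_pls(X, y, ncomp=4)
        with pytest.raises(DegenerateInputError):
            fit_pls(X, np.ones(10), ncomp=1)
        model = fit_pls(X, y, 2)
        with pytest.raises(UsageError):
            predict_pls(model, rng.normal(size=(2, 5)))

    def test_predict_at_center_returns_mean(self, rng):
        X, y = _random_regression(rng, 15, 4, noise=0.1)
        model = fit_pls(X, y, 2)
        pred = predict_pls(model, model.x_center[None, :])
        assert pred[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_matches_sklearn_cross_check(self, rng):
        """Independent oracle: scikit-learn's PLSRegression (NIPALS,
        centering only) gives the same predictions."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _random_regression(rng, 30, 8, noise=0.7)
        for k in (1, 3, 5):
            ours = fit_pls(X, y, k)
            ref = sklearn.PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(predict_pls(ours, X),
                                       ref.predict(X).ravel(), atol=1e-8)

    def test_json_round_trip(self, rng):
        X, y = _random_regression(rng, 12, 4)
        model = fit_pls(X, y, 2, chain_id="plsda")
        back = PLSModel.from_json(model.to_json())
        np.testing.assert_array_equal(back.regression_vector,
                                      model.regression_vector)
        assert back.chain_id == "plsda"
        np.testing.assert_allclose(predict_pls(back, X),
                                   predict_pls(model, X), atol=0)


class TestGroupedCV:
    def test_groups_stay_together_and_cover(self, rng):
        X, y = _random_regression(rng, 60, 4, noise=0.5)
        groups = [f"g{i // 3}" for i in range(60)]  # 20 groups of 3
        cv = cross_validate_grouped(X, y, groups, nseg=10, max_ncomp=3,
                                    seed=1)
        assert set(cv.segment_assignment) == set(groups)
        segs = np.array(list(cv.segment_assignment.values()))
        counts = np.bincount(segs, minlength=10)
        assert counts.min() >= 1 and counts.max() - counts.min() <= 1
        assert cv.rmsep_cv.shape == (3,)
        assert np.all(cv.rmsep_cv >= 0)

    def test_noiseless_linear_data_recovered(self, rng):
        X, y = _random_regression(rng, 50, 4, noise=0.0)
        groups = [f"g{i // 2}" for i in range(50)]
        cv = cross_validate_grouped(X, y, groups, nseg=10, max_ncomp=4,
                                    seed=2)
        assert cv.rmsep_cv[-1] < 1e-6

    def test_too_many_segments_rejected(self, rng):
        X, y = _random_regression(rng, 20, 3)
        with pytest.raises(ValidationError):
            cross_validate_grouped(X, y, [f"g{i // 2}" for i in range(20)],
                                   nseg=11, max_ncomp=2)

    def test_seeded_reproducibility(self, rng):
        X, y = _random_regression(rng, 40, 5, noise=0.4)
        groups = [f"g{i // 4}" for i in range(40)]
        a = cross_validate_grouped(X, y, groups, nseg=5, max_ncomp=3, seed=9)
        b = cross_validate_grouped(X, y, groups, nseg=5, max_ncomp=3, seed=9)
        np.testing.assert_array_equal(a.rmsep_cv, b.rmsep_cv)
        assert a.segment_assignment == b.segment_assignment


class TestCocaineModels:
    def test_plsr_requires_spanning_labels(self, library, grid):
        sset = single_spectrum_set("lactose", library, grid)
        with pytest.raises((UsageError, DegenerateInputError)):
            fit_plsr_cocaine(sset)

    def test_plsda_requires_both_classes(self, library, grid):
        panel = generate_binary_panel(library=library, agents=("lactose",),
                                      levels=(50.0,), replicates=2,
                                      instrument=NOISELESS_INSTRUMENT,
                                      grid=grid, seed=2)
        cocaine_only = panel.subset(
            np.array([m.cocaine_wt_pct > 0 for m in panel.metas]))
        with pytest.raises(DegenerateInputError):
            fit_plsda_cocaine(cocaine_only)

    def test_class_encoding_covers_both_forms(self, noiseless_bundle):
        """Both salt forms are encoded as the cocaine class: the fitted
        PLS-DA training classes are 0 (non-cocaine) and 1 (any cocaine)."""
        metas = noiseless_bundle.trainset.metas
        forms = {m.cocaine_form for m in metas if m.cocaine_wt_pct > 0}
        assert forms == {"HCl", "base"}
        assert all((m.cocaine_wt_pct > 0) == (m.cocaine_form != "none")
                   for m in metas)

    def test_transparent_diluent_snv_saturation(self, library, grid):
        """For a weak scatterer (inositol) the regression features
        saturate: 60 and 90 wt% mixtures are nearly indistinguishable
        after full-spectrum SNV, which bounds achievable quantitation."""
        panel = generate_binary_panel(library=library, agents=("inositol",),
                                      levels=(10.0, 60.0, 90.0), replicates=1,
                                      instrument=NOISELESS_INSTRUMENT,
                                      grid=grid, seed=3)
        X = apply_chain_matrix(panel, PLSR_CHAIN)
        wt = np.array([m.cocaine_wt_pct for m in panel.metas])
        lo = X[wt == 10.0][0]
        mid = X[wt == 60.0][0]
        hi = X[wt == 90.0][0]
        # 60→90 moves the features far less than 10→60
        assert np.linalg.norm(hi - mid) < 0.1 * np.linalg.norm(mid - lo)

    def test_parameter_recovery_strong_scatter_diluents(self, library, grid):
        """Grouped CV on noiseless single-diluent panels recovers the
        cocaine mass fraction within 5 wt% RMSEP for diluents whose
        out-of-ROI bands preserve concentration dependence after SNV."""
        for agent in ("mannitol", "levamisole"):
            panel = generate_binary_panel(library=library, agents=(agent,),
                                          replicates=2,
                                          instrument=NOISELESS_INSTRUMENT,
                                          grid=grid, seed=3)
            X = apply_chain_matrix(panel, PLSR_CHAIN)
            y = np.array([m.cocaine_wt_pct for m in panel.metas])
            groups = np.array([m.sample_id for m in panel.metas])
            # manual grouped CV keeping per-row predictions
            cv = cross_validate_grouped(X, y, groups, nseg=10, max_ncomp=1,
                                        seed=0)
            seg = np.array([cv.segment_assignment[g] for g in groups])
            preds = np.full(len(y), np.nan)
            for s in range(10):
                held = seg == s
                model = fit_pls(X[~held], y[~held], 1)
                preds[held] = predict_pls(model, X[held])
            mix = (y > 0) & (y < 100)
            rmsep = float(np.sqrt(np.mean((preds[mix] - y[mix]) ** 2)))
            assert rmsep < 5.0, f"{agent}: RMSEP {rmsep:.2f}"
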