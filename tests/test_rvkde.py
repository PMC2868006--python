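"""Tests for the relaxed variable kernel density estimator and classifier."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import norm

from triadsig.rvkde import (
    ClassifierModel,
    decision_score,
    density_at,
    fit_classifier,
    fit_kde,
    grid_search,
    load_classifier,
    log_density_at,
    predict,
    save_classifier,
)

from helpers import naive_kde_density


class TestNeighborRadii:
    def test_nearest_neighbor_radii_by_hand(self):
        model = fit_kde(np.array([[0.0], [1.0], [3.0]]), ks=1)
        # R = (1, 1, 2); in 1-D with ks=1, V_1(R)/1 = 2R so sigma = 2R.
        np.testing.assert_allclose(model.bandwidths, [2.0, 2.0, 4.0])

    def test_ks_equal_n_minus_one_uses_farthest(self, rng):
        X = rng.normal(size=(8, 3))
        model = fit_kde(X, ks=7)
        D = cdist(X, X)
        np.testing.assert_allclose(
            model.bandwidths / model.bandwidths[0],
            (D.max(axis=1) / D.max(axis=1)[0]) ** 1,  # sigma proportional to R
            rtol=1e-12,
        )

    def test_grid_spacing_radii(self):
        xs, ys = np.meshgrid(np.arange(4.0), np.arange(4.0))
        X = np.c_[xs.ravel(), ys.ravel()]
        model = fit_kde(X, ks=1)
        # every grid point's nearest neighbour is one spacing away
        assert np.allclose(model.bandwidths, model.bandwidths[0])
        brute = np.sort(cdist(X, X), axis=1)[:, 1]
        assert np.allclose(brute, 1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="ks \\+ 1"):
            fit_kde(np.zeros((3, 2)), ks=3)

    def test_duplicate_points_get_floored_bandwidths(self):
        X = np.array([[0.0], [0.0], [1.0], [2.0]])
        with np.errstate(all="raise"):
            model = fit_kde(X, ks=1)
        assert (model.bandwidths > 0).all()


class TestDensity:
    def test_beta_scales_all_bandwidths_linearly(self, rng):
        X = rng.normal(size=(30, 4))
        m1 = fit_kde(X, beta=1.0, ks=3)
        m3 = fit_kde(X, beta=3.0, ks=3)
        np.testing.assert_allclose(m3.bandwidths, 3.0 * m1.bandwidths)

    def test_closed_form_normal_mixture(self):
        # two 1-D samples at 0 and 5 with ks=1: sigma_i = 2*R_i = 10 each
        model = fit_kde(np.array([[0.0], [5.0]]), ks=1)
        v = np.array([[1.7]])
        expected = 0.5 * (norm.pdf(1.7, 0, 10) + norm.pdf(1.7, 5, 10))
        np.testing.assert_allclose(density_at(model, v), [expected], rtol=1e-12)

    @pytest.mark.parametrize("m", [1, 2])
    def test_untruncated_estimator_integrates_to_one(self, m, rng):
        X = rng.normal(size=(12, m))
        model = fit_kde(X, ks=3)
        span = np.abs(X).max() + 8 * model.bandwidths.max()
        axis = np.linspace(-span, span, 801 if m == 1 else 301)
        if m == 1:
            f = density_at(model, axis[:, None])
            integral = np.trapezoid(f, axis)
        else:
            gx, gy = np.meshgrid(axis, axis)
            f = density_at(model, np.c_[gx.ravel(), gy.ravel()])
            integral = np.trapezoid(
                np.trapezoid(f.reshape(gx.shape), axis, axis=1), axis
            )
        assert abs(integral - 1.0) < 1e-3

    def test_matches_naive_double_loop(self, rng):
        X = rng.normal(size=(60, 3))
        model = fit_kde(X, ks=4)
        for v in rng.normal(size=(5, 3)):
            expected = naive_kde_density(X, model.bandwidths, v)
            np.testing.assert_allclose(density_at(model, v), expected,
                                       rtol=1e-10)

    def test_kt_truncation_error_monotone(self, rng):
        X = rng.normal(size=(40, 2))
        model = fit_kde(X, ks=3)
        v = rng.normal(size=(3, 2))
        full = density_at(model, v)  # kt = n
        errors = np.array(
            [np.abs(density_at(model, v, kt=kt) - full) for kt in range(1, 41)]
        )
        assert (np.diff(errors, axis=0) <= 1e-15).all()
        np.testing.assert_allclose(density_at(model, v, kt=40), full)

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_kde(rng.normal(size=(10, 3)), ks=2)
        with pytest.raises(ValueError, match="dimension"):
            density_at(model, np.zeros(4))


class TestClassifier:
    def _symmetric_model(self):
        pos = np.array([[-1.0], [-1.5]])
        neg = np.array([[1.0], [1.5]])
        return fit_classifier(pos, neg, ks=1, kt=4)

    def test_symmetric_boundary_at_midpoint(self):
        model = self._symmetric_model()
        score = decision_score(model, np.array([[0.0]]))
        np.testing.assert_allclose(score, [0.0], atol=1e-12)
        assert not predict(model, np.array([[0.0]]))[0]  # tie -> negative

    def test_points_near_own_class_classified(self):
        model = self._symmetric_model()
        assert predict(model, np.array([[-1.2]]))[0]
        assert not predict(model, np.array([[1.2]]))[0]

    def test_larger_class_prior_wins_with_identical_densities(self, rng):
        X = rng.normal(size=(10, 2))
        kde = fit_kde(X, ks=2)
        model = ClassifierModel(kde_pos=kde, kde_neg=kde, n_pos=10, n_neg=20,
                                alpha=1.0, kt=10)
        v = rng.normal(size=(6, 2))
        assert (decision_score(model, v) < 0).all()
        model_eq = ClassifierModel(kde_pos=kde, kde_neg=kde, n_pos=10,
                                   n_neg=10, alpha=1.0, kt=10)
        np.testing.assert_allclose(decision_score(model_eq, v), 0.0,
                                   atol=1e-12)

    def test_score_equals_brute_force_log_ratio(self, rng):
        pos = rng.normal(size=(25, 3))
        neg = rng.normal(loc=2.0, size=(30, 3))
        model = fit_classifier(pos, neg, ks=3, kt=55)
        for v in rng.normal(size=(4, 3)):
            fp = naive_kde_density(pos, model.kde_pos.bandwidths, v)
            fn = naive_kde_density(neg, model.kde_neg.bandwidths, v)
            expected = np.log(25 * fp) - np.log(30 * fn)
            np.testing.assert_allclose(decision_score(model, v), expected,
                                       rtol=1e-8)

    def test_separated_gaussian_clouds_accuracy(self):
        rng = np.random.default_rng(7)
        train_pos = rng.normal(loc=(-2.0, 0.0), size=(200, 2))
        train_neg = rng.normal(loc=(2.0, 0.0), size=(200, 2))
        test_pos = rng.normal(loc=(-2.0, 0.0), size=(200, 2))
        test_neg = rng.normal(loc=(2.0, 0.0), size=(200, 2))
        model = fit_classifier(train_pos, train_neg, ks=5, kt=50)
        X = np.vstack([test_pos, test_neg])
        y = np.r_[np.ones(200, bool), np.zeros(200, bool)]
        accuracy = np.mean(predict(model, X) == y)
        assert accuracy >= 0.95

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            fit_classifier(np.zeros((0, 2)), np.zeros((5, 2)))

    def test_degenerate_zero_likelihood_scores_zero_with_warning(self):
        pos = np.array([[0.0], [0.01]])
        neg = np.array([[0.02], [0.03]])
        model = fit_classifier(pos, neg, ks=1, kt=4)
        with pytest.warns(RuntimeWarning, match="zero likelihood"):
            score = decision_score(model, np.array([[1e200]]))
        assert score[0] == 0.0

    def test_round_trip_persistence(self, rng, tmp_path):
        pos = rng.normal(size=(20, 4))
        neg = rng.normal(loc=1.0, size=(25, 4))
        model = fit_classifier(pos, neg, alpha=0.8, beta=1.5, ks=3, kt=7)
        path = tmp_path / "model.npz"
        save_classifier(model, path)
        loaded = load_classifier(path)
        v = rng.normal(size=(5, 4))
        np.testing.assert_allclose(decision_score(loaded, v),
                                   decision_score(model, v))


class TestGridSearch:
    def _toy_data(self, rng, n=60):
        X = np.vstack([rng.normal(loc=-1.5, size=(n, 2)),
                       rng.normal(loc=1.5, size=(n, 2))])
        y = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        return X, y

    def test_single_combination_returned(self, rng):
        X, y = self._toy_data(rng)
        grid = {"alpha": [1.0], "beta": [2.0], "ks": [3], "kt": [10]}
        result = grid_search(X, y, grid, folds=3, seed=0)
        assert result.best_params == {"alpha": 1.0, "beta": 2.0, "ks": 3,
                                      "kt": 10}

    def test_duplicate_candidates_equivalent_to_deduplicated(self, rng):
        X, y = self._toy_data(rng)
        grid_a = {"alpha": [1.0], "beta": [1.0, 2.0], "ks": [3], "kt": [10]}
        grid_b = {"alpha": [1.0, 1.0], "beta": [2.0, 1.0, 1.0], "ks": [3, 3],
                  "kt": [10]}
        ra = grid_search(X, y, grid_a, folds=3, seed=5)
        rb = grid_search(X, y, grid_b, folds=3, seed=5)
        assert ra.best_params == rb.best_params
        assert ra.best_score == rb.best_score

    def test_best_mean_verified_exhaustively(self, rng):
        X, y = self._toy_data(rng)
        grid = {"alpha": [0.5, 1.0], "beta": [1.0, 2.0], "ks": [2, 4],
                "kt": [5, 20]}
        result = grid_search(X, y, grid, folds=3, seed=2)
        assert result.table.shape[0] == 16
        best_row = result.table["mean_f_measure"].max()
        assert result.best_score == best_row
        chosen = result.table.loc[
            (result.table[["alpha", "beta", "ks", "kt"]]
             == pd_series(result.best_params)).all(axis=1),
            "mean_f_measure",
        ]
        assert (chosen == best_row).all()

    def test_single_class_fold_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.r_[np.ones(1, bool), np.zeros(9, bool)]
        with pytest.raises(ValueError, match="single class|least populated"):
            grid_search(X, y, {"alpha": [1.0], "beta": [1.0], "ks": [1],
                               "kt": [2]}, folds=5, seed=0)


def pd_series(params):
    import pandas as pd

    return pd.Series(params)
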