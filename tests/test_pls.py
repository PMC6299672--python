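"""NIPALS PLS against linear-algebra oracles; metric arithmetic; PLS-DA."""

import numpy as np
import pytest

from nirsfq import ConfigurationError
from nirsfq.pls import (
    calibration_metrics,
    classification_metrics,
    fit_plsda,
    fit_plsr,
    loo_press_curve,
    null_model,
    one_hot,
    select_components,
    validation_metrics,
)


class TestFit:
    def test_rank_one_response_fits_exactly(self, rng):
        t = rng.normal(size=20)
        load = rng.normal(size=8)
        X = np.outer(t, load)
        y = 3.0 * t + 1.0
        model = fit_plsr(X, y, 1)
        rmse = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmse <= 1e-8

    def test_full_rank_equals_pseudoinverse_solution(self, rng):
        """At components = rank(X), PLS reproduces least squares exactly."""
        X = rng.normal(size=(10, 8))
        y = rng.normal(size=10)
        model = fit_plsr(X, y, 8)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        expected = y.mean() + Xc @ beta
        assert np.max(np.abs(model.predict(X) - expected)) <= 1e-8

    def test_matches_sklearn_nipals(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(15, 9))
        y = rng.normal(size=15)
        for k in (1, 3, 5):
            ours = fit_plsr(X, y, k).predict(X)
            ref = sklearn.PLSRegression(n_components=k, scale=False).fit(X, y)
            theirs = ref.predict(X).ravel()
            assert np.max(np.abs(ours - theirs)) <= 1e-8

    def test_coefficients_reproduce_predictions(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        model = fit_plsr(X, y, 4)
        manual = model.y_mean[0] + (X - model.x_mean) @ model.coefficients()[:, 0]
        assert np.allclose(model.predict(X), manual, atol=1e-10)

    def test_rmsec_non_increasing_in_components(self, rng):
        X = rng.normal(size=(15, 10))
        y = rng.normal(size=15)
        rmses = []
        for k in range(1, 8):
            model = fit_plsr(X, y, k)
            rmses.append(np.sqrt(np.mean((model.predict(X) - y) ** 2)))
        assert np.all(np.diff(rmses) <= 1e-10)

    def test_prediction_invariant_to_column_shifts(self, rng):
        X = rng.normal(size=(14, 7))
        y = rng.normal(size=14)
        shift = rng.normal(size=7) * 10
        a = fit_plsr(X, y, 3).predict(X[:4])
        b = fit_plsr(X + shift, y, 3).predict(X[:4] + shift)
        assert np.allclose(a, b, atol=1e-8)

    def test_explained_x_variance_cumulative_bounded(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        model = fit_plsr(X, y, 5)
        cum = model.cumulative_x_variance
        assert np.all(np.diff(cum) >= -1e-12)
        assert cum[-1] <= 1.0 + 1e-9

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ConfigurationError, match="constant response"):
            fit_plsr(rng.normal(size=(8, 4)), np.ones(8), 2)

    def test_component_bounds_enforced(self, rng):
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        with pytest.raises(ConfigurationError):
            fit_plsr(X, y, 0)
        with pytest.raises(ConfigurationError):
            fit_plsr(X, y, 6)

    def test_null_model_predicts_mean(self):
        nm = null_model([1.0, 2.0, 6.0])
        assert np.allclose(nm.predict(np.zeros((4, 3))), 3.0)


class TestComponentSelection:
    def test_noiseless_rank_one_chooses_one(self, rng):
        t = rng.normal(size=25)
        X = np.outer(t, rng.normal(size=6)) + rng.normal(scale=1e-10, size=(25, 6))
        y = 2.0 * t
        k, curve = select_components(X, y, 5)
        assert k == 1
        assert curve[0] <= 1e-6

    def test_three_factor_data_modal_choice_is_three(self):
        """Low-noise 3-latent-factor data: LOO picks 3 components most often."""
        picks = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            T = rng.normal(size=(30, 3))
            P = rng.normal(size=(3, 15))
            X = T @ P + rng.normal(scale=0.01, size=(30, 15))
            y = T @ np.array([1.0, -2.0, 0.5]) + rng.normal(scale=0.01, size=30)
            k, _ = select_components(X, y, 8)
            picks.append(k)
        values, counts = np.unique(picks, return_counts=True)
        assert values[np.argmax(counts)] == 3

    def test_loo_curve_matches_explicit_loop(self, rng):
        X = rng.normal(size=(9, 5))
        y = rng.normal(size=9)
        kmax = 4
        press = np.zeros(kmax)
        for i in range(9):
            keep = np.arange(9) != i
            for k in range(1, kmax + 1):
                m = fit_plsr(X[keep], y[keep], k)
                press[k - 1] += (m.predict(X[i:i + 1])[0] - y[i]) ** 2
        assert np.allclose(loo_press_curve(X, y, kmax), press, atol=1e-10)


class TestRegressionMetrics:
    def test_perfect_fit_calibration(self, rng):
        t = rng.normal(size=12)
        X = np.outer(t, rng.normal(size=5))
        y = 2.0 * t
        model = fit_plsr(X, y, 1)
        rep = calibration_metrics(model, X, y)
        assert rep.rmsec == pytest.approx(0.0, abs=1e-9)
        assert rep.r2c == pytest.approx(1.0, abs=1e-9)

    def test_explicit_formula_oracle_six_points(self, rng):
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        model = fit_plsr(X, y, 2)
        k, curve = select_components(X, y, 2)
        rep = calibration_metrics(model, X, y, curve)
        pred = model.predict(X)
        assert rep.rmsec == pytest.approx(
            np.sqrt(np.sum((pred - y) ** 2) / 6), abs=1e-10)
        assert rep.r2c == pytest.approx(
            1 - np.sum((pred - y) ** 2) / np.sum((y - y.mean()) ** 2), abs=1e-10)
        # RMSECV read off the LOO curve at the model's component count
        assert rep.rmsecv == pytest.approx(curve[1], abs=1e-12)
        assert rep.r2cv == pytest.approx(
            1 - 6 * rep.rmsecv**2 / np.sum((y - y.mean()) ** 2), abs=1e-10)

    def test_r2cv_may_be_negative(self, rng):
        # pure-noise response: LOO predictions are worse than the mean
        X = rng.normal(size=(10, 8))
        y = rng.normal(size=10)
        model = fit_plsr(X, y, 3)
        rep = calibration_metrics(model, X, y)
        assert np.isfinite(rep.r2cv)  # reported as-is, sign unconstrained

    def test_hand_arithmetic_biased_prediction(self):
        """ref 1..5, pred = ref+1: RMSEP 1, R2v 1, RPD 1.5811, RER 4."""
        ref = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rep = validation_metrics(ref + 1.0, ref)
        assert rep.rmsep == pytest.approx(1.0, abs=1e-12)
        assert rep.r2v == pytest.approx(1.0, abs=1e-12)
        assert rep.rpd == pytest.approx(np.sqrt(2.5), abs=1e-12)
        assert rep.rpd == pytest.approx(1.5811, abs=1e-4)
        assert rep.rer == pytest.approx(4.0, abs=1e-12)
        assert not rep.excellent

    def test_perfect_prediction_flags_infinite_ratios(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        rep = validation_metrics(ref.copy(), ref)
        assert rep.perfect_fit
        assert np.isinf(rep.rpd) and np.isinf(rep.rer)

    def test_excellence_rule(self):
        ref = np.linspace(0, 30, 16)
        rep = validation_metrics(ref + np.resize([0.1, -0.1], 16), ref)
        assert rep.rpd > 3 and rep.rer > 15 and rep.excellent

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ConfigurationError, match="zero-variance"):
            validation_metrics(np.array([1.0, 2.0, 3.0]), np.full(3, 2.0))


class TestPLSDA:
    @staticmethod
    def two_clusters(rng, n_per=12, gap=8.0):
        a = rng.normal(size=(n_per, 6)) + np.r_[gap, np.zeros(5)]
        b = rng.normal(size=(n_per, 6))
        X = np.vstack([a, b])
        labels = ["A"] * n_per + ["B"] * n_per
        return X, labels

    def test_separable_clusters_fully_correct(self, rng):
        X, labels = self.two_clusters(rng)
        tr = np.r_[0:8, 12:20]
        te = np.r_[8:12, 20:24]
        model = fit_plsda(X[tr], [labels[i] for i in tr], 2)
        rep = classification_metrics(model, X[tr], [labels[i] for i in tr],
                                     X[te], [labels[i] for i in te])
        assert rep.calibration_correct == 100.0
        assert rep.validation_correct == 100.0
        assert rep.r2 > 0.5 and rep.q2 > 0.5

    def test_single_class_rejected(self, rng):
        with pytest.raises(ConfigurationError, match="2 classes"):
            fit_plsda(rng.normal(size=(6, 4)), ["A"] * 6, 2)

    def test_unseen_validation_class_counted_as_error(self, rng):
        X, labels = self.two_clusters(rng)
        model = fit_plsda(X, labels, 2)
        X_val = rng.normal(size=(4, 6))
        with pytest.warns(RuntimeWarning, match="absent from calibration"):
            rep = classification_metrics(model, X, labels, X_val, ["C"] * 4)
        assert rep.validation_correct == 0.0
        assert rep.confusion.loc["C"].sum() == 4

    def test_metrics_match_explicit_press_oracle(self, rng):
        X, labels = self.two_clusters(rng, n_per=6, gap=3.0)
        tr, te = np.r_[0:4, 6:10], np.r_[4:6, 10:12]
        model = fit_plsda(X[tr], [labels[i] for i in tr], 2)
        rep = classification_metrics(model, X[tr], [labels[i] for i in tr],
                                     X[te], [labels[i] for i in te])
        Y_tr = one_hot([labels[i] for i in tr], model.classes)
        Y_te = one_hot([labels[i] for i in te], model.classes)
        fitted = model.predict_indicators(X[tr])
        pred = model.predict_indicators(X[te])
        ybar = Y_tr.mean(axis=0)
        r2 = 1 - np.sum((fitted - Y_tr) ** 2) / np.sum((Y_tr - ybar) ** 2)
        q2 = 1 - np.sum((pred - Y_te) ** 2) / np.sum((Y_te - ybar) ** 2)
        assert rep.r2 == pytest.approx(r2, abs=1e-10)
        assert rep.q2 == pytest.approx(q2, abs=1e-10)

    def test_random_labels_classify_at_chance(self):
        """Permuted labels: validation correct rate near 100/#classes."""
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 10))
            labels = list(rng.permutation(["A"] * 20 + ["B"] * 20))
            tr, te = np.arange(0, 24), np.arange(24, 40)
            model = fit_plsda(X[tr], [labels[i] for i in tr], 3)
            rep = classification_metrics(model, X[tr], [labels[i] for i in tr],
                                         X[te], [labels[i] for i in te])
            rates.append(rep.validation_correct)
        assert 35.0 < np.mean(rates) < 65.0

    def test_argmax_tie_goes_to_earlier_grade(self, rng):
        X, labels = self.two_clusters(rng)
        model = fit_plsda(X, labels, 2)
        assert model.classes == ("A", "B")
        # indicator rows need not sum to 1, but argmax is still total
        preds = model.predict_class(X)
        assert set(preds) <= {"A", "B"}
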