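"""Logistic cost/gradient, L1 fitting, cross-validation, MCC, odds-ratio
weights, shuffle controls, and the two-stage choice model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whiskloc.classifier import (ClassifierModel, ConfusionMatrix,
                                 cost_and_gradient, cross_validate, fit,
                                 fit_two_stage, labels_from, mcc,
                                 normalized_odds_weights, shuffle_control,
                                 sigmoid, stratified_folds, two_stage_predict)
from whiskloc.session import LICK, NO_LICK


def random_instance(rng, m=60, p=3, beta=None):
    X = np.column_stack([np.ones(m), rng.normal(size=(m, p))])
    if beta is None:
        beta = rng.normal(size=p + 1)
    y = (rng.random(m) < sigmoid(X @ beta)).astype(float)
    return X, y


def table_from(X, y, names=None):
    names = names or [f"f{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df["choice"] = np.where(y == 1, LICK, NO_LICK)
    return df, names


class TestSigmoid:
    def test_zero_is_half(self):
        assert sigmoid(0.0) == 0.5

    def test_symmetry(self):
        z = np.linspace(-30, 30, 13)
        np.testing.assert_allclose(sigmoid(z) + sigmoid(-z), 1.0, atol=1e-12)

    def test_saturation_without_overflow(self):
        assert sigmoid(50.0) == pytest.approx(1.0, abs=1e-15)
        assert sigmoid(-50.0) == pytest.approx(0.0, abs=1e-15)
        assert np.isfinite(sigmoid(np.array([-1000.0, 1000.0]))).all()


class TestCostGradient:
    def test_zero_theta_cost_is_ln2(self):
        rng = np.random.default_rng(0)
        for frac in (0.5, 0.2, 0.9):
            X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
            y = (rng.random(40) < frac).astype(float)
            J, _ = cost_and_gradient(np.zeros(3), X, y, 0.0)
            assert J == pytest.approx(np.log(2))

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(7)
        for lam in (0.0, 0.05):
            X, y = random_instance(rng, m=50, p=4)
            theta = rng.normal(size=5) + 0.2  # away from theta=0 kinks
            J, g = cost_and_gradient(theta, X, y, lam)
            eps = 1e-6
            for j in range(5):
                tp, tm = theta.copy(), theta.copy()
                tp[j] += eps
                tm[j] -= eps
                num = (cost_and_gradient(tp, X, y, lam)[0]
                       - cost_and_gradient(tm, X, y, lam)[0]) / (2 * eps)
                assert g[j] == pytest.approx(num, abs=1e-6)

    def test_perfect_separation_cost_vanishes(self):
        X = np.column_stack([np.ones(20), np.r_[np.full(10, -3.0), np.full(10, 3.0)]])
        y = np.r_[np.zeros(10), np.ones(10)]
        J, _ = cost_and_gradient(np.array([0.0, 50.0]), X, y, 0.0)
        assert J < 1e-10


class TestFit:
    def test_separable_data_reaches_perfect_training_mcc(self):
        X = np.column_stack([np.ones(30),
                             np.r_[np.linspace(-3, -1, 15), np.linspace(1, 3, 15)]])
        y = np.r_[np.zeros(15), np.ones(15)]
        model = fit(X, y, 0.0, max_iter=5000)
        pred = (sigmoid(X @ model.theta) >= 0.5).astype(int)
        assert mcc(ConfusionMatrix.from_predictions(y, pred)) == 1.0

    def test_l1_path_shrinks_coefficients(self):
        rng = np.random.default_rng(3)
        X, y = random_instance(rng, m=120, p=4)
        grid = np.logspace(-4, 1, 20)
        norms = []
        theta = None
        for lam in grid:
            model = fit(X, y, lam, theta0=theta, max_iter=3000, tol=1e-12)
            theta = model.theta
            norms.append(np.sum(np.abs(theta[1:])))
        assert np.all(np.diff(norms) <= 1e-6)
        # strong regularization drives penalized coefficients to exact zero
        assert norms[-1] == 0.0

    def test_matches_reference_solver_unregularized(self):
        """At lambda=0 the fit agrees with an independent logistic solver."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(11)
        X, y = random_instance(rng, m=250, p=4,
                               beta=np.array([0.3, 1.0, -1.5, 0.5, 0.0]))
        model = fit(X, y, 0.0, max_iter=50000, tol=1e-15)
        ref = sklearn.LogisticRegression(C=np.inf, tol=1e-12,
                                         max_iter=10000).fit(X[:, 1:], y)
        p_ref = ref.predict_proba(X[:, 1:])[:, 1]
        p_fit = sigmoid(X @ model.theta)
        assert np.max(np.abs(p_fit - p_ref)) < 1e-4

    def test_nonconvergence_is_flagged(self):
        rng = np.random.default_rng(5)
        X, y = random_instance(rng, m=200, p=5)
        with pytest.warns(UserWarning, match="did not converge"):
            model = fit(X, y, 0.0, max_iter=3, tol=1e-16)
        assert not model.converged


class TestStratifiedCV:
    def test_folds_preserve_class_ratio(self):
        y = np.r_[np.zeros(60), np.ones(40)]
        folds = stratified_folds(y, 5, np.random.default_rng(0))
        for test_idx in folds:
            assert np.sum(y[test_idx] == 0) == 12
            assert np.sum(y[test_idx] == 1) == 8

    def test_small_class_raises_with_counts(self):
        y = np.r_[np.zeros(20), np.ones(3)]
        with pytest.raises(ValueError, match="fewer members"):
            stratified_folds(y, 5, np.random.default_rng(0))

    def test_null_data_scores_near_zero(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(120, 3))
        y = (rng.random(120) < 0.5).astype(float)
        df, names = table_from(X, y)
        res = cross_validate(df, names[:2], "choice", iterations=5,
                             rng=np.random.default_rng(1))
        assert abs(res.mean_mcc) < max(3 * res.sem_mcc, 0.15)

    def test_duplicated_rows_leave_selection_stable(self):
        rng = np.random.default_rng(31)
        X, y = random_instance(rng, m=100, p=2,
                               beta=np.array([0.0, 1.5, -1.0]))
        df, names = table_from(X[:, 1:], y, names=["a", "b"])
        doubled = pd.concat([df, df], ignore_index=True)
        r1 = cross_validate(df, ["a", "b"], "choice", iterations=5,
                            rng=np.random.default_rng(2))
        r2 = cross_validate(doubled, ["a", "b"], "choice", iterations=5,
                            rng=np.random.default_rng(2))
        assert abs(r1.mean_mcc - r2.mean_mcc) < 0.1
        ratio = r2.chosen_lambda / r1.chosen_lambda
        assert 1.0 / 4.0 < ratio < 4.0

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 2.0, 0.5, 1.1, 0.2] * 5,
                           "choice": [LICK, NO_LICK] * 15})
        with pytest.raises(ValueError, match="missing"):
            cross_validate(df, ["a"], "choice", iterations=1)


class TestMCC:
    def test_perfect_prediction(self):
        assert mcc(ConfusionMatrix(TP=50, TN=50, FP=0, FN=0)) == 1.0

    def test_fully_inverted_prediction(self):
        assert mcc(ConfusionMatrix(TP=0, TN=0, FP=50, FN=50)) == -1.0

    def test_hand_evaluated_formula(self):
        # (40*30 - 20*10) / sqrt(60*50*50*40)
        expected = 1000.0 / np.sqrt(6_000_000.0)
        assert mcc(ConfusionMatrix(TP=40, TN=30, FP=20, FN=10)) == \
            pytest.approx(expected)

    def test_degenerate_matrix_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert mcc(ConfusionMatrix(TP=10, TN=0, FP=0, FN=0)) == 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_label_swap_symmetry(self, tp, tn, fp, fn):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = mcc(ConfusionMatrix(tp, tn, fp, fn))
            b = mcc(ConfusionMatrix(tn, tp, fn, fp))
        assert a == pytest.approx(b)

    def test_balanced_accuracy_mcc_consistency(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        cm = ConfusionMatrix.from_predictions(y, y)
        assert mcc(cm) == 1.0 and (cm.TP + cm.TN) == cm.total


class TestOddsWeights:
    def test_direct_evaluation(self):
        theta = np.array([0.7, 2.0, -1.0, 0.0])  # intercept + 3 predictors
        w = normalized_odds_weights([theta])
        e = np.exp(np.abs(theta[1:]))
        mag = (e - e.min()) / (e.max() - e.min())
        np.testing.assert_allclose(w, mag * np.sign(theta[1:]))
        assert abs(w[0]) > abs(w[1]) > abs(w[2])

    def test_zero_coefficient_averages_to_zero(self):
        folds = [np.array([0.1, 1.0, 0.0, -2.0]),
                 np.array([-0.3, 2.0, 0.0, -1.0])]
        w = normalized_odds_weights(folds)
        assert w[1] == 0.0

    def test_single_predictor_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            w = normalized_odds_weights([np.array([0.2, -3.0])])
        np.testing.assert_allclose(w, [-1.0])

    def test_equal_coefficients_share_weight(self):
        w = normalized_odds_weights([np.array([0.0, 1.5, 1.5, 1.5])])
        np.testing.assert_allclose(w, [1.0, 1.0, 1.0])


class TestShuffleControl:
    def _informative_table(self, n=80):
        rng = np.random.default_rng(13)
        x = np.r_[rng.normal(-1.2, 1, n // 2), rng.normal(1.2, 1, n // 2)]
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        return table_from(x[:, None], y, names=["a"])[0]

    def test_informative_feature_beats_null(self):
        df = self._informative_table()
        res = shuffle_control(df, ["a"], "choice", n_shuffles=5,
                              rng=np.random.default_rng(3), iterations=2)
        assert res.real.mean_mcc > res.percentile_95
        assert res.pvalue < 0.05

    def test_pure_noise_feature_within_null(self):
        rng = np.random.default_rng(17)
        df, _ = table_from(rng.normal(size=(60, 1)),
                           (rng.random(60) < 0.5).astype(float), names=["a"])
        res = shuffle_control(df, ["a"], "choice", n_shuffles=6,
                              rng=np.random.default_rng(4), iterations=2)
        lo, hi = np.percentile(res.null_mcc, [1, 99])
        assert lo - 0.3 < res.real.mean_mcc < hi + 0.3

    def test_deterministic_under_fixed_seed(self):
        df = self._informative_table(40)
        r1 = shuffle_control(df, ["a"], "choice", n_shuffles=3,
                             rng=np.random.default_rng(5), iterations=2)
        r2 = shuffle_control(df, ["a"], "choice", n_shuffles=3,
                             rng=np.random.default_rng(5), iterations=2)
        np.testing.assert_array_equal(r1.null_mcc, r2.null_mcc)

    def test_too_few_shuffles_raises(self):
        df = self._informative_table(40)
        with pytest.raises(ValueError, match="n_shuffles"):
            shuffle_control(df, ["a"], "choice", n_shuffles=1,
                            rng=np.random.default_rng(0))


def constant_model(names, theta):
    stats = {n: (0.0, 0.0, 1.0) for n in names}
    return ClassifierModel(theta=np.asarray(theta, dtype=float), lam=0.0,
                           predictor_names=list(names),
                           normalization_stats=stats)


class TestTwoStage:
    def test_zero_touch_trials_always_no_lick(self):
        # even a lick-biased count model cannot flip touchless trials
        count_model = constant_model(["touch_count"], [5.0, 0.1])
        touch_model = constant_model(["protraction_midpoint", "touch_count"],
                                     [5.0, 1.0, 1.0])
        df = pd.DataFrame({
            "touch_count": [0.0, 0.0, 3.0, 0.0],
            "protraction_midpoint": [np.nan, np.nan, 10.0, np.nan],
        })
        pred = two_stage_predict(df, count_model, touch_model)
        assert list(pred[df["touch_count"] == 0]) == [0, 0, 0]

    def test_all_touch_table_equals_touch_model(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame({
            "touch_count": rng.integers(1, 8, 30).astype(float),
            "protraction_midpoint": rng.normal(10, 5, 30),
        })
        count_model = constant_model(["touch_count"], [-1.0, 2.0])
        touch_model = constant_model(["protraction_midpoint", "touch_count"],
                                     [-0.5, -1.0, 2.0])
        pred = two_stage_predict(df, count_model, touch_model)
        np.testing.assert_array_equal(pred, touch_model.predict(df))

    def test_retraction_only_trials_fall_back_to_count_stage(self):
        count_model = constant_model(["touch_count"], [-3.0, 1.0])
        touch_model = constant_model(["protraction_midpoint", "touch_count"],
                                     [0.0, -1.0, 1.0])
        df = pd.DataFrame({
            "touch_count": [5.0, 5.0],
            "protraction_midpoint": [np.nan, 10.0],
        })
        pred = two_stage_predict(df, count_model, touch_model)
        assert pred[0] == count_model.predict(df.iloc[[0]])[0]

    def test_two_stage_tracks_bayes_ceiling(self):
        """On simulated sessions the fitted two-stage model approaches the
        MCC of the Bayes-optimal rule built from the generative
        probabilities."""
        from whiskloc.config import SessionConfig
        from whiskloc.synth import generate_session
        from whiskloc.features import build_feature_table
        for seed in (21, 22, 23):
            session = generate_session(SessionConfig(n_trials=300, rng_seed=seed))
            table = build_feature_table(session)
            y = labels_from(table, "choice")
            _, _, pred = fit_two_stage(table, "protraction_midpoint", "choice",
                                       rng=np.random.default_rng(seed),
                                       iterations=5)
            m_model = mcc(ConfusionMatrix.from_predictions(y, pred))
            p_true = np.array([t.latent["lick_probability"]
                               for t in session.trials])
            bayes = (p_true >= 0.5).astype(int)
            m_bayes = mcc(ConfusionMatrix.from_predictions(y, bayes))
            assert abs(m_model - m_bayes) <= 0.05
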