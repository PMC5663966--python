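import numpy as np
import pytest
from scipy.stats import norm

from itibias.decoding import (
    StepwiseLinearDecoder,
    StepwiseLogisticDecoder,
    bias_conditioned_psychometric,
    boundary_distance,
    fit_bias_regression,
    fit_classifier,
    independent_history_info,
    stepwise_select,
)


class TestStepwiseSelection:
    def test_informative_feature_found(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = r.normal(size=200)
            X = r.normal(size=(200, 10))
            X[:, 4] = y + r.normal(0, 0.1, 200)
            sel = stepwise_select(X, y)
            hits += (4 in sel and len(sel) <= 3)
        assert hits >= 17

    def test_null_selection_rate_near_p_enter(self):
        per_feature = []
        for seed in range(150):
            r = np.random.default_rng(seed)
            y = r.normal(size=100)
            X = r.normal(size=(100, 5))
            per_feature.append(len(stepwise_select(X, y)) / 5)
        # forward entry picks the best of 5 candidates, so the per-feature
        # spurious rate sits near (not exactly at) p_enter
        assert 0.01 < np.mean(per_feature) < 0.12

    def test_zero_features_empty(self):
        sel = stepwise_select(np.empty((50, 0)), np.random.default_rng(0).normal(size=50))
        assert len(sel) == 0


class TestBiasRegression:
    @staticmethod
    def _population(n=300, n_tuned=8, n_noise=8, noise=0.2, seed=0):
        r = np.random.default_rng(seed)
        bias = r.normal(0, 1, n)
        gains = r.uniform(0.5, 1.5, n_tuned) * r.choice([-1, 1], n_tuned)
        X = np.column_stack(
            [g * bias + r.normal(0, noise, n) for g in gains]
            + [r.normal(0, 1, n) for _ in range(n_noise)])
        return X, bias

    def test_tuned_population_high_r2(self):
        X, bias = self._population()
        res = fit_bias_regression(X, bias)
        assert res.cv_value > 0.8

    def test_shuffled_bias_no_fit(self):
        X, bias = self._population(seed=1)
        res = fit_bias_regression(X, np.random.default_rng(2).permutation(bias))
        assert res.cv_value <= 0.05

    def test_single_choice_trials_still_fit(self):
        # continuous bias is decodable even within one categorical choice
        X, bias = self._population(seed=3)
        one_sided = bias > 0
        res = fit_bias_regression(X[one_sided], bias[one_sided])
        assert res.cv_value > 0.5

    def test_empty_selection_flagged_r2_zero(self):
        r = np.random.default_rng(4)
        res = fit_bias_regression(r.normal(size=(100, 3)), r.normal(size=100))
        if "empty feature selection" in res.flags:
            assert res.cv_value == 0.0

    def test_strict_mode_runs(self):
        X, bias = self._population(seed=5, n=200)
        res = fit_bias_regression(X, bias, mode="strict")
        assert res.cv_value > 0.7


class TestClassifier:
    def test_separable_population(self):
        r = np.random.default_rng(0)
        y = r.choice([-1.0, 1.0], 200)
        X = np.column_stack([y * 2, r.normal(size=200)])
        res = fit_classifier(X, y)
        assert res.cv_value > 0.99

    def test_shuffled_labels_chance(self):
        r = np.random.default_rng(1)
        y = r.choice([-1.0, 1.0], 400)
        X = r.normal(size=(400, 6))
        res = fit_classifier(X, y)
        assert res.cv_value == pytest.approx(0.5, abs=0.1)

    def test_graded_overlap_matches_ideal_observer(self):
        # 1-D Gaussian classes at d' = 1: ideal accuracy Phi(1/2) ~ 0.691
        accs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = r.choice([-1.0, 1.0], 600)
            X = (y / 2 + r.normal(0, 1, 600))[:, None]
            accs.append(fit_classifier(X, y).cv_value)
        ideal = norm.cdf(0.5)
        assert np.mean(accs) == pytest.approx(ideal, abs=0.05)
        assert 0.6 <= np.mean(accs) <= 0.8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_classifier(np.random.default_rng(0).normal(size=(50, 2)), np.ones(50))


class TestBoundaryDistance:
    @staticmethod
    def _clf():
        r = np.random.default_rng(3)
        y = r.choice([-1.0, 1.0], 200)
        X = np.column_stack([y + r.normal(0, 0.5, 200), r.normal(size=200)])
        return X, StepwiseLogisticDecoder().fit(X, y)

    def test_point_on_boundary_is_zero(self):
        X, clf = self._clf()
        w, b = clf.coef_, clf.intercept_
        x = np.zeros((1, X.shape[1]))
        x[0, clf.selected_[0]] = -b / w[0]
        assert boundary_distance(x, clf)[0] == pytest.approx(0.0, abs=1e-10)

    def test_reflection_flips_sign(self):
        X, clf = self._clf()
        d = boundary_distance(X, clf)
        # reflect each point across the boundary in the selected subspace
        Xr = X.copy()
        w = np.zeros(X.shape[1])
        w[clf.selected_] = clf.coef_
        nrm2 = float(w @ w)
        Xr -= 2 * ((X @ w + clf.intercept_) / nrm2)[:, None] * w[None, :]
        dr = boundary_distance(Xr, clf)
        np.testing.assert_allclose(dr, -d, atol=1e-8)

    def test_invariant_to_positive_rescaling(self):
        X, clf = self._clf()
        d1 = boundary_distance(X, clf)
        clf.coef_ = clf.coef_ * 4.2
        clf.intercept_ = clf.intercept_ * 4.2
        np.testing.assert_allclose(boundary_distance(X, clf), d1, atol=1e-10)

    def test_zero_weights_rejected(self):
        X, clf = self._clf()
        clf.coef_ = np.zeros_like(clf.coef_)
        with pytest.raises(ValueError):
            boundary_distance(X, clf)


class TestPsychometric:
    @staticmethod
    def _simulate(w_bias, w_stim, n=2000, seed=0):
        r = np.random.default_rng(seed)
        bias = r.normal(0, 1.5, n)
        stim = r.choice([-1.0, 1.0], n)
        p = 1 / (1 + np.exp(-(w_bias * bias + w_stim * stim)))
        choice = np.where(r.random(n) < p, 1.0, -1.0)
        return bias, choice, stim

    def test_bias_and_stimulus_integrated(self):
        bias, choice, stim = self._simulate(1.0, 1.0)
        out = bias_conditioned_psychometric(bias, choice, stim, n_bins=5)
        fwd, dwn = out["forward_stim"], out["downward_stim"]
        assert np.all(np.diff(fwd) >= -0.05) and fwd[-1] > fwd[0] + 0.2
        assert np.all(fwd >= dwn - 0.02)

    def test_stimulus_only_curves_flat(self):
        bias, choice, stim = self._simulate(0.0, 2.0, seed=1)
        out = bias_conditioned_psychometric(bias, choice, stim, n_bins=5)
        assert np.nanstd(out["forward_stim"]) < 0.06
        assert np.nanmean(out["forward_stim"]) > 0.8 > 0.2 > np.nanmean(out["downward_stim"])

    def test_bias_only_curves_coincide(self):
        bias, choice, stim = self._simulate(1.5, 0.0, seed=2)
        out = bias_conditioned_psychometric(bias, choice, stim, n_bins=5)
        np.testing.assert_allclose(out["forward_stim"], out["downward_stim"], atol=0.12)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            bias_conditioned_psychometric(np.arange(30.0), np.ones(30), np.ones(30), n_bins=5)


class TestIndependentHistoryInfo:
    @staticmethod
    def _features(orthogonal, n=400, seed=0):
        r = np.random.default_rng(seed)
        bias = r.normal(0, 1, n)
        outcome = r.choice([-1.0, 1.0], n)
        cols = [g * bias + r.normal(0, 0.2, n) for g in (1.0, -0.8, 0.6, 1.2)]
        if orthogonal:
            cols += [g * outcome + r.normal(0, 0.4, n) for g in (1.0, -1.0)]
        else:
            cols += [r.normal(0, 1, n) for _ in range(2)]
        return np.column_stack(cols), bias, outcome

    def test_orthogonal_outcome_axis_detected(self):
        X, bias, outcome = self._features(orthogonal=True)
        res = fit_bias_regression(X, bias)
        info = independent_history_info(X, res, outcome)
        assert info["difference"] > 0.1

    def test_collinear_population_near_zero(self):
        # outcome information reaches the features only through the bias
        r = np.random.default_rng(5)
        n = 400
        outcome = r.choice([-1.0, 1.0], n)
        bias = 0.9 * outcome + r.normal(0, 0.5, n)
        X = np.column_stack([g * bias + r.normal(0, 0.2, n) for g in (1.0, -0.8, 0.7, 1.1)])
        res = fit_bias_regression(X, bias)
        info = independent_history_info(X, res, outcome)
        assert abs(info["difference"]) <= 0.05

    def test_shuffled_history_near_zero(self):
        X, bias, outcome = self._features(orthogonal=True, seed=6)
        res = fit_bias_regression(X, bias)
        info = independent_history_info(X, res,
                                        np.random.default_rng(7).permutation(outcome))
        assert abs(info["difference"]) <= 0.06


class TestDecoderEstimators:
    def test_linear_decoder_sklearn_protocol(self):
        from sklearn.base import clone
        r = np.random.default_rng(0)
        X, y = r.normal(size=(100, 5)), r.normal(size=100)
        dec = StepwiseLinearDecoder(p_enter=0.1)
        assert clone(dec).get_params()["p_enter"] == 0.1
        dec.fit(X, y)
        assert dec.predict(X).shape == (100,)

    def test_logistic_decoder_prediction_rule(self):
        r = np.random.default_rng(1)
        y = r.choice([-1.0, 1.0], 150)
        X = np.column_stack([y * 3])
        clf = StepwiseLogisticDecoder().fit(X, y)
        assert np.array_equal(clf.predict(X), y)
        assert set(np.unique(clf.predict(X))) <= {-1.0, 1.0}
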