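import numpy as np
import pytest
from sklearn.base import clone

from itibias.agent import AgentSpec, simulate_agent_session
from itibias.history import (
    DEFAULT_TAU_GRID,
    FitResult,
    HistoryChoiceModel,
    InestimableSessionError,
    ModelParams,
    _predict_sign,
    bootstrap_mean_test,
    build_regressors,
    classify_adaptiveness,
    cv_accuracy,
    fit_logistic,
    grid_search_fit,
    internal_bias,
    likelihood_ratio_test,
    weight_change_zscores,
)

from conftest import make_session


def naive_regressors(outcome, choice, tau_o, tau_c, tau_oc):
    """Independent O(N^2) double-loop oracle for the discounted kernels."""
    n = len(outcome)
    O = np.zeros(n)
    C = np.zeros(n)
    I = np.zeros(n)
    for N in range(1, n + 1):           # 1-based trial number
        for k in range(1, N):
            w = np.exp(-(N - 1 - k) / tau_o)
            O[N - 1] += outcome[k - 1] * w
            C[N - 1] += choice[k - 1] * np.exp(-(N - 1 - k) / tau_c)
            I[N - 1] += outcome[k - 1] * choice[k - 1] * np.exp(-(N - 1 - k) / tau_oc)
    return O, C, I


class TestRegressors:
    def test_first_trial_history_is_zero(self):
        regs = build_regressors({"stimulus": [1], "choice": [1], "outcome": [-1]})
        assert regs["O"][0] == regs["C"][0] == regs["I"][0] == 0.0

    def test_worked_kernel_value(self):
        hist = {"stimulus": [1] * 5, "choice": [1] * 5, "outcome": [-1, 1, -1, 1, 1]}
        regs = build_regressors(hist, tau_o=1.0)
        expect = -np.exp(-3) + np.exp(-2) - np.exp(-1) + 1.0
        assert regs["O"][4] == pytest.approx(expect, abs=1e-12)
        assert regs["O"][4] == pytest.approx(0.71766877, abs=1e-8)

    def test_no_response_contributes_outcome_only(self):
        hist = {"stimulus": [1, 1], "choice": [0, 1], "outcome": [1, -1]}
        regs = build_regressors(hist, tau_o=1.0, tau_c=1.0, tau_oc=1.0)
        assert regs["O"][1] == 1.0   # error enters the outcome kernel
        assert regs["C"][1] == 0.0   # but not choice
        assert regs["I"][1] == 0.0   # nor the interaction

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            build_regressors({"stimulus": [1], "choice": [1], "outcome": [1]}, tau_o=0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(2, 60))
            outcome = rng.choice([-1, 1], n)
            choice = rng.choice([-1, 0, 1], n)
            outcome[choice == 0] = 1
            taus = rng.uniform(0.05, 50, 3)
            regs = build_regressors(
                {"stimulus": np.ones(n), "choice": choice, "outcome": outcome}, *taus)
            O, C, I = naive_regressors(outcome, choice, *taus)
            np.testing.assert_allclose(regs["O"], O, atol=1e-12)
            np.testing.assert_allclose(regs["C"], C, atol=1e-12)
            np.testing.assert_allclose(regs["I"], I, atol=1e-12)

    def test_geometric_bound_on_kernel(self):
        rng = np.random.default_rng(3)
        outcome = rng.choice([-1, 1], 500)
        for tau in (0.1, 1.0, 10.0):
            regs = build_regressors(
                {"stimulus": np.ones(500), "choice": np.ones(500), "outcome": outcome},
                tau_o=tau)
            assert np.max(np.abs(regs["O"])) <= 1.0 / (1.0 - np.exp(-1.0 / tau)) + 1e-12


class TestLogisticFit:
    def test_separable_toy_recovers_stimulus_weight(self):
        rng = np.random.default_rng(0)
        stim = np.tile([1.0, -1.0], 10)
        X = stim[:, None]
        fit = fit_logistic(X, stim)
        assert fit["weights"][0] > 5.0           # large under the tiny ridge
        assert abs(fit["constant"]) < 1.0

    def test_null_weights_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10_000, 3))
        y = rng.choice([-1.0, 1.0], 10_000)
        fit = fit_logistic(X, y)
        assert np.all(np.abs(fit["weights"]) < 0.06)

    def test_single_class_raises(self):
        with pytest.raises(InestimableSessionError):
            fit_logistic(np.ones((20, 1)), np.ones(20))

    def test_agrees_with_sklearn_oracle(self):
        from sklearn.linear_model import LogisticRegression
        rng = np.random.default_rng(7)
        X = rng.normal(size=(300, 4))
        y = np.where(rng.random(300) < 1 / (1 + np.exp(-(X @ [1, -0.5, 0.2, 0]))), 1.0, -1.0)
        ours = fit_logistic(X, y, ridge=1e-6)
        ref = LogisticRegression(C=1e6, tol=1e-10, max_iter=5000).fit(X, (y + 1) / 2)
        np.testing.assert_allclose(ours["weights"], ref.coef_[0], atol=2e-3)
        assert ours["constant"] == pytest.approx(ref.intercept_[0], abs=2e-3)


class TestCrossValidation:
    def test_tie_probability_predicts_downward(self):
        assert np.all(_predict_sign(np.zeros(5)) == -1)

    def test_stimulus_follower_predicted_perfectly(self, rng):
        sess = simulate_agent_session(AgentSpec(params=ModelParams(w_s=20.0)), 200, rng=rng)
        cv = cv_accuracy(sess, ModelParams(), variables_used=("s",))
        assert cv["accuracy"] > 0.97

    def test_pure_noise_agent_near_chance(self, rng):
        sess = simulate_agent_session(AgentSpec(params=ModelParams()), 600,
                                      rng=rng, with_times=False)
        cv = cv_accuracy(sess, ModelParams(), variables_used=("s", "o", "c", "oc"))
        assert cv["accuracy"] == pytest.approx(0.5, abs=0.08)

    def test_single_grid_point_reduces_to_cv(self, history_agent_session):
        fit = grid_search_fit(history_agent_session, ("s", "o"), tau_grid=[2.0])
        cv = cv_accuracy(history_agent_session, ModelParams(tau_o=2.0), ("s", "o"))
        assert fit.cv_accuracy == pytest.approx(cv["accuracy"])
        assert fit.params.tau_o == 2.0


class TestGridSearchFit:
    def test_recovers_outcome_weight_sign_and_scale(self, history_agent_session):
        fit = grid_search_fit(history_agent_session, ("s", "o", "c", "oc"),
                              tau_grid=[0.3, 2.0, 10.0])
        assert fit.params.w_o > 0.5
        assert fit.params.w_c < 0.0
        assert fit.params.w_s > 0.3
        assert 0.5 < fit.cv_accuracy <= 1.0

    def test_bias_excludes_stimulus_term(self, history_agent_session):
        fit = grid_search_fit(history_agent_session, ("s", "o"), tau_grid=[2.0])
        bias = internal_bias(history_agent_session, fit)
        np.testing.assert_allclose(bias, fit.bias, atol=1e-12)
        regs = build_regressors(history_agent_session.trials, tau_o=2.0)
        np.testing.assert_allclose(
            bias, fit.params.w_o * regs["O"] + fit.params.constant, atol=1e-12)

    def test_constant_only_bias_is_constant(self):
        sess = make_session([1, -1] * 30, [1, 1, -1, -1] * 15)
        fit = grid_search_fit(sess, (), tau_grid=[1.0])
        assert np.allclose(fit.bias, fit.params.constant)


class TestLikelihoodRatio:
    def _fit(self, sess, variables):
        return grid_search_fit(sess, variables, tau_grid=[2.0])

    def test_identical_models_give_p_one(self, history_agent_session):
        f = self._fit(history_agent_session, ("s", "o"))
        res = likelihood_ratio_test(f, f)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert res["p_value"] == 1.0

    def test_strong_history_agent_significant(self, history_agent_session):
        full = self._fit(history_agent_session, ("s", "o", "c", "oc"))
        partial = self._fit(history_agent_session, ("s",))
        res = likelihood_ratio_test(full, partial)
        assert res["df"] == 3
        assert res["p_value"] < 1e-4

    def test_non_nested_misuse_rejected(self, history_agent_session):
        full = self._fit(history_agent_session, ("s", "o"))
        partial = self._fit(history_agent_session, ("s", "c"))
        with pytest.raises(ValueError):
            likelihood_ratio_test(full, partial)


class TestAdaptiveness:
    def test_three_canonical_strategies(self, rng):
        assert classify_adaptiveness(ModelParams(constant=5.0), n_trials=200,
                                     rng=rng).label == "maladaptive"
        win_stay = classify_adaptiveness(ModelParams(w_oc=-20.0, tau_oc=0.01),
                                         n_trials=200, rng=rng)
        assert win_stay.label == "adaptive"
        assert win_stay.sim_fractions.mean() == pytest.approx(7 / 11, abs=0.03)
        assert classify_adaptiveness(ModelParams(), n_trials=200,
                                     rng=rng).label == "neutral"


class TestInactivationTools:
    def test_zero_resamples_rejected(self, history_agent_session):
        with pytest.raises(ValueError):
            weight_change_zscores(history_agent_session, n_resample=0)

    def test_single_class_light_on_excluded(self, rng):
        sess = make_session([1, -1] * 40, [1, -1] * 40,
                            light=([False] * 80))
        df = sess.trials.copy()
        df.loc[df.index % 10 == 0, "light"] = True
        df.loc[df.index % 10 == 0, "choice"] = 1
        df.loc[df.index % 10 == 0, "outcome"] = np.where(
            df.loc[df.index % 10 == 0, "stimulus"] == 1, -1, 1)
        from itibias.session import Session
        sess = Session(df, iti_seconds=8.0)
        with pytest.raises(InestimableSessionError):
            weight_change_zscores(sess, n_resample=5, rng=rng, tau_grid=[1.0])


class TestTransferAsymmetry:
    def test_model_fits_own_agent_better_than_another(self):
        """A session's model predicts held-out trials of its own agent better
        than trials generated by a different agent."""
        own, cross = [], []
        pa = ModelParams(w_s=1.0, w_o=1.8, tau_o=1.0)
        pb = ModelParams(w_s=1.0, w_c=-1.8, tau_c=5.0)
        for seed in range(6):
            ra = np.random.default_rng(9000 + seed)
            rb = np.random.default_rng(9500 + seed)
            sa = simulate_agent_session(AgentSpec(params=pa), 300, rng=ra, with_times=False)
            sb = simulate_agent_session(AgentSpec(params=pb), 300, rng=rb, with_times=False)
            m = HistoryChoiceModel(variables=("s", "o", "c", "oc"),
                                   tau_grid=[1.0, 5.0]).fit(sa)
            own.append(m.cv_accuracy_)
            cross.append(m.score(sb))
        assert np.mean(own) > np.mean(cross) + 0.02


class TestBootstrap:
    def test_degenerate_values(self, rng):
        res = bootstrap_mean_test(np.ones(10), rng=rng)
        assert (res["ci_lo"], res["ci_hi"]) == (1.0, 1.0) and res["significant"]
        res = bootstrap_mean_test(np.zeros(10), rng=rng)
        assert not res["significant"]

    def test_type_one_error_near_nominal(self):
        hits = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            res = bootstrap_mean_test(r.normal(size=100), n_boot=300, rng=r)
            hits += res["significant"]
        assert 0.005 <= hits / 200 <= 0.12


class TestEstimatorAPI:
    def test_sklearn_protocol(self, history_agent_session):
        m = HistoryChoiceModel(variables=("s", "o"), tau_grid=[2.0])
        assert clone(m).get_params()["tau_grid"] == [2.0]
        m.fit(history_agent_session)
        assert hasattr(m, "params_") and 0.0 <= m.cv_accuracy_ <= 1.0
        preds = m.predict(history_agent_session)
        assert set(np.unique(preds)) <= {-1, 1}
        assert m.score(history_agent_session) >= m.cv_accuracy_ - 0.1

    def test_unfitted_raises(self, history_agent_session):
        with pytest.raises(AttributeError):
            HistoryChoiceModel().predict(history_agent_session)
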