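import numpy as np
import pandas as pd
import pytest

from itibias.preprocess import DffTrace
from itibias.tuning import (
    ITI_EPOCH_IDS,
    auroc_score,
    behavioral_variables,
    conditioned_tuning,
    epoch_means,
    roc_selectivity,
    tuning_bias_correlation,
)

FR = 28.4


def _trace_and_events(step_at_stim=False):
    n_trials = 12
    stim = 20.0 + 12.0 * np.arange(n_trials)
    ev = pd.DataFrame({"t_stim_on": stim, "t_move_on": stim + 3.3})
    n = int((stim[-1] + 10) * FR)
    t = np.arange(n) / FR
    dff = np.zeros(n)
    if step_at_stim:
        for s in stim:
            dff[t >= s] += 1.0
            dff[t >= s + 6.0] -= 1.0
    return DffTrace(t=t, dff=dff), ev


class TestEpochMeans:
    def test_constant_trace_equal_epochs(self):
        trace, ev = _trace_and_events()
        em = epoch_means(DffTrace(t=trace.t, dff=np.full_like(trace.dff, 0.7)), ev)
        assert em.shape == (12, 9)
        np.testing.assert_allclose(em.to_numpy(), 0.7, atol=1e-12)

    def test_step_at_stimulus_onset(self):
        trace, ev = _trace_and_events(step_at_stim=True)
        em = epoch_means(trace, ev)
        pre = em[["stim0", "stim1", "stim2", "stim3"]].mean(axis=1)
        post = em[["stim4", "stim5"]].mean(axis=1)
        assert (post - pre > 0.9).all()

    def test_missing_movement_gives_nan_move_epochs(self):
        trace, ev = _trace_and_events()
        ev.loc[3, "t_move_on"] = np.nan
        em = epoch_means(trace, ev)
        assert em.loc[3, ["move0", "move1", "move2"]].isna().all()
        assert em.loc[3, ["stim0"]].notna().all()


class TestRocSelectivity:
    def test_perfect_separation(self, rng):
        values = np.concatenate([np.zeros(30), np.ones(30)])
        labels = np.concatenate([np.zeros(30), np.ones(30)])
        res = roc_selectivity(values, labels, rng=rng)
        assert res.auroc == 1.0 and res.strength == 1.0 and res.significant

    def test_identical_distributions_not_significant(self, rng):
        values = np.tile(np.arange(200.0), 2)
        labels = np.repeat([0, 1], 200)
        res = roc_selectivity(values, labels, rng=rng)
        assert res.strength < 0.15 and not res.significant

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        a = auroc_score(values, labels)
        b = auroc_score(values, 1 - labels)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_strength_invariant_to_monotone_transform(self, rng):
        r = np.random.default_rng(8)
        values = r.normal(size=120)
        labels = (values + r.normal(0, 1, 120) > 0).astype(int)
        s1 = roc_selectivity(values, labels, rng=np.random.default_rng(1)).strength
        s2 = roc_selectivity(np.exp(3 * values), labels, rng=np.random.default_rng(1)).strength
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_one_class_rejected(self, rng):
        with pytest.raises(ValueError):
            roc_selectivity(np.arange(10.0), np.ones(10), rng=rng)

    def test_tuned_cell_power(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            labels = np.repeat([0, 1], 100)
            values = r.normal(size=200) + labels  # 1-sd effect
            hits += roc_selectivity(values, labels, rng=r).significant
        assert hits >= 18


class TestConditionedTuning:
    @staticmethod
    def _variables(n, seed=0):
        r = np.random.default_rng(seed)
        return pd.DataFrame({
            "n_choice": r.choice([-1.0, 1.0], n),
            "n1_choice": r.choice([-1.0, 1.0], n),
            "n1_outcome": r.choice([-1.0, 1.0], n),
        })

    def test_outcome_only_cell_shows_no_choice_tuning(self, rng):
        v = self._variables(800, seed=1)
        values = 1.5 * v["n1_outcome"].to_numpy() + np.random.default_rng(2).normal(0, 1, 800)
        res = conditioned_tuning(values, v, target="n_choice", rng=rng)
        assert res["n_evaluable"] == 4
        assert res["n_significant"] <= 1    # at most a null-rate hit

    def test_independent_choice_gain_detected(self, rng):
        v = self._variables(800, seed=3)
        values = (1.2 * v["n_choice"] + 1.0 * v["n1_outcome"]).to_numpy() \
            + np.random.default_rng(4).normal(0, 1, 800)
        res = conditioned_tuning(values, v, target="n_choice", rng=rng)
        assert res["n_evaluable"] == 4
        assert res["n_significant"] >= 3

    def test_small_conditions_not_evaluable(self, rng):
        v = self._variables(100, seed=5)  # ~6 trials per class per condition
        values = np.random.default_rng(6).normal(size=100)
        res = conditioned_tuning(values, v, target="n_choice", rng=rng)
        assert res["n_evaluable"] == 0
        assert np.isnan(res["fraction_significant"])


class TestTuningBiasCorrelation:
    @staticmethod
    def _table(slope, n_cells=15, n_sessions=4, noise=0.02, seed=0):
        r = np.random.default_rng(seed)
        rows = []
        for c in range(n_cells):
            accs = r.uniform(0.5, 0.9, n_sessions)
            for s, acc in enumerate(accs):
                rows.append({
                    "cell_id": c, "session": s,
                    "strength": np.clip(slope * (acc - 0.5) + r.normal(0, noise), 0, 1),
                    "significant": True, "model_acc": acc,
                })
        return pd.DataFrame(rows)

    def test_gain_tracking_behavior_positive(self):
        res = tuning_bias_correlation(self._table(slope=1.0))
        assert res["defined"] and res["r"] > 0.5 and res["p_value"] < 0.05

    def test_independent_gains_near_zero(self):
        res = tuning_bias_correlation(self._table(slope=0.0, noise=0.2, seed=1))
        assert abs(res["r"]) < 0.25

    def test_single_session_undefined(self):
        res = tuning_bias_correlation(self._table(slope=1.0, n_sessions=1))
        assert not res["defined"]


class TestBehavioralVariables:
    def test_shifts_and_nan_handling(self):
        ev = pd.DataFrame({"choice": [1, 0, -1, 1], "outcome": [-1, 1, 1, -1]})
        v = behavioral_variables(ev)
        assert np.isnan(v.loc[0, "n1_choice"]) and np.isnan(v.loc[0, "n1_outcome"])
        assert np.isnan(v.loc[1, "n_choice"])       # no-response trial
        assert v.loc[2, "n1_choice"] is np.nan or np.isnan(v.loc[2, "n1_choice"])
        assert v.loc[3, "n1_choice"] == -1.0
        assert v.loc[2, "n1_outcome"] == 1.0
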