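"""Property-based validation experiments for the whole pipeline.

Real sessions from the original study are not redistributable, so the
package validates itself against synthetic ground truth: each function
here runs one self-contained experiment (kernel oracle agreement,
parameter recovery, model comparison, null calibration, inactivation
analogues, decoding analogues, preprocessing gates, determinism) and
returns its summary metrics. The acceptance tests and the acceptance
script are thin callers of these functions.

Problem sizes (seeds, trials, grids) are chosen to give stable pass/fail
margins on a single CPU; the methods note records them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import decoding, history, preprocess, tuning
from .agent import AgentSpec, simulate_agent_session
from .history import DEFAULT_TAU_GRID, ModelParams
from .neural_sim import CellSpec, generate_population
from .preprocess import DffTrace
from .task import assign_light_trials

WORKED_KERNEL_VALUE = -np.exp(-3) + np.exp(-2) - np.exp(-1) + 1.0  # 0.7176687…


def kernel_oracle_deviation(seed: int = 0, n_sessions: int = 100) -> dict:
    """Max |recursive - double-loop| kernel deviation over random sessions."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_sessions):
        n = int(rng.integers(2, 80))
        choice = rng.choice([-1, 0, 1], n)
        outcome = rng.choice([-1, 1], n)
        outcome[choice == 0] = 1
        tau_o, tau_c, tau_oc = rng.uniform(0.05, 80, 3)
        regs = history.build_regressors(
            {"stimulus": np.ones(n), "choice": choice, "outcome": outcome},
            tau_o, tau_c, tau_oc)
        O = np.zeros(n)
        C = np.zeros(n)
        I = np.zeros(n)
        for N in range(1, n + 1):
            for k in range(1, N):
                O[N - 1] += outcome[k - 1] * np.exp(-(N - 1 - k) / tau_o)
                C[N - 1] += choice[k - 1] * np.exp(-(N - 1 - k) / tau_c)
                I[N - 1] += outcome[k - 1] * choice[k - 1] * np.exp(-(N - 1 - k) / tau_oc)
        worst = max(worst,
                    np.max(np.abs(regs["O"] - O)),
                    np.max(np.abs(regs["C"] - C)),
                    np.max(np.abs(regs["I"] - I)))
    return {"max_deviation": float(worst), "n_sessions": n_sessions}


def worked_kernel_value() -> dict:
    """O(5) for outcomes [-1,+1,-1,+1] at tau=1 vs independent summation."""
    regs = history.build_regressors(
        {"stimulus": np.ones(5), "choice": np.ones(5),
         "outcome": [-1, 1, -1, 1, 1]}, tau_o=1.0)
    return {"computed": float(regs["O"][4]), "expected": float(WORKED_KERNEL_VALUE)}


def _one_grid_step(grid, true_tau):
    """Grid values within one step of the value bracketing true_tau."""
    g = np.asarray(sorted(grid))
    below = g[g <= true_tau]
    above = g[g >= true_tau]
    ok = set()
    if len(below):
        ok.add(below[-1])
    if len(above):
        ok.add(above[0])
    return ok


def parameter_recovery(seed: int = 0, n_seeds: int = 20, n_trials: int = 400) -> dict:
    """Sign and time-constant recovery for two generating agents.

    Agents: (w_s, w_o, tau_o) = (1, 1.5, 0.5) and (w_s, w_c, tau_c) =
    (1, -1, 10), fit with the matching variable subset over the full
    default tau grid. Reports per-seed sign-recovery rates and the median
    recovered tau per configuration.
    """
    configs = [
        ("o", ModelParams(w_s=1.0, w_o=1.5, tau_o=0.5), ("s", "o"), 0.5, 1),
        ("c", ModelParams(w_s=1.0, w_c=-1.0, tau_c=10.0), ("s", "c"), 10.0, -1),
    ]
    out = {}
    ss = np.random.SeedSequence(seed).spawn(len(configs))
    for (var, params, variables, true_tau, sign), seq in zip(configs, ss):
        child = seq.spawn(n_seeds)
        taus, signs = [], []
        for i in range(n_seeds):
            rng = np.random.default_rng(child[i])
            sess = simulate_agent_session(AgentSpec(params=params), n_trials,
                                          rng=rng, with_times=False)
            fit = history.grid_search_fit(sess, variables, tau_grid=DEFAULT_TAU_GRID)
            taus.append(fit.params.tau(var))
            signs.append(np.sign(fit.params.weight(var)) == sign)
        med = float(np.median(taus))
        out[var] = {
            "sign_rate": float(np.mean(signs)),
            "median_tau": med,
            "median_tau_within_one_step": med in _one_grid_step(DEFAULT_TAU_GRID, true_tau),
            "true_tau": true_tau,
        }
    out["n_seeds"] = n_seeds
    out["n_trials"] = n_trials
    return out


def model_comparison(seed: int = 0, n_seeds: int = 20, n_trials: int = 300,
                     tau_grid=(0.3, 2.0, 10.0)) -> dict:
    """Full vs stimulus-only CV accuracy on history-driven and
    stimulus-only agents (paired sign test across seeds)."""
    history_params = ModelParams(w_s=1.0, w_o=1.5, tau_o=2.0, w_c=-1.0, tau_c=10.0)
    stim_params = ModelParams(w_s=1.5)
    out = {}
    ss = np.random.SeedSequence(seed).spawn(2)
    for name, params, seq in (("history_agent", history_params, ss[0]),
                              ("stimulus_agent", stim_params, ss[1])):
        child = seq.spawn(n_seeds)
        diffs = []
        for i in range(n_seeds):
            rng = np.random.default_rng(child[i])
            sess = simulate_agent_session(AgentSpec(params=params), n_trials,
                                          rng=rng, with_times=False)
            full = history.grid_search_fit(sess, ("s", "o", "c", "oc"), tau_grid=tau_grid)
            part = history.grid_search_fit(sess, ("s",), tau_grid=tau_grid)
            diffs.append(full.cv_accuracy - part.cv_accuracy)
        diffs = np.asarray(diffs)
        n_pos = int(np.sum(diffs > 0))
        n_nonzero = int(np.sum(diffs != 0))
        p = stats.binomtest(n_pos, max(n_nonzero, 1), 0.5,
                            alternative="greater").pvalue if n_nonzero else 1.0
        out[name] = {"mean_diff": float(diffs.mean()), "n_positive": n_pos,
                     "sign_test_p": float(p)}
    out["n_seeds"] = n_seeds
    return out


def adaptiveness_classification(seed: int = 0, n_sim: int = 100, n_trials: int = 250) -> dict:
    """Labels for the three canonical strategies + the win-stay/lose-switch
    discrimination against its Markov-chain value 7/11."""
    ss = np.random.SeedSequence(seed).spawn(3)
    const = history.classify_adaptiveness(ModelParams(constant=5.0), n_trials=n_trials,
                                          n_sim=n_sim, rng=np.random.default_rng(ss[0]))
    wsls = history.classify_adaptiveness(ModelParams(w_oc=-20.0, tau_oc=0.01),
                                         n_trials=n_trials, n_sim=n_sim,
                                         rng=np.random.default_rng(ss[1]))
    zero = history.classify_adaptiveness(ModelParams(), n_trials=n_trials, n_sim=n_sim,
                                         rng=np.random.default_rng(ss[2]))
    return {
        "constant_label": const.label,
        "wsls_label": wsls.label,
        "zero_label": zero.label,
        "wsls_mean_fraction": float(wsls.sim_fractions.mean()),
        "wsls_expected_fraction": 7.0 / 11.0,
    }


def lrt_null_calibration(seed: int = 0, n_seeds: int = 200, n_trials: int = 300) -> dict:
    """KS uniformity of LRT p-values on null (memoryless) agents."""
    child = np.random.SeedSequence(seed).spawn(n_seeds)
    pvals = []
    for i in range(n_seeds):
        rng = np.random.default_rng(child[i])
        sess = simulate_agent_session(AgentSpec(params=ModelParams(w_s=0.8)), n_trials,
                                      rng=rng, with_times=False)
        full = history.grid_search_fit(sess, ("s", "o", "c", "oc"), tau_grid=[1.0])
        part = history.grid_search_fit(sess, ("s",), tau_grid=[1.0])
        pvals.append(history.likelihood_ratio_test(full, part)["p_value"])
    ks = stats.kstest(pvals, "uniform")
    return {"ks_statistic": float(ks.statistic), "ks_p": float(ks.pvalue),
            "n_seeds": n_seeds}


def roc_null_calibration(seed: int = 0, n_cells: int = 600, n_trials: int = 160) -> dict:
    """Fraction of untuned cells flagged significant by the shuffle-null
    ROC test (nominal corrected rate alpha/m ~ 0.0011)."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n_trials // 2)
    hits = 0
    for _ in range(n_cells):
        values = rng.normal(size=n_trials)
        hits += tuning.roc_selectivity(values, labels, rng=rng).significant
    return {"significant_rate": hits / n_cells, "nominal": 0.01 / 9, "n_cells": n_cells}


def _light_session(params, light_effect, n_trials, rng):
    light = assign_light_trials(n_trials, 0.15, 5, rng)
    spec = AgentSpec(params=params, light_effect=light_effect)
    return simulate_agent_session(spec, n_trials, light=light, rng=rng, with_times=False)


def inactivation_analysis(seed: int = 0, n_seeds: int = 20, n_trials: int = 400,
                          transfer_grid=(1.0, 10.0), z_grid=(2.0,)) -> dict:
    """Inactivation analogues: light-off-model transfer accuracy drop and
    weight-magnitude z-scores, for perturbed vs unperturbed agents.

    The perturbed agent has its choice-history, interaction, and constant
    weights scaled to 0.2 on light-on trials (outcome history untouched).
    """
    params = ModelParams(w_s=1.0, w_o=1.5, tau_o=2.0, w_c=-1.2, tau_c=10.0, constant=0.4)
    effects = {"perturbed": {"c": 0.2, "oc": 0.2, "constant": 0.2}, "unperturbed": {}}
    out = {}
    ss = np.random.SeedSequence(seed).spawn(2)
    for (name, eff), seq in zip(effects.items(), ss):
        child = seq.spawn(n_seeds)
        acc_diff = []
        z_wc = []
        z_all = []
        for i in range(n_seeds):
            rng = np.random.default_rng(child[i])
            sess = _light_session(params, eff, n_trials, rng)
            tr = history.lightoff_model_transfer(sess, ("o", "c", "oc"),
                                                 tau_grid=transfer_grid)
            acc_diff.append(tr["acc_on_light_on"] - tr["acc_on_heldout_off"])
            try:
                z = history.weight_change_zscores(sess, n_resample=100, rng=rng,
                                                  tau_grid=z_grid)
                z_wc.append(z["z"]["w_c"])
                z_all.extend(z["z"].values())
            except history.InestimableSessionError:
                pass
        acc_diff = np.asarray(acc_diff)
        n_neg = int(np.sum(acc_diff < 0))
        n_nonzero = int(np.sum(acc_diff != 0))
        p = stats.binomtest(n_neg, max(n_nonzero, 1), 0.5,
                            alternative="greater").pvalue if n_nonzero else 1.0
        z_all = np.asarray(z_all)
        out[name] = {
            "mean_acc_drop_on_light_on": float(acc_diff.mean()),
            "transfer_sign_test_p": float(p),
            "mean_z_wc": float(np.mean(z_wc)) if z_wc else float("nan"),
            "frac_wc_z_negative": float(np.mean(np.asarray(z_wc) < 0)) if z_wc else float("nan"),
            "frac_abs_z_below_2": float(np.mean(np.abs(z_all) < 2)) if len(z_all) else float("nan"),
        }
    out["n_seeds"] = n_seeds
    return out


def _bias_population(seed, n_trials=250, orthogonal=False, n_bias=12, n_hist=6):
    rng = np.random.default_rng(seed)
    params = ModelParams(w_s=1.0, w_o=1.5, tau_o=2.0, w_c=-0.8, tau_c=10.0, constant=0.2)
    sess = simulate_agent_session(AgentSpec(params=params), n_trials, rng=rng)
    cells = [CellSpec(tuning={"bias": 18.0 * (1 if i % 2 else -1)},
                      baseline_rate=22.0, noise_sd=0.03) for i in range(n_bias)]
    if orthogonal:
        cells += [CellSpec(tuning={"n1_outcome": 25.0 * (1 if i % 2 else -1)},
                           baseline_rate=22.0, noise_sd=0.03) for i in range(n_hist)]
    else:
        cells += [CellSpec(tuning={}, baseline_rate=22.0, noise_sd=0.03)
                  for _ in range(n_hist)]
    rec = generate_population(sess, cells, rng=rng)
    feats, _ = tuning.iti_feature_matrix(rec)
    bias = rec.trial_events["bias_true"].to_numpy()
    outcome = tuning.behavioral_variables(rec.trial_events)["n1_outcome"].to_numpy()
    ok = np.isfinite(feats).all(axis=1) & np.isfinite(outcome)
    return feats[ok], bias[ok], outcome[ok], rng


def decoding_analysis(seed: int = 0, n_seeds: int = 3) -> dict:
    """Decoding analogues: cross-validated r^2 of the true vs shuffled
    internal bias, and bias-independent previous-outcome information for
    populations with vs without an orthogonal outcome axis."""
    child = np.random.SeedSequence(seed).spawn(2 * n_seeds)
    r2_true, r2_shuf, diff_orth, diff_coll = [], [], [], []
    for i in range(n_seeds):
        feats, bias, outcome, rng = _bias_population(child[i], orthogonal=True)
        res = decoding.fit_bias_regression(feats, bias)
        r2_true.append(res.cv_value)
        res_sh = decoding.fit_bias_regression(feats, rng.permutation(bias))
        r2_shuf.append(res_sh.cv_value)
        diff_orth.append(decoding.independent_history_info(feats, res, outcome)["difference"])

        feats, bias, outcome, rng = _bias_population(child[n_seeds + i], orthogonal=False)
        res = decoding.fit_bias_regression(feats, bias)
        diff_coll.append(decoding.independent_history_info(feats, res, outcome)["difference"])
    return {
        "bias_r2_true": float(np.mean(r2_true)),
        "bias_r2_shuffled": float(np.mean(r2_shuf)),
        "independent_info_orthogonal": float(np.mean(diff_orth)),
        "independent_info_collinear": float(np.mean(diff_coll)),
        "n_seeds": n_seeds,
    }


def preprocessing_gates(seed: int = 0, n_null_cells: int = 25, n_null_each: int = 10) -> dict:
    """Constructed positives/negatives through the transient, active, and
    task-related gates, plus the shift-shuffle false-positive rate."""
    fr = 28.4
    rng = np.random.default_rng(seed)

    def trace_with(peaks, amp=0.8, noise=0.02, minutes=3.0, seed_=0):
        n = int(minutes * 60 * fr)
        r = np.random.default_rng(seed_)
        dff = r.normal(0, noise, n)
        for pk in peaks:
            i = int(pk * fr)
            dff[i:] += amp * np.exp(-np.arange(n - i) / (0.3 * fr))
        return DffTrace(t=np.arange(n) / fr, dff=dff)

    pos = trace_with(np.arange(10, 170, 20.0))
    tr_pos = preprocess.detect_transients(pos)
    act_pos = preprocess.classify_active(pos, tr_pos)
    small = trace_with([60.0], amp=0.4)
    neg_detected = len(preprocess.detect_transients(small))

    # task-related positive: sparse reliable burst cell
    times = 100 + 120.0 * np.arange(10)
    ev = pd.DataFrame({"t_stim_on": times, "t_move_on": times + 3.3,
                       "t_reward": times + 3.6, "outcome": -1})
    n = int(1500 * fr)
    dff = rng.normal(0, 0.02, n)
    for tt in times:
        i = int(tt * fr) + 6
        for k in range(5):
            dff[i + k:] += np.exp(-np.arange(n - i - k) / (0.3 * fr))
    burst = DffTrace(t=np.arange(n) / fr, dff=dff)
    task_pos = preprocess.classify_task_related(burst, ev, rng=rng, n_null=5)

    # shift-shuffled false-positive rate over null noise cells
    times_n = 15.0 + 10.0 * np.arange(20)
    ev_n = pd.DataFrame({"t_stim_on": times_n, "t_move_on": times_n + 3.3,
                         "t_reward": times_n + 3.6, "outcome": -1})
    fps = []
    for c in range(n_null_cells):
        noise_cell = trace_with(rng.uniform(5, 225, 6), amp=0.8, noise=0.05,
                                minutes=4.0, seed_=1000 + c)
        res = preprocess.classify_task_related(noise_cell, ev_n, rng=rng,
                                               n_null=n_null_each)
        fps.append(res["fp_estimate"])
    return {
        "transients_detected_positive": int(len(tr_pos)),
        "active_positive": bool(act_pos["active"]),
        "subthreshold_transients": int(neg_detected),
        "task_related_positive": bool(task_pos["task_related"]),
        "shift_shuffle_fp_rate": float(np.mean(fps)),
        "n_null_tests": n_null_cells * n_null_each,
    }


def determinism_check(seed: int = 0, tmp_dir=None) -> dict:
    """Byte-identity of two full pipeline runs with the same config."""
    import tempfile
    from .pipeline import RunConfig, run_pipeline

    cfg = RunConfig({
        "seed": seed,
        "behavior": {"n_trials": 200},
        "model": {"tau_grid": [1.0, 10.0]},
        "neural": {"n_bias": 4, "n_outcome": 3, "n_choice": 2, "n_move": 2,
                   "n_untuned": 3},
    }).merged()
    with tempfile.TemporaryDirectory(dir=tmp_dir) as td:
        m1 = run_pipeline(cfg, f"{td}/a")
        m2 = run_pipeline(cfg, f"{td}/b")
    h1 = {k: v["sha256"] for k, v in m1["outputs"].items()}
    h2 = {k: v["sha256"] for k, v in m2["outputs"].items()}
    return {"identical": h1 == h2, "n_outputs": len(h1),
            "stage_results": m1["stage_results"]}
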