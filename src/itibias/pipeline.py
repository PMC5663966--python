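"""End-to-end orchestration: synthetic generation through analysis tables.

A run executes simulate-behavior -> fit-model -> adaptiveness ->
inactivation -> simulate-neural -> preprocess -> tuning -> decode in
dependency order, derives a logged sub-seed for every stochastic stage
from the master seed, and writes a manifest with SHA-256 hashes of all
outputs. Identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agent, decoding, history, neural_sim, preprocess, task, tuning
from .session import Session, write_trial_table

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": ["behavior", "fit", "adaptiveness", "inactivation",
               "neural", "preprocess", "tuning", "decode"],
    "behavior": {
        "n_trials": 300,
        "iti_seconds": 8.0,
        "params": {"w_s": 1.0, "w_o": 1.5, "tau_o": 2.0, "w_c": -1.0, "tau_c": 10.0,
                   "w_oc": 0.0, "tau_oc": 1.0, "constant": 0.2},
        "lapse": 0.0,
        "no_response_rate": 0.05,
        "light_fraction": 0.15,
        "min_gap": 5,
        "light_effect": {"c": 0.2, "oc": 0.2, "constant": 0.2},
    },
    "model": {"variables": ["s", "o", "c", "oc"], "tau_grid": [0.1, 1.0, 10.0], "n_folds": 10},
    "adaptiveness": {"n_sim": 100, "n_trials": 250},
    "inactivation": {"n_resample": 100},
    "neural": {
        "frame_rate": 28.4,
        "n_bias": 10, "n_outcome": 6, "n_choice": 4, "n_move": 4, "n_untuned": 6,
        "baseline_rate": 6.0, "gain": 20.0, "bias_gain": 10.0, "move_gain": 150.0,
        "noise_sd": 0.05,
    },
    "decode": {"n_folds": 10, "mode": "pooled"},
}


@dataclass
class RunConfig:
    """Structured run configuration; unspecified keys take package defaults."""

    values: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def merged(self) -> dict:
        out = json.loads(json.dumps(DEFAULT_CONFIG))
        _deep_update(out, self.values)
        return out


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return [round(float(x), 10) if np.isfinite(x) else None for x in o.ravel()]
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not serializable: {type(o)}")


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def default_cell_specs(cfg: dict) -> list:
    """Population composition used by the neural stage: bias-, history-,
    choice-, and movement-tuned cells plus untuned controls, with
    alternating preferred directions."""
    specs = []
    common = dict(baseline_rate=cfg["baseline_rate"], noise_sd=cfg["noise_sd"])
    for i in range(cfg["n_bias"]):
        specs.append(neural_sim.CellSpec(
            tuning={"bias": cfg["bias_gain"] * (1 if i % 2 else -1)}, **common))
    for i in range(cfg["n_outcome"]):
        specs.append(neural_sim.CellSpec(
            tuning={"n1_outcome": cfg["gain"] * (1 if i % 2 else -1)}, **common))
    for i in range(cfg["n_choice"]):
        specs.append(neural_sim.CellSpec(
            tuning={"n_choice": cfg["gain"] * (1 if i % 2 else -1)}, **common))
    for i in range(cfg["n_move"]):
        specs.append(neural_sim.CellSpec(tuning={"movement": cfg["move_gain"]}, **common))
    for _ in range(cfg["n_untuned"]):
        specs.append(neural_sim.CellSpec(tuning={}, **common))
    return specs


def fit_to_dict(fit: history.FitResult) -> dict:
    return _round_floats({
        "params": fit.params.as_dict(),
        "variables_used": list(fit.variables_used),
        "cv_accuracy": fit.cv_accuracy,
        "log_likelihood": fit.log_likelihood,
        "n_included": fit.n_included,
        "warnings": fit.warnings,
    })


def run_pipeline(config: RunConfig | dict, out_dir) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    cfg = config.merged() if isinstance(config, RunConfig) else config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    master = np.random.SeedSequence(cfg["seed"])
    sub = {name: np.random.default_rng(s) for name, s in zip(
        ("behavior", "adaptiveness", "inactivation", "neural", "preprocess", "tuning", "decode"),
        master.spawn(7))}
    manifest = {"config": cfg, "outputs": {}, "skipped": [], "stage_results": {}}

    def record(name, path):
        manifest["outputs"][name] = {"path": str(path.name), "sha256": sha256_file(path)}

    session = fit = recording = feats = tables = None

    if "behavior" in stages:
        b = cfg["behavior"]
        params = history.ModelParams(**b["params"])
        spec = agent.AgentSpec(params=params, lapse=b["lapse"],
                               no_response_rate=b["no_response_rate"],
                               light_effect=dict(b.get("light_effect") or {}))
        light = task.assign_light_trials(b["n_trials"], b["light_fraction"],
                                         b["min_gap"], sub["behavior"]) \
            if b["light_fraction"] > 0 else None
        session = agent.simulate_agent_session(spec, b["n_trials"], light=light,
                                               rng=sub["behavior"],
                                               iti_seconds=b["iti_seconds"])
        p = out / "session.csv"
        write_trial_table(session, p)
        record("session", p)
    else:
        manifest["skipped"].append("behavior")

    if "fit" in stages and session is not None:
        m = cfg["model"]
        fit = history.grid_search_fit(session, tuple(m["variables"]),
                                      tau_grid=m["tau_grid"], n_folds=m["n_folds"])
        partial = history.grid_search_fit(session, ("s",), tau_grid=m["tau_grid"],
                                          n_folds=m["n_folds"])
        lrt = history.likelihood_ratio_test(fit, partial)
        d = fit_to_dict(fit)
        d["stimulus_only_cv_accuracy"] = round(partial.cv_accuracy, 10)
        d["lrt_vs_stimulus_only"] = _round_floats(lrt)
        p = out / "fit.json"
        _write_json(d, p)
        record("fit", p)
        bias_df = pd.DataFrame({
            "index": session.trials["index"],
            "bias": fit.bias,
            "p_forward": fit.p_forward,
        })
        pb = out / "bias.csv"
        bias_df.to_csv(pb, index=False, float_format="%.8f")
        record("bias", pb)
        manifest["stage_results"]["fit"] = {"cv_accuracy": round(fit.cv_accuracy, 6),
                                            "lrt_p": lrt["p_value"]}
    elif "fit" in stages:
        manifest["skipped"].append("fit")

    if "adaptiveness" in stages and fit is not None:
        a = cfg["adaptiveness"]
        label = history.classify_adaptiveness(fit.params, n_trials=a["n_trials"],
                                              n_sim=a["n_sim"], rng=sub["adaptiveness"])
        p = out / "adaptiveness.json"
        _write_json({"label": label.label,
                     "mean_fraction_correct": round(float(label.sim_fractions.mean()), 10),
                     "n_sim": a["n_sim"]}, p)
        record("adaptiveness", p)
    elif "adaptiveness" in stages:
        manifest["skipped"].append("adaptiveness")

    if "inactivation" in stages and session is not None and session.light.any():
        m = cfg["model"]
        transfer = history.lightoff_model_transfer(
            session, tuple(v for v in m["variables"] if v != "s"),
            tau_grid=m["tau_grid"], n_folds=m["n_folds"])
        try:
            z = history.weight_change_zscores(
                session, n_resample=cfg["inactivation"]["n_resample"],
                rng=sub["inactivation"], variables_used=tuple(m["variables"]),
                tau_grid=m["tau_grid"], n_folds=m["n_folds"])
            zs = _round_floats(z["z"])
        except history.InestimableSessionError as e:
            zs = {"excluded": str(e)}
        p = out / "inactivation.json"
        _write_json({"transfer": _round_floats({k: v for k, v in transfer.items()}),
                     "weight_change_z": zs}, p)
        record("inactivation", p)
    elif "inactivation" in stages:
        manifest["skipped"].append("inactivation")

    if "neural" in stages and session is not None:
        ncfg = cfg["neural"]
        specs = default_cell_specs(ncfg)
        bias = fit.bias if fit is not None else None
        recording = neural_sim.generate_population(
            session, specs, rng=sub["neural"], frame_rate=ncfg["frame_rate"], bias=bias)
        p = out / "recording.h5"
        gt = out / "ground_truth.json"
        recording.to_hdf5(p, ground_truth_path=gt)
        record("recording", p)
        record("ground_truth", gt)
    elif "neural" in stages:
        manifest["skipped"].append("neural")

    if "preprocess" in stages and recording is not None:
        qc = preprocess.qc_table(recording, rng=sub["preprocess"])
        p = out / "qc.csv"
        qc.to_csv(p, index=False, float_format="%.6f")
        record("qc", p)
        manifest["stage_results"]["preprocess"] = {
            "n_active": int(qc["active"].sum()),
            "n_task_related": int(qc["task_related"].fillna(False).sum()),
        }
    elif "preprocess" in stages:
        manifest["skipped"].append("preprocess")

    if "tuning" in stages and recording is not None:
        feats, tables = tuning.iti_feature_matrix(recording)
        variables = tuning.behavioral_variables(recording.trial_events)
        rows = []
        for ci, em in enumerate(tables):
            iti = em[tuning.ITI_EPOCH_IDS].mean(axis=1).to_numpy()
            for var in ("n_choice", "n1_choice", "n1_outcome"):
                lab = variables[var].to_numpy()
                m = np.isfinite(iti) & np.isfinite(lab)
                if len(np.unique(lab[m])) < 2:
                    continue
                res = tuning.roc_selectivity(iti[m], (lab[m] == 1).astype(int),
                                             rng=sub["tuning"], variable=var, epoch="iti")
                rows.append({"cell_id": ci, "variable": var, "epoch": "iti",
                             "auroc": round(res.auroc, 8), "strength": round(res.strength, 8),
                             "p": round(res.p_shuffle, 8), "significant": res.significant,
                             "n_pos": res.n_pos, "n_neg": res.n_neg})
        p = out / "tuning.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        record("tuning", p)
    elif "tuning" in stages:
        manifest["skipped"].append("tuning")

    if "decode" in stages and recording is not None and fit is not None:
        if feats is None:
            feats, tables = tuning.iti_feature_matrix(recording)
        dcfg = cfg["decode"]
        variables = tuning.behavioral_variables(recording.trial_events)
        bias = recording.trial_events["bias_true"].to_numpy()
        ok = np.isfinite(feats).all(axis=1)
        res = decoding.fit_bias_regression(feats[ok], bias[ok], n_folds=dcfg["n_folds"],
                                           mode=dcfg["mode"])
        shuffled = sub["decode"].permutation(bias[ok])
        res_sh = decoding.fit_bias_regression(feats[ok], shuffled, n_folds=dcfg["n_folds"],
                                              mode=dcfg["mode"])
        out_d = {"bias_r2": round(res.cv_value, 8),
                 "bias_r2_shuffled": round(res_sh.cv_value, 8),
                 "n_selected": int(len(res.selected))}
        for var in ("n_choice", "n1_choice", "n1_outcome"):
            lab = variables[var].to_numpy()
            m = ok & np.isfinite(lab)
            clf = decoding.fit_classifier(feats[m], lab[m], n_folds=dcfg["n_folds"],
                                          mode=dcfg["mode"], target_name=var)
            out_d[f"acc_{var}"] = round(clf.cv_value, 8)
            if var != "n_choice" and len(res.selected):
                info = decoding.independent_history_info(
                    feats[m], res, lab[m], n_folds=dcfg["n_folds"], target_name=var)
                out_d[f"independent_{var}"] = round(info["difference"], 8)
        p = out / "decode.json"
        _write_json(out_d, p)
        record("decode", p)
        manifest["stage_results"]["decode"] = out_d
    elif "decode" in stages:
        manifest["skipped"].append("decode")

    mp = out / "manifest.json"
    _write_json(manifest, mp)
    return manifest
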