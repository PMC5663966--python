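"""Epoch-wise ROC selectivity for choice and history variables.

Selectivity strength is 2*|AUROCC - 0.5|; significance comes from a
label-shuffle null (the threshold percentile implements a Bonferroni-
corrected alpha over the epochs tested per cell). Conditioned tuning
isolates a variable's coding by fixing the other two task variables, and
the between-session correlation relates tuning changes to changes in the
behavioral dependency on the same variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# 6 one-second epochs tiling [-4, 2) s around stimulus onset, then
# 3 epochs tiling [-1.5, 1.5) s around movement onset.
STIM_EPOCH_EDGES = np.arange(-4.0, 2.5, 1.0)
MOVE_EPOCH_EDGES = np.arange(-1.5, 2.0, 1.0)
EPOCH_IDS = [f"stim{i}" for i in range(6)] + [f"move{i}" for i in range(3)]
ITI_EPOCH_IDS = EPOCH_IDS[:4]  # the [-4, 0) s pre-stimulus window


@dataclass
class SelectivityResult:
    variable: str
    epoch: str
    auroc: float
    strength: float
    p_shuffle: float
    significant: bool
    n_pos: int
    n_neg: int


def epoch_means(trace, trial_events: pd.DataFrame) -> pd.DataFrame:
    """Mean dF/F per trial in the 9 canonical 1-s epochs.

    Frames are assigned to epochs by their midpoint time. Missing events
    (e.g., no movement onset) leave the corresponding epochs NaN; epochs
    falling outside the recording are NaN with a warning.
    """
    fr = trace.frame_rate
    mid = trace.t + 0.5 / fr
    csum = np.concatenate([[0.0], np.cumsum(trace.dff)])
    out = {}
    warned = False
    for align, edges, prefix in (
        ("t_stim_on", STIM_EPOCH_EDGES, "stim"),
        ("t_move_on", MOVE_EPOCH_EDGES, "move"),
    ):
        times = trial_events[align].to_numpy(dtype=float)
        n_ep = len(edges) - 1
        vals = np.full((len(times), n_ep), np.nan)
        finite = np.isfinite(times)
        for j in range(n_ep):
            lo_t = times[finite] + edges[j]
            hi_t = times[finite] + edges[j + 1]
            lo = np.searchsorted(mid, lo_t, side="left")
            hi = np.searchsorted(mid, hi_t, side="left")
            inside = (lo_t >= trace.t[0]) & (hi_t <= trace.t[-1] + 1.0 / fr)
            if (~inside).any() and not warned:
                warnings.warn("epoch outside recording; trial epoch dropped")
                warned = True
            good = inside & (hi > lo)
            col = np.full(finite.sum(), np.nan)
            col[good] = (csum[hi[good]] - csum[lo[good]]) / (hi[good] - lo[good])
            vals[finite, j] = col
        for j in range(n_ep):
            out[f"{prefix}{j}"] = vals[:, j]
    return pd.DataFrame(out, index=trial_events.index)


def iti_feature_matrix(recording, cells=None) -> tuple:
    """ITI population features: per-trial mean dF/F in the 4 pre-stimulus
    epochs of each cell (n_trials x 4*n_cells), plus per-cell epoch tables.

    Feature column 4*c + e is epoch ``e`` of cell ``c``.
    """
    from .preprocess import compute_dff

    cells = range(recording.n_cells) if cells is None else cells
    tables = []
    cols = []
    for ci in cells:
        trace = compute_dff(recording.raw[ci], recording.background[ci], recording.frame_rate)
        em = epoch_means(trace, recording.trial_events)
        tables.append(em)
        cols.append(em[ITI_EPOCH_IDS].to_numpy())
    return np.column_stack(cols), tables


def auroc_score(values: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(values)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_selectivity(
    values,
    labels,
    n_shuffle: int = 1000,
    alpha: float = 0.01,
    bonferroni_m: int = 9,
    rng=None,
    variable: str = "",
    epoch: str = "",
) -> SelectivityResult:
    """ROC selectivity with a label-shuffle null.

    Significance: strength above the 100*(1 - alpha/bonferroni_m) percentile
    of the shuffled-strength null (e.g., the 99.9th percentile for alpha
    0.01 corrected over 9 epochs). Deterministic given ``rng``.
    """
    rng = np.random.default_rng() if rng is None else rng
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    n = n1 + n0
    ranks = stats.rankdata(values)
    auroc = float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
    strength = 2.0 * abs(auroc - 0.5)

    # vectorized shuffles: random n1-subsets of the rank vector
    perm = np.argsort(rng.random((n_shuffle, n)), axis=1)[:, :n1]
    u = ranks[perm].sum(axis=1) - n1 * (n1 + 1) / 2.0
    null_strength = 2.0 * np.abs(u / (n1 * n0) - 0.5)
    pct = 100.0 * (1.0 - alpha / bonferroni_m)
    threshold = np.percentile(null_strength, pct)
    p_shuffle = float((np.sum(null_strength >= strength) + 1) / (n_shuffle + 1))
    return SelectivityResult(
        variable=variable, epoch=epoch, auroc=auroc, strength=strength,
        p_shuffle=p_shuffle, significant=bool(strength > threshold),
        n_pos=n1, n_neg=n0,
    )


def behavioral_variables(trial_events: pd.DataFrame) -> pd.DataFrame:
    """Signed (+1/-1) n_choice, n1_choice, n1_outcome per trial; the first
    trial and no-response entries are NaN."""
    choice = trial_events["choice"].to_numpy(dtype=float)
    outcome = trial_events["outcome"].to_numpy(dtype=float)
    out = pd.DataFrame(index=trial_events.index)
    out["n_choice"] = np.where(choice == 0, np.nan, choice)
    out["n1_choice"] = np.concatenate([[np.nan], np.where(choice == 0, np.nan, choice)[:-1]])
    out["n1_outcome"] = np.concatenate([[np.nan], outcome[:-1]])
    return out


def conditioned_tuning(
    values: np.ndarray,
    variables: pd.DataFrame,
    target: str,
    min_per_class: int = 18,
    n_shuffle: int = 1000,
    alpha: float = 0.01,
    rng=None,
) -> dict:
    """Tuning for ``target`` within the 4 conditions fixing the other two
    task variables (n_choice / n1_choice / n1_outcome).

    A condition is evaluable only when both target classes have at least
    ``min_per_class`` trials; returns per-condition results and the
    fraction of evaluable conditions significant.
    """
    rng = np.random.default_rng() if rng is None else rng
    others = [v for v in ("n_choice", "n1_choice", "n1_outcome") if v != target]
    values = np.asarray(values, dtype=float)
    results = {}
    n_sig = n_eval = 0
    for a in (-1.0, 1.0):
        for b in (-1.0, 1.0):
            m = (
                (variables[others[0]] == a).to_numpy()
                & (variables[others[1]] == b).to_numpy()
                & variables[target].notna().to_numpy()
                & np.isfinite(values)
            )
            tv = variables.loc[m, target].to_numpy()
            key = f"{others[0]}={a:+.0f},{others[1]}={b:+.0f}"
            n_pos = int((tv == 1).sum())
            n_neg = int((tv == -1).sum())
            if min(n_pos, n_neg) < min_per_class:
                results[key] = None  # not evaluable
                continue
            res = roc_selectivity(values[m], (tv == 1).astype(int), n_shuffle=n_shuffle,
                                  alpha=alpha, bonferroni_m=4, rng=rng,
                                  variable=target, epoch=key)
            results[key] = res
            n_eval += 1
            n_sig += int(res.significant)
    return {
        "conditions": results,
        "n_evaluable": n_eval,
        "n_significant": n_sig,
        "fraction_significant": n_sig / n_eval if n_eval else float("nan"),
    }


def tuning_bias_correlation(table: pd.DataFrame) -> dict:
    """Between-session Delta(tuning strength) vs Delta(behavioral dependency).

    ``table`` has one row per (cell_id, session) with columns ``strength``,
    ``significant`` and ``model_acc`` (accuracy of the matching one-variable
    partial model). For every cell and session pair the differences are
    paired; cells must be significantly tuned in at least one session of a
    pair to enter. Fewer than 3 pairs yields an undefined, flagged result.
    """
    d_tuning, d_acc = [], []
    for _, g in table.groupby("cell_id"):
        g = g.sort_values("session")
        rows = list(g.itertuples(index=False))
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                if not (rows[i].significant or rows[j].significant):
                    continue
                d_tuning.append(rows[j].strength - rows[i].strength)
                d_acc.append(rows[j].model_acc - rows[i].model_acc)
    if len(d_tuning) < 3:
        return {"r": float("nan"), "p_value": float("nan"), "n_pairs": len(d_tuning),
                "defined": False}
    r, p = stats.pearsonr(d_acc, d_tuning)
    return {"r": float(r), "p_value": float(p), "n_pairs": len(d_tuning), "defined": True}
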