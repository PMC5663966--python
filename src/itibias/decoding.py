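"""Population decoding of internal bias and trial-history variables.

ITI population activity (cells x pre-stimulus epochs) is related to the
behavioral model's internal bias by stepwise-selected linear regression,
and to binary variables (upcoming choice, previous outcome/choice) by a
logistic classifier, both scored with 10-fold cross-validation. The signed
Euclidean distance of each trial's activity from the choice classifier's
decision boundary serves as a neural proxy of the bias, and the difference
between decoding from the full activity and from its 1-D bias-axis
projection quantifies history information beyond the bias.

Feature selection follows the stepwise partial-F procedure (entry p < 0.05,
removal p > 0.10). By default selection runs once on all trials before
cross-validation — matching the original analysis — with a "strict" mode
that reselects within every training fold for methodological hygiene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from .history import fit_logistic


@dataclass
class DecodeResult:
    target: str
    selected: np.ndarray          # column indices of the offered feature matrix
    cv_metric: str                # "r2" or "accuracy"
    cv_value: float
    per_trial_prediction: np.ndarray
    weights: np.ndarray           # over selected features
    constant: float
    flags: list = field(default_factory=list)


def _ols(X: np.ndarray, y: np.ndarray):
    Xd = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    return beta, float(resid @ resid)


def stepwise_select(
    X: np.ndarray,
    y: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_iter: int = 200,
) -> np.ndarray:
    """Forward-entry / backward-removal stepwise linear selection.

    Candidates enter by the smallest partial-F p-value below ``p_enter``
    and leave when their partial-F p-value exceeds ``p_remove``.
    Deterministic; may select the empty set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    selected: list[int] = []
    for _ in range(max_iter):
        changed = False
        # forward step
        _, rss0 = _ols(X[:, selected], y) if selected else (None, float(np.sum((y - y.mean()) ** 2)))
        best = (None, 1.0)
        for j in range(m):
            if j in selected:
                continue
            dof = n - (len(selected) + 2)
            if dof < 1:
                break
            _, rss1 = _ols(X[:, selected + [j]], y)
            if rss1 <= 0:
                p = 0.0
            else:
                f = (rss0 - rss1) / (rss1 / dof)
                p = float(stats.f.sf(max(f, 0.0), 1, dof))
            if p < best[1]:
                best = (j, p)
        if best[0] is not None and best[1] < p_enter:
            selected.append(best[0])
            changed = True
        # backward step
        if len(selected) > 1:
            _, rss_full = _ols(X[:, selected], y)
            dof = n - (len(selected) + 1)
            worst = (None, 0.0)
            for j in selected:
                rest = [k for k in selected if k != j]
                _, rss_r = _ols(X[:, rest], y)
                if rss_full <= 0:
                    p = 0.0
                else:
                    f = (rss_r - rss_full) / (rss_full / dof)
                    p = float(stats.f.sf(max(f, 0.0), 1, dof))
                if p > worst[1]:
                    worst = (j, p)
            if worst[0] is not None and worst[1] > p_remove:
                selected.remove(worst[0])
                changed = True
        if not changed:
            break
    return np.asarray(sorted(selected), dtype=int)


class StepwiseLinearDecoder(BaseEstimator, RegressorMixin):
    """Stepwise-selected ordinary least squares.

    Attributes after fit: ``selected_`` (feature indices), ``coef_`` (over
    selected features), ``intercept_``.
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10):
        self.p_enter = p_enter
        self.p_remove = p_remove

    def fit(self, X, y, selected: Optional[np.ndarray] = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if selected is None:
            selected = stepwise_select(X, y, self.p_enter, self.p_remove)
        self.selected_ = np.asarray(selected, dtype=int)
        if len(self.selected_):
            beta, _ = _ols(X[:, self.selected_], y)
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:]
        else:
            self.intercept_ = float(y.mean())
            self.coef_ = np.zeros(0)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.selected_] @ self.coef_ + self.intercept_


class StepwiseLogisticDecoder(BaseEstimator, ClassifierMixin):
    """Stepwise feature selection followed by a logistic classifier.

    Selection uses the linear stepwise procedure on the signed (+1/-1)
    target; the classifier is a maximum-likelihood logistic fit, and
    prediction is +1 iff the predicted probability exceeds 0.5.
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10, ridge: float = 1e-6):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.ridge = ridge

    def fit(self, X, y, selected: Optional[np.ndarray] = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {-1.0, 1.0}:
            raise ValueError("target must be coded +1/-1")
        if len(np.unique(y)) < 2:
            raise ValueError("single-class target")
        if selected is None:
            selected = stepwise_select(X, y, self.p_enter, self.p_remove)
        self.selected_ = np.asarray(selected, dtype=int)
        if len(self.selected_):
            fit = fit_logistic(X[:, self.selected_], y, ridge=self.ridge)
            self.coef_ = fit["weights"]
            self.intercept_ = fit["constant"]
        else:
            base = np.log((np.mean(y == 1) + 1e-12) / (np.mean(y == -1) + 1e-12))
            self.coef_ = np.zeros(0)
            self.intercept_ = float(base)
        self.classes_ = np.array([-1.0, 1.0])
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.selected_] @ self.coef_ + self.intercept_

    def predict_proba_forward(self, X):
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    def predict(self, X):
        return np.where(self.decision_function(X) > 0, 1.0, -1.0)


def _contiguous_folds(n: int, n_folds: int):
    return [f for f in np.array_split(np.arange(n), n_folds) if len(f)]


def fit_bias_regression(
    features: np.ndarray,
    bias: np.ndarray,
    n_folds: int = 10,
    mode: str = "pooled",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> DecodeResult:
    """Cross-validated linear fit of the internal bias from ITI features.

    Returns the held-out r^2 pooled over folds. With ``mode="pooled"``
    selection runs once on all trials; ``mode="strict"`` reselects within
    each training fold. An empty selection yields r^2 = 0 with a flag.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(bias, dtype=float)
    flags: list[str] = []
    selected_all = stepwise_select(X, y, p_enter, p_remove) if mode == "pooled" else None
    pred = np.full(len(y), np.nan)
    for fold in _contiguous_folds(len(y), n_folds):
        train = np.delete(np.arange(len(y)), fold)
        dec = StepwiseLinearDecoder(p_enter, p_remove)
        dec.fit(X[train], y[train], selected=selected_all)
        pred[fold] = dec.predict(X[fold])
    final = StepwiseLinearDecoder(p_enter, p_remove).fit(X, y, selected=selected_all)
    if len(final.selected_) == 0:
        flags.append("empty feature selection")
        r2 = 0.0
    else:
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return DecodeResult(
        target="internal_bias", selected=final.selected_, cv_metric="r2",
        cv_value=r2, per_trial_prediction=pred, weights=final.coef_,
        constant=final.intercept_, flags=flags,
    )


def fit_classifier(
    features: np.ndarray,
    target: np.ndarray,
    n_folds: int = 10,
    mode: str = "pooled",
    target_name: str = "binary",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    ridge: float = 1e-6,
) -> DecodeResult:
    """Cross-validated logistic decoding of a signed binary variable."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class target")
    selected_all = stepwise_select(X, y, p_enter, p_remove) if mode == "pooled" else None
    pred = np.full(len(y), np.nan)
    for fold in _contiguous_folds(len(y), n_folds):
        train = np.delete(np.arange(len(y)), fold)
        if len(np.unique(y[train])) < 2:
            continue
        dec = StepwiseLogisticDecoder(p_enter, p_remove, ridge)
        dec.fit(X[train], y[train], selected=selected_all)
        pred[fold] = dec.predict(X[fold])
    final = StepwiseLogisticDecoder(p_enter, p_remove, ridge).fit(X, y, selected=selected_all)
    evaluated = np.isfinite(pred)
    acc = float(np.mean(pred[evaluated] == y[evaluated])) if evaluated.any() else float("nan")
    return DecodeResult(
        target=target_name, selected=final.selected_, cv_metric="accuracy",
        cv_value=acc, per_trial_prediction=pred, weights=final.coef_,
        constant=final.intercept_,
        flags=[] if len(final.selected_) else ["empty feature selection"],
    )


def boundary_distance(features: np.ndarray, classifier) -> np.ndarray:
    """Signed Euclidean distance of each trial from the decision boundary.

    distance = (w . x + const) / ||w||; positive on the forward side.
    ``classifier`` is a fitted StepwiseLogisticDecoder or DecodeResult.
    """
    if isinstance(classifier, DecodeResult):
        w, b, sel = classifier.weights, classifier.constant, classifier.selected
    else:
        w, b, sel = classifier.coef_, classifier.intercept_, classifier.selected_
    norm = float(np.linalg.norm(w))
    if norm == 0:
        raise ValueError("zero weight vector has no decision boundary")
    X = np.asarray(features, dtype=float)
    return (X[:, sel] @ w + b) / norm


def bias_conditioned_psychometric(
    distances: np.ndarray,
    choices: np.ndarray,
    stimuli: np.ndarray,
    n_bins: int = 5,
) -> dict:
    """Fraction of forward choices per (z-scored, equi-populated) bias bin,
    separately for forward- and downward-stimulus trials."""
    d = np.asarray(distances, dtype=float)
    if len(d) < n_bins * 10:
        raise ValueError(f"need at least {n_bins * 10} trials for {n_bins} bins")
    z = (d - d.mean()) / d.std()
    edges = np.quantile(z, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    bins = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, n_bins - 1)
    out = {"bin_centers": np.array([z[bins == b].mean() if (bins == b).any() else np.nan
                                    for b in range(n_bins)])}
    for s, key in ((1, "forward_stim"), (-1, "downward_stim")):
        fr = np.full(n_bins, np.nan)
        for b in range(n_bins):
            m = (bins == b) & (np.asarray(stimuli) == s)
            if m.any():
                fr[b] = float(np.mean(np.asarray(choices)[m] == 1))
        out[key] = fr
    return out


def independent_history_info(
    features: np.ndarray,
    bias_result: DecodeResult,
    target: np.ndarray,
    n_folds: int = 10,
    target_name: str = "history",
    **kwargs,
) -> dict:
    """History information in the ITI activity beyond the internal bias.

    accuracy(classifier on the full features) minus accuracy(classifier on
    the 1-D projection onto the bias axis from ``bias_result``); positive
    values indicate history coding that the bias axis cannot carry.
    """
    X = np.asarray(features, dtype=float)
    full = fit_classifier(X, target, n_folds=n_folds, target_name=target_name, **kwargs)
    if len(bias_result.selected) == 0:
        raise ValueError("bias regression selected no features; no bias axis")
    projection = (X[:, bias_result.selected] @ bias_result.weights)[:, None]
    proj = fit_classifier(projection, target, n_folds=n_folds,
                          target_name=f"{target_name}|bias_axis", **kwargs)
    return {
        "acc_full": full.cv_value,
        "acc_bias_axis": proj.cv_value,
        "difference": full.cv_value - proj.cv_value,
        "full": full,
        "projected": proj,
    }
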