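"""Trial-history logistic choice model with exponentially discounted kernels.

The model predicts the log-odds of a forward choice on trial N as

    w_s * stimulus(N)
  + w_o  * sum_{k<N} outcome(k)            * exp(-(N-1-k)/tau_o)
  + w_c  * sum_{k<N} choice(k)             * exp(-(N-1-k)/tau_c)
  + w_oc * sum_{k<N} outcome(k)*choice(k)  * exp(-(N-1-k)/tau_oc)
  + constant

Outcome/choice history enters from *all* preceding trials of the session
(including no-response trials, coded choice 0 / outcome +1), while choices
are predicted only on trials in which a target was reached. Weights are
maximum-likelihood logistic coefficients (with a tiny ridge as a numerical
guard against separable sessions); the per-variable time constants are
selected by grid search maximizing 10-fold cross-validated prediction
accuracy. Predicted choice is +1 when the predicted probability exceeds
0.5 and -1 otherwise.

The per-trial sum of all terms except the current stimulus is the model's
estimate of the internal bias (in log-odds of a forward choice).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .session import Session

DEFAULT_TAU_GRID: tuple[float, ...] = (0.01, 0.03, 0.1, 0.3, 1.0, 2.0, 3.0, 5.0, 10.0, 20.0, 50.0, 100.0)
TAU_BOUNDS = (0.01, 100.0)
ALL_VARIABLES: tuple[str, ...] = ("s", "o", "c", "oc")
HISTORY_VARIABLES: tuple[str, ...] = ("o", "c", "oc")


class InestimableSessionError(ValueError):
    """Logistic regression on a single-class choice sequence is unreliable."""


@dataclass
class ModelParams:
    """Weights and time constants of the history choice model."""

    w_s: float = 0.0
    w_o: float = 0.0
    w_c: float = 0.0
    w_oc: float = 0.0
    constant: float = 0.0
    tau_o: float = 1.0
    tau_c: float = 1.0
    tau_oc: float = 1.0

    def weight(self, var: str) -> float:
        return {"s": self.w_s, "o": self.w_o, "c": self.w_c, "oc": self.w_oc}[var]

    def tau(self, var: str) -> float:
        return {"o": self.tau_o, "c": self.tau_c, "oc": self.tau_oc}[var]

    def as_dict(self) -> dict:
        return {
            "w_s": self.w_s, "w_o": self.w_o, "w_c": self.w_c, "w_oc": self.w_oc,
            "constant": self.constant,
            "tau_o": self.tau_o, "tau_c": self.tau_c, "tau_oc": self.tau_oc,
        }


@dataclass
class FitResult:
    """Outcome of fitting the history model to one session."""

    params: ModelParams
    variables_used: tuple[str, ...]
    cv_accuracy: float
    fold_assignment: np.ndarray  # -1 for trials excluded from prediction
    p_forward: np.ndarray        # per-trial predicted P(forward), NaN on excluded
    bias: np.ndarray             # per-trial internal bias (log-odds), all trials
    log_likelihood: float
    n_included: int
    warnings: list = field(default_factory=list)


def _extract(trials) -> pd.DataFrame:
    if isinstance(trials, Session):
        return trials.trials
    if isinstance(trials, pd.DataFrame):
        return trials
    raise TypeError("expected a Session or a canonical trial DataFrame")


def build_regressors(trials, tau_o: float = 1.0, tau_c: float = 1.0, tau_oc: float = 1.0) -> dict:
    """Per-trial regressors {stim, O, C, I} for the history model.

    ``trials`` is a Session, canonical DataFrame, or dict of arrays with keys
    stimulus/choice/outcome covering the *full* session in order (no-response
    trials included). Computed by the exact recurrence
    O(N) = O(N-1) * exp(-1/tau) + outcome(N-1), O(1) = 0.
    """
    for tau in (tau_o, tau_c, tau_oc):
        if not tau > 0:
            raise ValueError("time constants must be positive")
    if isinstance(trials, dict):
        stim = np.asarray(trials["stimulus"], dtype=float)
        choice = np.asarray(trials["choice"], dtype=float)
        outcome = np.asarray(trials["outcome"], dtype=float)
    else:
        df = _extract(trials)
        stim = df["stimulus"].to_numpy(dtype=float)
        choice = df["choice"].to_numpy(dtype=float)
        outcome = df["outcome"].to_numpy(dtype=float)
    out = {
        "stim": stim,
        "O": _discounted_sum(outcome, tau_o),
        "C": _discounted_sum(choice, tau_c),
        "I": _discounted_sum(outcome * choice, tau_oc),
    }
    if not all(np.isfinite(v).all() for v in out.values()):
        raise ValueError("non-finite regressors")
    return out


def _discounted_sum(x: np.ndarray, tau: float) -> np.ndarray:
    d = np.exp(-1.0 / tau)
    out = np.zeros_like(x)
    for n in range(1, len(x)):
        out[n] = out[n - 1] * d + x[n - 1]
    return out


_VAR_TO_REG = {"s": "stim", "o": "O", "c": "C", "oc": "I"}


def _design(regressors: dict, variables: Sequence[str]) -> np.ndarray:
    if len(variables) == 0:
        return np.empty((len(regressors["stim"]), 0))
    return np.column_stack([regressors[_VAR_TO_REG[v]] for v in variables])


def fit_logistic(X: np.ndarray, choices: np.ndarray, ridge: float = 1e-6) -> dict:
    """Maximum-likelihood logistic fit of signed choices (+1/-1) on X.

    A tiny ridge penalty on the weights (never the constant) keeps separable
    sessions finite; the returned log-likelihood is unpenalized.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and len(choices) != 1:
        X = X.T
    y = np.asarray(choices, dtype=float)
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("choices must be coded +1/-1")
    if len(np.unique(y)) < 2:
        raise InestimableSessionError(
            "single-class choice sequence: logistic weights are inestimable"
        )
    n, k = X.shape

    def objective(theta):
        w, b = theta[:k], theta[k]
        z = X @ w + b
        yz = y * z
        # log(1 + exp(-yz)) computed stably
        nll = np.sum(np.logaddexp(0.0, -yz))
        p = 1.0 / (1.0 + np.exp(np.clip(yz, -500, 500)))  # sigma(-yz)
        grad_z = -y * p
        grad = np.empty(k + 1)
        grad[:k] = X.T @ grad_z + ridge * w
        grad[k] = grad_z.sum()
        return nll + 0.5 * ridge * np.dot(w, w), grad

    theta0 = np.zeros(k + 1)
    res = optimize.minimize(objective, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    w, b = res.x[:k], res.x[k]
    z = X @ w + b
    ll = -float(np.sum(np.logaddexp(0.0, -y * z)))
    return {"weights": w, "constant": float(b), "log_likelihood": ll}


def _predict_sign(z: np.ndarray) -> np.ndarray:
    """Predicted choice: +1 iff P(forward) > 0.5, else -1 (ties to -1)."""
    return np.where(z > 0, 1, -1)


def _contiguous_folds(n: int, n_folds: int) -> list[np.ndarray]:
    return [f for f in np.array_split(np.arange(n), n_folds) if len(f)]


def cv_accuracy(
    session,
    params: ModelParams,
    variables_used: Sequence[str] = ALL_VARIABLES,
    n_folds: int = 10,
    ridge: float = 1e-6,
    extra_eval_pos: Optional[np.ndarray] = None,
    include_pos: Optional[np.ndarray] = None,
) -> dict:
    """Cross-validated prediction accuracy at fixed time constants.

    Included trials (choice != 0, or the explicit ``include_pos`` positions)
    are split into ``n_folds`` contiguous blocks in trial order; each block is
    predicted once from weights fit on the remaining blocks. Folds whose
    training set has a single choice class are skipped with a warning.

    ``extra_eval_pos`` (session positions) are additionally predicted by every
    fold's model; their mean accuracy across folds is returned separately
    (used for light-on transfer).
    """
    df = _extract(session)
    regs = build_regressors(df, params.tau_o, params.tau_c, params.tau_oc)
    choices = df["choice"].to_numpy(dtype=float)
    X = _design(regs, variables_used)
    if include_pos is None:
        include_pos = np.flatnonzero(choices != 0)
    include_pos = np.asarray(include_pos)
    if len(include_pos) < n_folds:
        raise ValueError(f"need >= {n_folds} included trials, got {len(include_pos)}")

    folds = _contiguous_folds(len(include_pos), n_folds)
    fold_assignment = np.full(len(df), -1, dtype=int)
    p_forward = np.full(len(df), np.nan)
    msgs: list[str] = []
    n_correct = 0
    n_eval = 0
    heldout_ll = 0.0
    extra_accs = []
    for fi, fold in enumerate(folds):
        test_pos = include_pos[fold]
        train_pos = np.delete(include_pos, fold)
        y_train = choices[train_pos]
        if len(np.unique(y_train)) < 2:
            msgs.append(f"fold {fi}: single-class training set, skipped")
            warnings.warn(msgs[-1], stacklevel=2)
            continue
        fit = fit_logistic(X[train_pos], y_train, ridge=ridge)
        z = X[test_pos] @ fit["weights"] + fit["constant"]
        pred = _predict_sign(z)
        n_correct += int(np.sum(pred == choices[test_pos]))
        n_eval += len(test_pos)
        heldout_ll += -float(np.sum(np.logaddexp(0.0, -choices[test_pos] * z)))
        fold_assignment[test_pos] = fi
        p_forward[test_pos] = 1.0 / (1.0 + np.exp(-z))
        if extra_eval_pos is not None and len(extra_eval_pos):
            ze = X[extra_eval_pos] @ fit["weights"] + fit["constant"]
            extra_accs.append(np.mean(_predict_sign(ze) == choices[extra_eval_pos]))
    if n_eval == 0:
        raise InestimableSessionError("all folds skipped: choices nearly constant")
    out = {
        "accuracy": n_correct / n_eval,
        "heldout_ll": heldout_ll,
        "fold_assignment": fold_assignment,
        "p_forward": p_forward,
        "warnings": msgs,
    }
    if extra_eval_pos is not None:
        out["extra_accuracy"] = float(np.mean(extra_accs)) if extra_accs else float("nan")
    return out


def _tau_combinations(variables_used, tau_grid):
    active = [v for v in HISTORY_VARIABLES if v in variables_used]
    grid = sorted(tau_grid)
    for combo in itertools.product(grid, repeat=len(active)):
        taus = {"tau_o": 1.0, "tau_c": 1.0, "tau_oc": 1.0}
        for v, t in zip(active, combo):
            taus[f"tau_{v}"] = t
        yield taus


def grid_search_fit(
    session,
    variables_used: Sequence[str] = ALL_VARIABLES,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    n_folds: int = 10,
    ridge: float = 1e-6,
) -> FitResult:
    """Fit the history model: grid search over time constants maximizing
    cross-validated accuracy, then refit weights on all included trials.

    Exact ties in CV accuracy (common, since accuracy is a 0/1 loss) are
    broken by the held-out log-likelihood, then toward smaller time constants
    (lexicographically over the active history variables).
    """
    tau_grid = tuple(tau_grid)
    if not tau_grid:
        raise ValueError("tau_grid must be nonempty")
    if any(t < TAU_BOUNDS[0] or t > TAU_BOUNDS[1] for t in tau_grid):
        raise ValueError(f"tau_grid values must lie in [{TAU_BOUNDS[0]}, {TAU_BOUNDS[1]}]")
    variables_used = tuple(variables_used)
    df = _extract(session)

    best = None
    for taus in _tau_combinations(variables_used, tau_grid):
        params = ModelParams(**taus)
        cv = cv_accuracy(df, params, variables_used, n_folds=n_folds, ridge=ridge)
        if best is None:
            best = (cv, taus)
            continue
        d_acc = cv["accuracy"] - best[0]["accuracy"]
        if d_acc > 1e-12 or (abs(d_acc) <= 1e-12 and cv["heldout_ll"] > best[0]["heldout_ll"] + 1e-9):
            best = (cv, taus)
    cv, taus = best

    params = ModelParams(**taus)
    regs = build_regressors(df, params.tau_o, params.tau_c, params.tau_oc)
    choices = df["choice"].to_numpy(dtype=float)
    include = choices != 0
    X = _design(regs, variables_used)
    fit = fit_logistic(X[include], choices[include], ridge=ridge)
    for v, w in zip(variables_used, fit["weights"]):
        setattr(params, f"w_{v}", float(w))
    params.constant = fit["constant"]

    bias = internal_bias_from_params(regs, params, variables_used)
    z_all = bias + (params.w_s * regs["stim"] if "s" in variables_used else 0.0)
    p_all = np.full(len(df), np.nan)
    p_all[include] = 1.0 / (1.0 + np.exp(-z_all[include]))
    return FitResult(
        params=params,
        variables_used=variables_used,
        cv_accuracy=cv["accuracy"],
        fold_assignment=cv["fold_assignment"],
        p_forward=p_all,
        bias=bias,
        log_likelihood=fit["log_likelihood"],
        n_included=int(include.sum()),
        warnings=cv["warnings"],
    )


def internal_bias_from_params(regressors: dict, params: ModelParams,
                              variables_used: Sequence[str] = ALL_VARIABLES) -> np.ndarray:
    """Internal bias per trial: all model terms except the current stimulus."""
    bias = np.full(len(regressors["stim"]), params.constant, dtype=float)
    if "o" in variables_used:
        bias += params.w_o * regressors["O"]
    if "c" in variables_used:
        bias += params.w_c * regressors["C"]
    if "oc" in variables_used:
        bias += params.w_oc * regressors["I"]
    return bias


def internal_bias(session, fit: FitResult) -> np.ndarray:
    """Per-trial internal bias series (log-odds of forward, stimulus excluded)."""
    p = fit.params
    regs = build_regressors(_extract(session), p.tau_o, p.tau_c, p.tau_oc)
    return internal_bias_from_params(regs, p, fit.variables_used)


def likelihood_ratio_test(full: FitResult, partial: FitResult, count_taus: bool = False) -> dict:
    """Likelihood-ratio test between nested history models.

    The statistic 2*(LL_full - LL_partial) is referred to a chi-square whose
    df is the difference in the number of fitted weights; time constants are
    treated as model selection, not free parameters (``count_taus=True``
    additionally counts them).
    """
    if not set(partial.variables_used) <= set(full.variables_used):
        raise ValueError("partial model variables must be a subset of the full model's")
    stat = 2.0 * (full.log_likelihood - partial.log_likelihood)
    if stat < -1e-6:
        raise ValueError("LL_full < LL_partial: models are not nested as claimed")
    stat = max(stat, 0.0)
    df = len(full.variables_used) - len(partial.variables_used)
    if count_taus:
        df += sum(v in HISTORY_VARIABLES for v in full.variables_used) - sum(
            v in HISTORY_VARIABLES for v in partial.variables_used)
    if df == 0:
        return {"statistic": stat, "df": 0, "p_value": 1.0}
    return {"statistic": stat, "df": df, "p_value": float(stats.chi2.sf(stat, df))}


@dataclass
class AdaptivenessLabel:
    label: str  # adaptive | neutral | maladaptive
    sim_fractions: np.ndarray


def classify_adaptiveness(
    history_params: ModelParams,
    n_trials: int = 250,
    n_sim: int = 100,
    rng=None,
    variables_used: Sequence[str] = HISTORY_VARIABLES,
) -> AdaptivenessLabel:
    """Simulate the history-only policy under the task's stimulus rules.

    Adaptive if the correctly-discriminating fraction exceeds 0.5 in more
    than 95% of ``n_sim`` simulated sessions, maladaptive if below 0.5 in
    more than 95%, neutral otherwise. The stimulus weight is ignored.
    """
    from .agent import AgentSpec, simulate_agent_session  # local to avoid cycle

    rng = np.random.default_rng() if rng is None else rng
    params = ModelParams(**history_params.as_dict())
    params.w_s = 0.0
    spec = AgentSpec(params=params)
    fracs = np.empty(n_sim)
    for i in range(n_sim):
        sess = simulate_agent_session(spec, n_trials, rng=rng, with_times=False)
        fracs[i] = np.mean(sess.choice == sess.stimulus)
    frac_above = np.mean(fracs > 0.5)
    frac_below = np.mean(fracs < 0.5)
    if frac_above > 0.95:
        label = "adaptive"
    elif frac_below > 0.95:
        label = "maladaptive"
    else:
        label = "neutral"
    return AdaptivenessLabel(label=label, sim_fractions=fracs)


def lightoff_model_transfer(
    session,
    variables_used: Sequence[str] = HISTORY_VARIABLES,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    n_folds: int = 10,
    ridge: float = 1e-6,
) -> dict:
    """Fit on light-off trials, test on held-out light-off vs light-on trials.

    Time constants are selected by grid search with CV restricted to light-off
    included trials; then the light-off folds are rotated, each fold's model
    predicting both its held-out light-off trials and all light-on trials.
    History regressors are always computed from the true preceding trials of
    the full session.
    """
    df = _extract(session)
    choices = df["choice"].to_numpy(dtype=float)
    light = df["light"].to_numpy(dtype=bool)
    off_pos = np.flatnonzero((choices != 0) & ~light)
    on_pos = np.flatnonzero((choices != 0) & light)
    result_warnings = []
    if len(on_pos) == 0:
        return {"acc_on_heldout_off": float("nan"), "acc_on_light_on": float("nan"),
                "degenerate": True, "warnings": ["no light-on trials"]}
    if len(on_pos) < 10:
        result_warnings.append(f"only {len(on_pos)} light-on trials")

    best = None
    for taus in _tau_combinations(variables_used, tau_grid):
        params = ModelParams(**taus)
        cv = cv_accuracy(df, params, variables_used, n_folds=n_folds, ridge=ridge,
                         include_pos=off_pos, extra_eval_pos=on_pos)
        if best is None or cv["accuracy"] > best["accuracy"] + 1e-12:
            best = cv
            best_taus = taus
    return {
        "acc_on_heldout_off": best["accuracy"],
        "acc_on_light_on": best["extra_accuracy"],
        "taus": best_taus,
        "n_light_on": len(on_pos),
        "n_light_off": len(off_pos),
        "degenerate": False,
        "warnings": result_warnings + best["warnings"],
    }


def weight_change_zscores(
    session,
    n_resample: int = 100,
    rng=None,
    variables_used: Sequence[str] = ALL_VARIABLES,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    n_folds: int = 10,
    ridge: float = 1e-6,
) -> dict:
    """Per-parameter z-score of light-on weight magnitudes against a null of
    size-matched light-off refits.

    Time constants are fixed from a fit to the whole session; a full set of
    weights is then refit on the light-on trials and on ``n_resample`` random
    light-off subsets matched in trial count. For each weight (and constant),
    z = (|w|_on - mean(|w|_off)) / sd(|w|_off).
    """
    if n_resample < 1:
        raise ValueError("n_resample must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    df = _extract(session)
    choices = df["choice"].to_numpy(dtype=float)
    light = df["light"].to_numpy(dtype=bool)
    on_pos = np.flatnonzero((choices != 0) & light)
    off_pos = np.flatnonzero((choices != 0) & ~light)
    if len(np.unique(choices[on_pos])) < 2:
        raise InestimableSessionError("single-class choices on light-on trials; session excluded")

    base = grid_search_fit(df, variables_used, tau_grid=tau_grid, n_folds=n_folds, ridge=ridge)
    p = base.params
    regs = build_regressors(df, p.tau_o, p.tau_c, p.tau_oc)
    X = _design(regs, variables_used)

    def magnitudes(pos):
        fit = fit_logistic(X[pos], choices[pos], ridge=ridge)
        return np.abs(np.append(fit["weights"], fit["constant"]))

    mag_on = magnitudes(on_pos)
    n_on = len(on_pos)
    null = []
    attempts = 0
    while len(null) < n_resample and attempts < 20 * n_resample:
        attempts += 1
        pos = np.sort(rng.choice(off_pos, size=n_on, replace=False))
        if len(np.unique(choices[pos])) < 2:
            continue
        null.append(magnitudes(pos))
    if len(null) < n_resample:
        raise InestimableSessionError("could not draw enough estimable light-off subsets")
    null = np.asarray(null)
    sd = null.std(axis=0, ddof=1)
    z = (mag_on - null.mean(axis=0)) / np.where(sd > 0, sd, np.nan)
    names = [f"w_{v}" for v in variables_used] + ["constant"]
    return {"z": dict(zip(names, z)), "mag_on": dict(zip(names, mag_on)),
            "taus": {k: v for k, v in p.as_dict().items() if k.startswith("tau")}}


def bootstrap_mean_test(values, n_boot: int = 1000, ci: float = 0.95, rng=None) -> dict:
    """Percentile bootstrap CI of the mean; significant iff the CI excludes 0."""
    rng = np.random.default_rng() if rng is None else rng
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return {
        "mean": float(values.mean()),
        "ci_lo": float(lo),
        "ci_hi": float(hi),
        "significant": bool(lo > 0 or hi < 0),
    }


class HistoryChoiceModel(BaseEstimator):
    """Sklearn-style estimator for the trial-history logistic choice model.

    Parameters
    ----------
    variables : tuple of {"s", "o", "c", "oc"}
        Model terms to include (the constant is always fitted).
    tau_grid : sequence of float
        Candidate time constants (trials) searched for each history variable.
    n_folds : int
        Folds for the contiguous-block cross-validation.
    ridge : float
        Tiny L2 guard on the weights (not the constant).

    Attributes (after ``fit``)
    --------------------------
    params_ : ModelParams
    cv_accuracy_ : float
    bias_ : ndarray — per-trial internal bias (log-odds)
    p_forward_ : ndarray — per-trial predicted P(forward), NaN on excluded trials
    log_likelihood_ : float
    result_ : FitResult
    """

    def __init__(self, variables=ALL_VARIABLES, tau_grid=DEFAULT_TAU_GRID,
                 n_folds: int = 10, ridge: float = 1e-6):
        self.variables = variables
        self.tau_grid = tau_grid
        self.n_folds = n_folds
        self.ridge = ridge

    def fit(self, X, y=None) -> "HistoryChoiceModel":
        """Fit to a Session (or canonical trial DataFrame); y is ignored."""
        result = grid_search_fit(X, self.variables, tau_grid=self.tau_grid,
                                 n_folds=self.n_folds, ridge=self.ridge)
        self.result_ = result
        self.params_ = result.params
        self.cv_accuracy_ = result.cv_accuracy
        self.bias_ = result.bias
        self.p_forward_ = result.p_forward
        self.log_likelihood_ = result.log_likelihood
        self.n_included_ = result.n_included
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise AttributeError("HistoryChoiceModel is not fitted yet")

    def decision_function(self, X) -> np.ndarray:
        """Per-trial log-odds of a forward choice."""
        self._check_fitted()
        p = self.params_
        regs = build_regressors(_extract(X), p.tau_o, p.tau_c, p.tau_oc)
        z = internal_bias_from_params(regs, p, self.variables)
        if "s" in self.variables:
            z = z + p.w_s * regs["stim"]
        return z

    def predict_proba(self, X) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    def predict(self, X) -> np.ndarray:
        """Predicted signed choice: +1 iff P(forward) > 0.5, else -1."""
        return _predict_sign(self.decision_function(X))

    def score(self, X, y=None) -> float:
        """Accuracy on included (choice != 0) trials of X."""
        df = _extract(X)
        choices = df["choice"].to_numpy()
        m = choices != 0
        return float(np.mean(self.predict(df)[m] == choices[m]))
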