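"""Generative synthetic subject whose choices follow the history model.

The agent draws stimuli from the task's pseudo-random rules and chooses
according to the logistic history model with known ground-truth parameters,
optionally perturbed on light-on trials (multiplicative scaling of weights,
emulating optogenetic inactivation of the bias signal). It is the ground
truth for all parameter-recovery and inactivation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .history import ModelParams, build_regressors
from .session import TRIAL_COLUMNS, Session
from .task import StimulusRuleState, next_stimulus

_WEIGHT_KEYS = ("s", "o", "c", "oc", "constant")


@dataclass
class AgentSpec:
    """Generative parameters of a synthetic subject.

    light_effect maps weight names ("s", "o", "c", "oc", "constant") to a
    multiplicative scale applied on light-on trials; missing keys default
    to 1.0 (no perturbation).
    """

    params: ModelParams
    lapse: float = 0.0
    light_effect: dict = field(default_factory=dict)
    no_response_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")
        if not 0.0 <= self.no_response_rate <= 1.0:
            raise ValueError("no_response_rate must lie in [0, 1]")
        for k, v in self.light_effect.items():
            if k not in _WEIGHT_KEYS:
                raise ValueError(f"unknown light_effect key {k!r}")
            if not np.isfinite(v):
                raise ValueError("light_effect scalings must be finite")

    def scale(self, key: str, light: bool) -> float:
        return self.light_effect.get(key, 1.0) if light else 1.0


def choice_probability(history, stimulus: int, params: ModelParams) -> float:
    """P(forward) for the current trial given the preceding trial history.

    ``history`` is a Session, trial DataFrame, or dict of stimulus/choice/
    outcome arrays for all preceding trials in order (may be empty).
    """
    if isinstance(history, dict):
        hist = {k: np.asarray(v, dtype=float) for k, v in history.items()}
    else:
        df = history.trials if isinstance(history, Session) else history
        hist = {k: df[k].to_numpy(dtype=float) for k in ("stimulus", "choice", "outcome")}
    # append a placeholder current trial; its regressor row sums the history
    ext = {k: np.append(v, 0.0) for k, v in hist.items()}
    regs = build_regressors(ext, params.tau_o, params.tau_c, params.tau_oc)
    z = (params.w_s * stimulus + params.w_o * regs["O"][-1]
         + params.w_c * regs["C"][-1] + params.w_oc * regs["I"][-1] + params.constant)
    if not np.isfinite(z):
        raise ValueError("non-finite log-odds from history regressors")
    return float(1.0 / (1.0 + np.exp(-z)))


def simulate_agent_session(
    spec: AgentSpec,
    n_trials: int,
    light: Optional[Sequence[bool]] = None,
    rng=None,
    iti_seconds: float = 8.0,
    session_id: str = "synthetic",
    with_times: bool = True,
) -> Session:
    """Simulate a full session: task stimulus rules + history-model chooser.

    On light-on trials each weight is scaled by the agent's light_effect.
    With probability ``no_response_rate`` the trial is a no-response (choice
    0, outcome error); with probability ``lapse`` the choice is uniform.
    Event times follow the task schedule (ITI, 1 s stimulus, 2 s memory,
    go cue, reach) with small reaction-time jitter when ``with_times``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    light = np.zeros(n_trials, dtype=bool) if light is None else np.asarray(light, dtype=bool)
    if len(light) != n_trials:
        raise ValueError("light flags length must equal n_trials")

    p0 = spec.params
    d_o, d_c, d_i = (np.exp(-1.0 / p0.tau_o), np.exp(-1.0 / p0.tau_c), np.exp(-1.0 / p0.tau_oc))
    O = C = I = 0.0
    state = StimulusRuleState()
    rows = []
    t = 0.0
    for n in range(n_trials):
        on = bool(light[n])
        s = next_stimulus(state, rng)
        z = (p0.w_s * spec.scale("s", on) * s
             + p0.w_o * spec.scale("o", on) * O
             + p0.w_c * spec.scale("c", on) * C
             + p0.w_oc * spec.scale("oc", on) * I
             + p0.constant * spec.scale("constant", on))
        p = 1.0 / (1.0 + np.exp(-z))
        u = rng.random()
        if u < spec.no_response_rate:
            choice = 0
        elif u < spec.no_response_rate + spec.lapse:
            choice = int(rng.choice((-1, 1)))
        else:
            choice = 1 if rng.random() < p else -1
        outcome = -1 if choice == s else 1

        if with_times:
            t_stim_on = t + iti_seconds
            t_go = t_stim_on + 3.0  # 1 s stimulus + 2 s memory
            if choice != 0:
                rt = float(np.clip(rng.normal(0.35, 0.08), 0.1, 0.9))
                move_dur = float(np.clip(rng.normal(0.18, 0.04), 0.05, 0.5))
                t_move_on = t_go + rt
                t_target = t_move_on + move_dur
                t_reward = t_target if outcome == -1 else np.nan
                t = t_target + 0.5
            else:
                t_move_on = t_target = t_reward = np.nan
                t = t_go + 1.5
            times = (t_stim_on, t_go, t_move_on, t_target, t_reward)
        else:
            times = (np.nan,) * 5

        rows.append((n + 1, s, choice, outcome, on, False, *times, session_id))
        state.update(s, outcome)
        O = O * d_o + outcome
        C = C * d_c + choice
        I = I * d_i + outcome * choice

    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return Session(df, iti_seconds=iti_seconds,
                   metadata={"agent_spec": spec, "generator": "simulate_agent_session"})
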