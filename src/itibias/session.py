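"""Behavioral data model: trial tables, selection filters, movement onset, performance.

Sign conventions (package-wide):

* stimulus: +1 forward, -1 downward
* choice:   +1 forward, -1 downward, 0 no target reached
* outcome:  +1 error,   -1 reward

A no-response trial (choice 0) is always coded as an error (outcome +1),
and a rewarded trial always has choice equal to the stimulus.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "index",
    "stimulus",
    "choice",
    "outcome",
    "light",
    "premature",
    "t_stim_on",
    "t_go",
    "t_move_on",
    "t_target",
    "t_reward",
    "session_id",
]

_TIME_COLUMNS = ["t_stim_on", "t_go", "t_move_on", "t_target", "t_reward"]


class SessionError(ValueError):
    """Raised for malformed or invariant-violating trial tables."""


@dataclass
class Trial:
    """One behavioral trial."""

    index: int
    stimulus: int
    choice: int
    outcome: int
    light: bool = False
    premature: bool = False
    t_stim_on: Optional[float] = None
    t_go: Optional[float] = None
    t_move_on: Optional[float] = None
    t_target: Optional[float] = None
    t_reward: Optional[float] = None
    session_id: str = "session"


@dataclass
class Session:
    """Ordered collection of trials with session-level metadata.

    ``trials`` is a DataFrame with the canonical columns in
    :data:`TRIAL_COLUMNS`; event times may be NaN for behavioral-only
    synthetic sessions.
    """

    trials: pd.DataFrame
    iti_seconds: float = 8.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = _canonicalize(self.trials)
        validate_trials(self.trials)
        if not self.iti_seconds > 0:
            raise SessionError("iti_seconds must be positive")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def stimulus(self) -> np.ndarray:
        return self.trials["stimulus"].to_numpy()

    @property
    def choice(self) -> np.ndarray:
        return self.trials["choice"].to_numpy()

    @property
    def outcome(self) -> np.ndarray:
        return self.trials["outcome"].to_numpy()

    @property
    def light(self) -> np.ndarray:
        return self.trials["light"].to_numpy().astype(bool)

    def subset(self, mask: np.ndarray) -> "Session":
        """Row subset preserving order; trial indices are kept, not renumbered."""
        sub = self.trials.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return Session(sub, iti_seconds=self.iti_seconds, metadata=dict(self.metadata))

    def iter_trials(self):
        for row in self.trials.itertuples(index=False):
            yield Trial(**{c: getattr(row, c) for c in TRIAL_COLUMNS})


@dataclass
class JoystickTrace:
    """2D angular joystick position sampled at a nominal 1 kHz."""

    t: np.ndarray
    angle_x: np.ndarray
    angle_y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.angle_x = np.asarray(self.angle_x, dtype=float)
        self.angle_y = np.asarray(self.angle_y, dtype=float)
        if not (len(self.t) == len(self.angle_x) == len(self.angle_y)):
            raise SessionError("joystick trace arrays must have equal length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise SessionError("joystick timestamps must strictly increase")
            if np.ptp(dt) > 0.5 * np.median(dt):
                raise SessionError("joystick sampling is not uniform within tolerance")


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SessionError(f"trial table missing columns: {missing}")
    df = df[TRIAL_COLUMNS].reset_index(drop=True)
    for col in ("index", "stimulus", "choice", "outcome"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise SessionError(f"row {row}: non-numeric value in column '{col}'")
        df[col] = vals.astype(int)
    for col in ("light", "premature"):
        df[col] = df[col].astype(bool)
    for col in _TIME_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    df["session_id"] = df["session_id"].astype(str)
    return df


def validate_trials(df: pd.DataFrame) -> None:
    """Check the trial-coding invariants, naming the first offending row."""
    for row, s in zip(df.index, df["stimulus"]):
        if s not in (-1, 1):
            raise SessionError(f"row {row}: stimulus {s} outside {{-1, +1}}")
    for row, c in zip(df.index, df["choice"]):
        if c not in (-1, 0, 1):
            raise SessionError(f"row {row}: choice {c} outside {{-1, 0, +1}}")
    for row, o in zip(df.index, df["outcome"]):
        if o not in (-1, 1):
            raise SessionError(f"row {row}: outcome {o} outside {{-1, +1}}")
    bad = (df["choice"] == 0) & (df["outcome"] != 1)
    if bad.any():
        row = int(df.index[bad][0])
        raise SessionError(f"row {row}: no-response must be an error (choice 0 requires outcome +1)")
    rewarded = df["outcome"] == -1
    bad = rewarded & (df["choice"] != df["stimulus"])
    if bad.any():
        row = int(df.index[bad][0])
        raise SessionError(f"row {row}: rewarded trial requires choice == stimulus")
    bad = rewarded & df["premature"]
    if bad.any():
        row = int(df.index[bad][0])
        raise SessionError(f"row {row}: rewarded trial cannot be premature")
    idx = df["index"].to_numpy()
    if len(idx) > 1 and np.any(np.diff(idx) <= 0):
        row = int(np.flatnonzero(np.diff(idx) <= 0)[0]) + 1
        raise SessionError(f"row {row}: trial indices must strictly increase")


def read_trial_table(path_or_buf, iti_seconds: float = 8.0, **metadata) -> Session:
    """Read a CSV trial table (header row, empty fields for missing times)."""
    df = pd.read_csv(path_or_buf)
    return Session(df, iti_seconds=iti_seconds, metadata=metadata)


def write_trial_table(session: Session, path_or_buf) -> None:
    """Write a Session to CSV; round-trips losslessly through read_trial_table."""
    df = session.trials.copy()
    for col in ("light", "premature"):
        df[col] = df[col].astype(int)
    df.to_csv(path_or_buf, index=False, float_format="%.6f")


def session_to_csv_string(session: Session) -> str:
    buf = io.StringIO()
    write_trial_table(session, buf)
    return buf.getvalue()


def read_joystick_trace(path_or_buf) -> JoystickTrace:
    """Read a joystick trace CSV with columns t, angle_x, angle_y."""
    df = pd.read_csv(path_or_buf)
    return JoystickTrace(df["t"].to_numpy(), df["angle_x"].to_numpy(),
                         df["angle_y"].to_numpy())


def write_joystick_trace(trace: JoystickTrace, path_or_buf) -> None:
    pd.DataFrame({"t": trace.t, "angle_x": trace.angle_x,
                  "angle_y": trace.angle_y}).to_csv(path_or_buf, index=False)


def select_model_trials(session: Session) -> Session:
    """Trials entering choice prediction: any target reached (choice != 0).

    Excluded trials still contribute to the *history* regressors of later
    trials; the history model handles that by receiving the full session
    and a per-trial inclusion mask.
    """
    return session.subset(session.choice != 0)


def select_neural_trials(session: Session, max_reach_s: float = 1.0) -> Session:
    """Trials entering neural analyses: responded, not premature, fast reach.

    Keeps trials with choice != 0, premature False, and target acquisition
    within ``max_reach_s`` of the go cue.
    """
    df = session.trials
    reaching = df["choice"] != 0
    if reaching.any():
        need = df.loc[reaching, ["t_go", "t_target"]]
        if need.isna().any().any():
            row = int(need.index[need.isna().any(axis=1)][0])
            raise SessionError(f"row {row}: reaching trial missing t_go/t_target timing")
    latency = df["t_target"] - df["t_go"]
    keep = reaching & ~df["premature"] & (latency <= max_reach_s)
    return session.subset(keep.fillna(False).to_numpy())


def detect_movement_onset(
    trace: JoystickTrace,
    v_thresh: float = 22.2,
    hold_ms: float = 20.0,
    min_disp: float = 1.3,
) -> Optional[float]:
    """First time radial speed exceeds ``v_thresh`` (deg/s) for ``hold_ms``
    while cumulative displacement from the origin has reached ``min_disp`` deg.

    Speed is computed from 1-sample finite differences; ties at the exact
    threshold count as exceeding. Returns None when never satisfied.
    """
    if len(trace.t) == 0:
        raise SessionError("empty joystick trace")
    if len(trace.t) < 2:
        return None
    dt = np.diff(trace.t)
    vx = np.diff(trace.angle_x) / dt
    vy = np.diff(trace.angle_y) / dt
    speed = np.hypot(vx, vy)  # aligned with samples 1..n-1
    disp = np.hypot(trace.angle_x - trace.angle_x[0], trace.angle_y - trace.angle_y[0])
    fast = speed >= v_thresh
    hold_n = max(1, int(round(hold_ms / 1000.0 / np.median(dt))))
    # runs of consecutive fast samples
    n = len(fast)
    i = 0
    while i < n:
        if fast[i]:
            j = i
            while j < n and fast[j]:
                j += 1
            if j - i >= hold_n:
                onset_idx = i + 1  # speed[i] spans samples i..i+1
                if np.any(disp[onset_idx:] >= min_disp):
                    return float(trace.t[onset_idx])
            i = j
        else:
            i += 1
    return None


def performance_metrics(session: Session) -> dict:
    """Withholding and discrimination performance of a session.

    withholding = responses after the go cue / all responses;
    discrimination = trials hitting the correct target / trials hitting any
    target (computed over all reaching trials regardless of withholding).
    Undefined ratios are returned as NaN with a flag rather than raised.
    """
    df = session.trials
    responded = df["choice"] != 0
    n_resp = int(responded.sum())
    n_after_go = int((responded & ~df["premature"]).sum())
    n_correct = int((responded & (df["choice"] == df["stimulus"])).sum())
    withholding = n_after_go / n_resp if n_resp else float("nan")
    discrimination = n_correct / n_resp if n_resp else float("nan")
    return {
        "withholding": withholding,
        "discrimination": discrimination,
        "n_responding": n_resp,
        "defined": n_resp > 0,
    }
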