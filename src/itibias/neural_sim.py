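"""Synthetic calcium-trace generator with known single-cell tuning.

Cells emit calcium-like transients from an inhomogeneous event rate:
a baseline plus additive gains active in tuning-specific windows (the
pre-stimulus ITI for history/bias tuning, a peri-movement window for
movement tuning). Events are convolved with an instantaneous-rise,
exponential-decay kernel, white noise is added, and the trace is written
back as raw fluorescence plus a background trace so the full dF/F
preprocessing path is exercised end to end.

Ground-truth cell specs are carried separately from the analysis inputs
(raw/background traces and event times) so analyses can never peek.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .session import Session

TUNING_TARGETS = ("n1_outcome", "n1_choice", "n_choice", "bias", "movement")

ITI_WINDOW = (-4.0, 0.0)        # s relative to stimulus onset
MOVE_WINDOW = (-0.5, 1.5)       # s relative to movement onset


@dataclass
class CellSpec:
    """Ground-truth generative parameters of one synthetic cell.

    tuning maps target names to gains in events/min added while the
    target's window is active; for binary targets the gain is multiplied
    by the signed variable value, for "bias" by the continuous internal
    bias, and for "movement" by 1 during the peri-movement window.
    """

    tuning: dict = field(default_factory=dict)
    baseline_rate: float = 3.0      # events/min
    amplitude: float = 1.0          # dF/F units per transient
    decay_s: float = 0.3            # GCaMP6f-like decay
    noise_sd: float = 0.05          # dF/F units

    def __post_init__(self) -> None:
        for k in self.tuning:
            if k not in TUNING_TARGETS:
                raise ValueError(f"unknown tuning target {k!r}")
        if not self.decay_s > 0:
            raise ValueError("decay_s must be positive")
        if self.baseline_rate < 0 or self.noise_sd < 0:
            raise ValueError("baseline_rate and noise_sd must be >= 0")


@dataclass
class PopulationRecording:
    """Per-cell raw fluorescence + background with trial-event alignment."""

    frame_rate: float
    t: np.ndarray                       # frame times, s
    raw: np.ndarray                     # (n_cells, n_frames)
    background: np.ndarray              # (n_cells, n_frames)
    trial_events: pd.DataFrame          # per-trial variables and event times
    cell_specs: Optional[list] = None   # ground truth; not an analysis input
    f0: float = 100.0
    iti_seconds: float = 8.0

    @property
    def n_cells(self) -> int:
        return self.raw.shape[0]

    def to_hdf5(self, path, ground_truth_path=None) -> None:
        """Write analysis inputs to HDF5 (/cells/<id>/{raw,background},
        /events/*); ground truth goes to a separate sidecar JSON if asked."""
        with h5py.File(path, "w") as f:
            f.attrs["frame_rate"] = self.frame_rate
            f.attrs["f0"] = self.f0
            f.attrs["iti_seconds"] = self.iti_seconds
            f.create_dataset("t", data=self.t, track_times=False)
            cells = f.create_group("cells")
            for i in range(self.n_cells):
                g = cells.create_group(f"{i:04d}")
                g.create_dataset("raw", data=self.raw[i], track_times=False)
                g.create_dataset("background", data=self.background[i], track_times=False)
            ev = f.create_group("events")
            for col in self.trial_events.columns:
                ev.create_dataset(col, data=self.trial_events[col].to_numpy(dtype=float), track_times=False)
        if ground_truth_path is not None and self.cell_specs is not None:
            payload = [
                {"tuning": c.tuning, "baseline_rate": c.baseline_rate,
                 "amplitude": c.amplitude, "decay_s": c.decay_s, "noise_sd": c.noise_sd}
                for c in self.cell_specs
            ]
            with open(ground_truth_path, "w") as fh:
                json.dump(payload, fh, indent=1)

    @classmethod
    def from_hdf5(cls, path) -> "PopulationRecording":
        with h5py.File(path, "r") as f:
            t = f["t"][()]
            ids = sorted(f["cells"].keys())
            raw = np.stack([f["cells"][i]["raw"][()] for i in ids])
            bg = np.stack([f["cells"][i]["background"][()] for i in ids])
            events = pd.DataFrame({c: f["events"][c][()] for c in f["events"]})
            return cls(frame_rate=float(f.attrs["frame_rate"]), t=t, raw=raw,
                       background=bg, trial_events=events,
                       f0=float(f.attrs["f0"]),
                       iti_seconds=float(f.attrs.get("iti_seconds", 8.0)))


def synthesize_event_times(session: Session) -> pd.DataFrame:
    """Deterministic task schedule for sessions lacking event times:
    ITI of session.iti_seconds, 1 s stimulus, 2 s memory, 0.4 s reach."""
    df = session.trials.copy()
    t = 0.0
    cols = {k: [] for k in ("t_stim_on", "t_go", "t_move_on", "t_target", "t_reward")}
    for row in df.itertuples(index=False):
        t_stim = t + session.iti_seconds
        t_go = t_stim + 3.0
        if row.choice != 0:
            t_move = t_go + 0.3
            t_target = t_move + 0.15
            t_reward = t_target if row.outcome == -1 else np.nan
            t = t_target + 0.5
        else:
            t_move = t_target = t_reward = np.nan
            t = t_go + 1.5
        for k, v in zip(cols, (t_stim, t_go, t_move, t_target, t_reward)):
            cols[k].append(v)
    for k, v in cols.items():
        df[k] = v
    return df


def _true_bias(session: Session) -> Optional[np.ndarray]:
    spec = session.metadata.get("agent_spec")
    if spec is None:
        return None
    from .history import build_regressors, internal_bias_from_params
    p = spec.params
    regs = build_regressors(session.trials, p.tau_o, p.tau_c, p.tau_oc)
    return internal_bias_from_params(regs, p)


def generate_population(
    session: Session,
    cell_specs: Sequence[CellSpec],
    rng=None,
    frame_rate: float = 28.4,
    bias: Optional[np.ndarray] = None,
    f0: float = 100.0,
    bg0: float = 30.0,
    bg_scale: float = 0.70,
) -> PopulationRecording:
    """Simulate a population recording over a behavioral session.

    ``bias`` supplies the per-trial internal bias driving "bias"-tuned
    cells; when omitted it is computed from the generating agent's true
    parameters (session.metadata["agent_spec"]), and an error is raised if
    neither is available while a cell needs it.
    """
    rng = np.random.default_rng() if rng is None else rng
    events = session.trials
    if events["t_stim_on"].isna().any():
        events = synthesize_event_times(session)
    needs_bias = any("bias" in c.tuning for c in cell_specs)
    if needs_bias and bias is None:
        bias = _true_bias(session)
        if bias is None:
            raise ValueError("bias tuning requested but no bias series available")
    if bias is None:
        bias = np.zeros(len(events))

    t_end = float(np.nanmax(events[["t_stim_on", "t_go", "t_move_on", "t_target", "t_reward"]]
                            .to_numpy())) + 5.0
    n_frames = int(np.ceil(t_end * frame_rate))
    t = np.arange(n_frames) / frame_rate

    stim_on = events["t_stim_on"].to_numpy(dtype=float)
    move_on = events["t_move_on"].to_numpy(dtype=float)
    outcome = events["outcome"].to_numpy(dtype=float)
    choice = events["choice"].to_numpy(dtype=float)

    # per-trial modulation values for each target during its window
    n_trials = len(events)
    values = {
        "n1_outcome": np.concatenate([[0.0], outcome[:-1]]),
        "n1_choice": np.concatenate([[0.0], choice[:-1]]),
        "n_choice": choice,
        "bias": np.asarray(bias, dtype=float),
        "movement": np.ones(n_trials),
    }

    kernel_len = None
    raw = np.empty((len(cell_specs), n_frames))
    background = np.full((len(cell_specs), n_frames), float(bg0))
    per_frame = 1.0 / (60.0 * frame_rate)  # converts events/min to events/frame
    for ci, cell in enumerate(cell_specs):
        rate = np.full(n_frames, float(cell.baseline_rate))
        for target, gain in cell.tuning.items():
            if target == "movement":
                centers, window = move_on, MOVE_WINDOW
            else:
                centers, window = stim_on, ITI_WINDOW
            for n in range(n_trials):
                c = centers[n]
                if not np.isfinite(c):
                    continue
                lo = np.searchsorted(t, c + window[0])
                hi = np.searchsorted(t, c + window[1])
                rate[lo:hi] += gain * values[target][n]
        np.clip(rate, 0.0, None, out=rate)
        spikes = (rng.random(n_frames) < rate * per_frame).astype(float)
        if kernel_len is None or kernel_len[0] != cell.decay_s:
            k = np.exp(-np.arange(0, 5 * cell.decay_s, 1.0 / frame_rate) / cell.decay_s)
            kernel_len = (cell.decay_s, k)
        conv = np.convolve(spikes, kernel_len[1])[:n_frames] * cell.amplitude
        dff = conv + rng.normal(0.0, cell.noise_sd, size=n_frames)
        raw[ci] = f0 * (1.0 + dff) + bg_scale * bg0

    ev_cols = ["index", "stimulus", "choice", "outcome", "light", "premature",
               "t_stim_on", "t_go", "t_move_on", "t_target", "t_reward"]
    trial_events = events[ev_cols].copy()
    trial_events["light"] = trial_events["light"].astype(int)
    trial_events["premature"] = trial_events["premature"].astype(int)
    trial_events["bias_true"] = values["bias"]
    return PopulationRecording(
        frame_rate=frame_rate, t=t, raw=raw, background=background,
        trial_events=trial_events, cell_specs=list(cell_specs), f0=f0,
        iti_seconds=session.iti_seconds,
    )
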