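"""From raw fluorescence to dF/F, calcium transients, and cell QC gates.

dF/F uses a dynamic baseline: the 8th percentile of the background-adjusted
intensity in a 20 s window centered on each frame (truncated at the trace
edges). Transients are local maxima of the zero-mean dF/F passing both an
absolute amplitude floor and a velocity-scaled threshold. "Active" and
"task-related" gates reproduce the stability and task-modulation criteria
used to admit cells into the analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

DEFAULT_ALIGNMENTS = {
    "t_stim_on": (-6.0, 3.0),
    "t_move_on": (-2.0, 7.0),
    "t_reward": (-4.0, 5.0),
}


class PreprocessError(ValueError):
    pass


@dataclass
class DffTrace:
    """Fractional fluorescence change per frame."""

    t: np.ndarray
    dff: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if len(self.t) != len(self.dff):
            raise PreprocessError("t and dff must have equal length")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0


def compute_dff(
    raw: np.ndarray,
    background: np.ndarray,
    frame_rate: float,
    window_s: float = 20.0,
    pct: float = 8.0,
    bg_scale: float = 0.70,
) -> DffTrace:
    """dF/F from raw and background fluorescence.

    adjusted = raw - bg_scale * background; baseline(t) = ``pct``-th
    percentile of adjusted in the ``window_s`` window centered at t
    (truncated at edges); dff = (adjusted - baseline) / baseline.
    """
    raw = np.asarray(raw, dtype=float)
    background = np.asarray(background, dtype=float)
    if raw.shape != background.shape:
        raise PreprocessError("raw and background must have equal length")
    if raw.size == 0:
        raise PreprocessError("zero-length trace")
    window = max(1, int(round(window_s * frame_rate)))
    adjusted = raw - bg_scale * background
    baseline = (
        pd.Series(adjusted)
        .rolling(window, center=True, min_periods=1)
        .quantile(pct / 100.0)
        .to_numpy()
    )
    bad = baseline <= 0
    if bad.any():
        raise PreprocessError(f"non-positive baseline at frame {int(np.flatnonzero(bad)[0])}")
    dff = (adjusted - baseline) / baseline
    t = np.arange(len(raw)) / frame_rate
    return DffTrace(t=t, dff=dff)


def detect_transients(trace: DffTrace, amp_floor: float = 0.5, vel_mult: float = 3.3) -> pd.DataFrame:
    """Calcium-transient peaks on the zero-mean dF/F trace.

    A local maximum qualifies if its zero-mean amplitude is >= ``amp_floor``
    and exceeds ``vel_mult`` times the standard deviation of the per-frame
    dF/F velocity (first difference). Plateau peaks take their first frame.
    Returns a DataFrame with columns frame, t, amplitude.
    """
    if len(trace.dff) < 3:
        raise PreprocessError("need at least 3 frames")
    z = trace.dff - trace.dff.mean()
    vel_sd = float(np.std(np.diff(trace.dff)))
    peaks, props = find_peaks(z, plateau_size=(None, None))
    if len(peaks):
        peaks = props["left_edges"]  # plateau tie-break: first frame
    amp = z[peaks]
    keep = (amp >= amp_floor) & (amp > vel_mult * vel_sd)
    frames = peaks[keep]
    return pd.DataFrame({"frame": frames, "t": trace.t[frames], "amplitude": amp[keep]})


def classify_active(
    trace: DffTrace,
    transients: pd.DataFrame,
    min_rate_per_min: float = 1.0,
    peak_mult: float = 5.0,
) -> dict:
    """Stable-cell gate: transient rate above ``min_rate_per_min`` in both
    session halves AND mean transient amplitude above ``peak_mult`` times
    the dF/F standard deviation."""
    half = trace.t[0] + trace.duration / 2.0
    half_min = trace.duration / 2.0 / 60.0
    n1 = int((transients["t"] < half).sum())
    n2 = int((transients["t"] >= half).sum())
    rate_h1 = n1 / half_min if half_min > 0 else 0.0
    rate_h2 = n2 / half_min if half_min > 0 else 0.0
    sd = float(np.std(trace.dff))
    mean_peak = float(transients["amplitude"].mean()) if len(transients) else 0.0
    active = (
        rate_h1 > min_rate_per_min
        and rate_h2 > min_rate_per_min
        and mean_peak > peak_mult * sd
    )
    return {"active": bool(active), "rate_h1": rate_h1, "rate_h2": rate_h2,
            "mean_peak": mean_peak, "sd": sd}


def _aligned_windows(trace: DffTrace, event_times: np.ndarray, window: tuple,
                     shifts: np.ndarray | None = None) -> np.ndarray:
    """Stack per-trial frame windows aligned to event times; trials whose
    window falls outside the recording are dropped. ``shifts`` circularly
    shifts the whole trace by a per-trial amount before extraction."""
    fr = trace.frame_rate
    n = len(trace.dff)
    n_win = int(round((window[1] - window[0]) * fr))
    rows = []
    for i, e in enumerate(event_times):
        if not np.isfinite(e):
            continue
        lo = int(round((e + window[0] - trace.t[0]) * fr))
        if lo < 0 or lo + n_win > n:
            continue
        src = trace.dff if shifts is None else np.roll(trace.dff, int(shifts[i]))
        rows.append(src[lo:lo + n_win])
    return np.asarray(rows)


def classify_task_related(
    trace: DffTrace,
    trial_events: pd.DataFrame,
    alignments: dict = None,
    pct: float = 99.9,
    run: int = 3,
    min_trials: int = 10,
    n_null: int = 20,
    rng=None,
) -> dict:
    """Task-modulation gate with a shift-shuffle false-positive estimate.

    The dF/F trace is aligned to stimulus, movement, and reward onsets and
    averaged across correct trials; the cell is task-related if the mean
    trace exceeds the cell's ``pct``-th dF/F percentile for >= ``run``
    consecutive frames in any alignment. The false-positive rate is
    estimated by repeating the test after circularly shifting the trace by
    an independent random amount for each trial.
    """
    rng = np.random.default_rng() if rng is None else rng
    alignments = DEFAULT_ALIGNMENTS if alignments is None else alignments
    correct = trial_events[trial_events["outcome"] == -1]
    if len(correct) < min_trials:
        return {"task_related": None, "fp_estimate": float("nan"),
                "reason": f"only {len(correct)} correct trials"}
    thresh = float(np.percentile(trace.dff, pct))

    def flagged(shifts=None):
        for col, window in alignments.items():
            mat = _aligned_windows(trace, correct[col].to_numpy(dtype=float), window, shifts)
            if len(mat) < min_trials:
                continue
            above = mat.mean(axis=0) > thresh
            if _longest_run(above) >= run:
                return True
        return False

    result = flagged()
    n = len(trace.dff)
    fp = np.mean([
        flagged(shifts=rng.integers(0, n, size=len(correct)))
        for _ in range(n_null)
    ]) if n_null > 0 else float("nan")
    return {"task_related": bool(result), "fp_estimate": float(fp), "threshold": thresh}


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def qc_table(recording, rng=None, frame_rate=None, **kwargs) -> pd.DataFrame:
    """Per-cell QC summary over a PopulationRecording.

    Columns: cell_id, n_transients, rate_h1, rate_h2, mean_peak, active,
    task_related, fp_estimate.
    """
    rng = np.random.default_rng() if rng is None else rng
    fr = frame_rate or recording.frame_rate
    rows = []
    for ci in range(recording.n_cells):
        trace = compute_dff(recording.raw[ci], recording.background[ci], fr)
        tr = detect_transients(trace)
        act = classify_active(trace, tr)
        task = classify_task_related(trace, recording.trial_events, rng=rng, **kwargs)
        rows.append({
            "cell_id": ci,
            "n_transients": len(tr),
            "rate_h1": act["rate_h1"],
            "rate_h2": act["rate_h2"],
            "mean_peak": act["mean_peak"],
            "active": act["active"],
            "task_related": task["task_related"],
            "fp_estimate": task["fp_estimate"],
        })
    return pd.DataFrame(rows)
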