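"""Trial-wise analysis of the finger force tracking task.

For each ramp-hold-release trial the module extracts: RMSE between applied
and commanded force over the ramp and the hold phase; force-onset and
release-onset times from threshold crossings of the smoothed dF/dt; the
release duration (time for force to fall from 75% to 25% of the target,
sub-sample by linear interpolation); the coefficient of variation and mean of
the hold force over the central 3 s of the hold (first/last 500 ms trimmed);
and the inter-trial baseline force over the window 1500-500 ms before the
next ramp onset.

Measures that cannot be computed for a trial (no threshold crossing, force
never reaching 25% of target, first trial's missing pre-ramp window) are
reported as NaN and excluded from summaries, never coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, InvalidParameterError
from .io import ForceRecording
from .protocol import TaskProtocol, TrackingTrialSpec

#: Default dF/dt magnitude for onset/release-onset detection (N/s).
ONSET_SLOPE_THRESHOLD = 1.0
#: Moving-average width used to smooth the trace before differentiation (s).
ONSET_SMOOTH_S = 0.05
#: Hold-phase trim on each side before computing mean/CV (s).
HOLD_TRIM_S = 0.5


@dataclass
class TrackingTrialMetrics:
    trial_index: int
    target_force: float
    rmse_ramp: float
    rmse_hold: float
    force_onset_time: float  # s relative to ramp cue; NaN if undefined
    release_onset_time: float  # s relative to hold end; NaN if undefined
    release_duration: float  # s; NaN if undefined
    cv_hold: float
    mean_hold_force: float
    baseline_force: float  # NaN for the first trial


_METRIC_COLUMNS = [
    "rmse_ramp",
    "rmse_hold",
    "force_onset_time",
    "release_onset_time",
    "release_duration",
    "cv_hold",
    "mean_hold_force",
    "baseline_force",
]


@dataclass
class TrackingSubjectSummary:
    """Per-target-force means of the trial metrics (NaN-aware)."""

    table: pd.DataFrame  # indexed by target_force; mean columns + n_used_<col>
    n_trials: int

    def mean(self, column: str) -> float:
        """Grand mean of a metric across all trials (NaN-excluded)."""
        return float(self._trials[column].mean())

    # stashed by summarize_tracking
    _trials: pd.DataFrame = None  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def rmse(trace: np.ndarray, target: np.ndarray) -> float:
    """Root-mean-square error between applied and target force."""
    trace = np.asarray(trace, dtype=float)
    target = np.asarray(target, dtype=float)
    if trace.shape != target.shape or trace.size == 0:
        raise InvalidParameterError("trace and target must be equal-length, non-empty")
    return float(np.sqrt(np.mean((trace - target) ** 2)))


def target_profile(protocol: TaskProtocol, times: np.ndarray) -> np.ndarray:
    """Commanded trapezoid target force evaluated on ``times``."""
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    for trial in protocol.trials:
        ramp = (times >= trial.ramp_start) & (times < trial.hold_start)
        out[ramp] = trial.target_force * (times[ramp] - trial.ramp_start) / trial.ramp_duration
        hold = (times >= trial.hold_start) & (times < trial.hold_end)
        out[hold] = trial.target_force
    return out


def _smoothed_derivative(trace: np.ndarray, rate: float, smooth_s: float) -> np.ndarray:
    w = max(1, int(round(smooth_s * rate)))
    kernel = np.ones(w) / w
    sm = np.convolve(trace, kernel, mode="same")
    return np.gradient(sm) * rate


def detect_force_onset(
    times: np.ndarray,
    trace: np.ndarray,
    cue_time: float,
    window_end: float,
    slope_threshold: float = ONSET_SLOPE_THRESHOLD,
    smooth_s: float = ONSET_SMOOTH_S,
    direction: int = 1,
) -> float:
    """First time in [cue_time, window_end) where the smoothed dF/dt crosses
    ``direction * slope_threshold``. Returns NaN when no crossing exists."""
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        return float("nan")
    rate = 1.0 / float(np.median(np.diff(times)))
    deriv = _smoothed_derivative(np.asarray(trace, dtype=float), rate, smooth_s)
    sel = (times >= cue_time) & (times < window_end)
    if direction >= 0:
        hits = np.flatnonzero(sel & (deriv > slope_threshold))
    else:
        hits = np.flatnonzero(sel & (deriv < -slope_threshold))
    if hits.size == 0:
        return float("nan")
    return float(times[hits[0]])


def _first_downward_crossing(
    times: np.ndarray, trace: np.ndarray, level: float, start: float, end: float
) -> float:
    """Sub-sample time of the first downward crossing of ``level`` in
    [start, end); NaN if none."""
    sel = np.flatnonzero((times >= start) & (times < end))
    if sel.size < 2:
        return float("nan")
    seg = trace[sel]
    below = seg < level
    for k in range(1, len(seg)):
        if not below[k - 1] and below[k]:
            f0, f1 = seg[k - 1], seg[k]
            t0, t1 = times[sel[k - 1]], times[sel[k]]
            frac = (f0 - level) / (f0 - f1)
            return float(t0 + frac * (t1 - t0))
    return float("nan")


def release_duration(
    times: np.ndarray,
    trace: np.ndarray,
    target_force: float,
    hold_end: float,
    window_end: float,
) -> float:
    """Time from the first downward 0.75·target crossing to the first
    downward 0.25·target crossing after the hold. NaN when the force never
    falls below 25% of target within the window (incomplete release)."""
    t75 = _first_downward_crossing(times, trace, 0.75 * target_force, hold_end, window_end)
    if np.isnan(t75):
        return float("nan")
    t25 = _first_downward_crossing(times, trace, 0.25 * target_force, t75, window_end)
    if np.isnan(t25):
        return float("nan")
    return t25 - t75


def hold_stats(
    times: np.ndarray,
    trace: np.ndarray,
    hold_start: float,
    hold_end: float,
    trim_s: float = HOLD_TRIM_S,
) -> tuple[float, float]:
    """(CV, mean) of the hold force over the trimmed central window.

    CV = sample SD / mean; NaN when the mean is non-positive.
    """
    if hold_end - hold_start < 2 * trim_s + 1e-9:
        raise InvalidParameterError("hold phase shorter than twice the trim")
    sel = (times >= hold_start + trim_s) & (times < hold_end - trim_s)
    seg = np.asarray(trace, dtype=float)[sel]
    if seg.size < 2:
        return float("nan"), float("nan")
    mean = float(np.mean(seg))
    if mean <= 0:
        return float("nan"), mean
    cv = float(np.std(seg, ddof=1) / mean)
    return cv, mean


def baseline_force(times: np.ndarray, trace: np.ndarray, ramp_onset: float) -> float:
    """Mean force over [ramp_onset − 1.5 s, ramp_onset − 0.5 s); NaN when the
    recording does not cover the window (e.g. the first trial)."""
    start, end = ramp_onset - 1.5, ramp_onset - 0.5
    if times.size == 0 or times[0] > start + 1e-9:
        return float("nan")
    sel = (times >= start) & (times < end)
    if not np.any(sel):
        return float("nan")
    return float(np.mean(np.asarray(trace, dtype=float)[sel]))


# ---------------------------------------------------------------------------
# trial-level pipeline
# ---------------------------------------------------------------------------

def segment_trials(
    rec: ForceRecording, protocol: TaskProtocol
) -> list[tuple[TrackingTrialSpec, slice]]:
    """Half-open sample window per trial covering ramp+hold+release+rest."""
    if protocol.task_kind != "tracking":
        raise InvalidParameterError("protocol.task_kind must be 'tracking'")
    rate = rec.sample_rate
    out = []
    missing = []
    for trial in protocol.trials:
        i0 = int(round(trial.ramp_start * rate))
        i1 = int(round(trial.end * rate))
        if i1 > rec.n_samples:
            missing.append(trial.trial_index)
            continue
        out.append((trial, slice(i0, i1)))
    if missing:
        raise AnalysisError(
            f"recording shorter than protocol; missing trial(s) {missing}"
        )
    return out


def analyze_tracking(
    rec: ForceRecording,
    protocol: TaskProtocol,
    finger: str = "index",
) -> list[TrackingTrialMetrics]:
    """Compute all tracking measures trial by trial for the lead finger."""
    trace = rec.channel(finger)
    times = rec.times
    target = target_profile(protocol, times)
    results = []
    for trial, sl in segment_trials(rec, protocol):
        ramp_sel = (times >= trial.ramp_start) & (times < trial.hold_start)
        hold_sel = (times >= trial.hold_start) & (times < trial.hold_end)
        rmse_ramp = rmse(trace[ramp_sel], target[ramp_sel])
        rmse_hold = rmse(trace[hold_sel], target[hold_sel])
        onset = detect_force_onset(
            times, trace, trial.ramp_start, trial.hold_start, direction=1
        )
        rel_onset = detect_force_onset(
            times, trace, trial.hold_end, trial.end, direction=-1
        )
        rel_dur = release_duration(times, trace, trial.target_force, trial.hold_end, trial.end)
        cv, mean_hold = hold_stats(times, trace, trial.hold_start, trial.hold_end)
        base = baseline_force(times, trace, trial.ramp_start)
        results.append(
            TrackingTrialMetrics(
                trial_index=trial.trial_index,
                target_force=trial.target_force,
                rmse_ramp=rmse_ramp,
                rmse_hold=rmse_hold,
                force_onset_time=(onset - trial.ramp_start) if not np.isnan(onset) else onset,
                release_onset_time=(rel_onset - trial.hold_end)
                if not np.isnan(rel_onset)
                else rel_onset,
                release_duration=rel_dur,
                cv_hold=cv,
                mean_hold_force=mean_hold,
                baseline_force=base,
            )
        )
    return results


def trials_frame(trials: Sequence[TrackingTrialMetrics]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in trials])


def summarize_tracking(trials: Sequence[TrackingTrialMetrics]) -> TrackingSubjectSummary:
    """NaN-aware per-target-force means, with the number of trials used per
    cell; cells where no trial yields a defined value come out as NaN."""
    if not trials:
        raise AnalysisError("at least one trial is required")
    df = trials_frame(trials)
    g = df.groupby("target_force")
    table = g[_METRIC_COLUMNS].mean()
    for col in _METRIC_COLUMNS:
        table[f"n_used_{col}"] = g[col].count()
    summary = TrackingSubjectSummary(table=table, n_trials=len(df))
    summary._trials = df
    return summary
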