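"""Tap event detection and scoring for the three tapping tasks.

A tap is a discrete force event: the channel crosses the 0.5 N detection
threshold upward, peaks at the local maximum, and ends at the downward
crossing; above-threshold segments closer than the refractory interval
(default 100 ms) merge into one event.

Task scoring:

* **sequential** — the ordered finger string of user taps in each 5 s trial
  window is aligned to the 5-digit target by longest common subsequence
  (LCS); a trial is correct only when the user string equals the target
  exactly. Missing/extra tap counts and the longest contiguous correct run
  are derived from the alignment.
* **single_tap** — per (finger, frequency, phase) condition: lead-finger tap
  count, achieved rate and inter-tap intervals; each non-lead tap is an
  *overflow* tap when it coincides (±100 ms by default) with a lead tap,
  otherwise an *unwanted* tap. The rate-vs-target-frequency slope across the
  1/2/3 Hz conditions (1 = veridical pacing, <1 = slowed) comes from an OLS
  fit on rates pooled over cued and uncued phases.
* **multi_tap** — per cue trial, the response set is the set of fingers with
  at least one tap in the response window; correctness, omissions and
  unwanted extra-finger-taps (UEFTs) follow set-wise, and the error matrix
  tabulates, per target combination, the percentage of trials in which each
  finger tapped erroneously. Four-finger trials are parsed but excluded from
  all rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, InvalidParameterError
from .io import ForceRecording
from .protocol import (
    FINGERS,
    FINGER_TO_DIGIT,
    Condition,
    CueEvent,
    SequenceSpec,
    TaskProtocol,
)

DETECTION_THRESHOLD = 0.5  # N
REFRACTORY_S = 0.1
COINCIDENCE_WINDOW_S = 0.1


@dataclass(frozen=True)
class TapEvent:
    finger: str
    onset_time: float
    peak_time: float
    amplitude: float


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_taps(
    rec: ForceRecording,
    threshold: float = DETECTION_THRESHOLD,
    refractory: float = REFRACTORY_S,
) -> list[TapEvent]:
    """Detect discrete tap events on every channel, sorted by peak time."""
    if threshold <= 0:
        raise InvalidParameterError("threshold must be > 0")
    events: list[TapEvent] = []
    t = rec.times
    for finger in FINGERS:
        x = rec.channel(finger)
        above = x > threshold
        if not above.any():
            continue
        edges = np.diff(above.astype(np.int8))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)  # first sample below
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(len(x))
        # merge segments separated by less than the refractory interval
        merged: list[list[int]] = []
        for s, e in zip(starts, ends):
            if merged and (t[s] - t[merged[-1][1] - 1]) < refractory:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            seg = x[s:e]
            k = s + int(np.argmax(seg))
            if s > 0:
                # sub-sample upward crossing time
                f0, f1 = x[s - 1], x[s]
                frac = (threshold - f0) / (f1 - f0)
                onset = float(t[s - 1] + frac * (t[s] - t[s - 1]))
            else:
                onset = float(t[0])
            events.append(TapEvent(finger, onset, float(t[k]), float(x[k])))
    events.sort(key=lambda ev: ev.peak_time)
    return events


def events_frame(events: Sequence[TapEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.finger, e.onset_time, e.peak_time, e.amplitude) for e in events],
        columns=["finger", "onset_s", "peak_s", "amplitude_N"],
    )


def _events_in(events: Iterable[TapEvent], start: float, end: float) -> list[TapEvent]:
    return [e for e in events if start <= e.peak_time < end]


# ---------------------------------------------------------------------------
# sequential task
# ---------------------------------------------------------------------------

@dataclass
class SequenceTrialResult:
    trial_index: int
    phase: str  # "learning" | "recall"
    n_user_taps: int
    is_correct: bool
    n_missing: int
    n_extra: int
    longest_correct_run: int
    n_correct_taps: int
    user_fingers: tuple[str, ...] = ()
    error_taps: dict[str, int] = field(default_factory=dict)  # unaligned taps per finger


def _lcs_length(a: Sequence, b: Sequence) -> int:
    m, n = len(a), len(b)
    dp = np.zeros((m + 1, n + 1), dtype=int)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            dp[i, j] = (
                dp[i - 1, j - 1] + 1 if a[i - 1] == b[j - 1] else max(dp[i - 1, j], dp[i, j - 1])
            )
    return int(dp[m, n])


def _longest_common_substring(a: Sequence, b: Sequence) -> int:
    best = 0
    m, n = len(a), len(b)
    dp = np.zeros((m + 1, n + 1), dtype=int)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if a[i - 1] == b[j - 1]:
                dp[i, j] = dp[i - 1, j - 1] + 1
                best = max(best, int(dp[i, j]))
    return best


def score_sequence_trial(
    user_fingers: Sequence[str],
    target: SequenceSpec,
    trial_index: int = 0,
    phase: str = "learning",
) -> SequenceTrialResult:
    """Score one trial's ordered user-tap finger string against the target."""
    tgt = target.fingers
    lcs = _lcs_length(user_fingers, tgt)
    run = _longest_common_substring(user_fingers, tgt)
    correct = tuple(user_fingers) == tgt
    aligned = _lcs_alignment_counts(user_fingers, tgt)
    errors = {}
    for f in FINGERS:
        n_err = sum(1 for u in user_fingers if u == f) - aligned.get(f, 0)
        if n_err:
            errors[f] = n_err
    return SequenceTrialResult(
        trial_index=trial_index,
        phase=phase,
        n_user_taps=len(user_fingers),
        is_correct=correct,
        n_missing=len(tgt) - lcs,
        n_extra=len(user_fingers) - lcs,
        longest_correct_run=run,
        n_correct_taps=lcs,
        user_fingers=tuple(user_fingers),
        error_taps=errors,
    )


def analyze_sequence(
    rec: ForceRecording,
    protocol: TaskProtocol,
    events: Sequence[TapEvent] | None = None,
) -> list[SequenceTrialResult]:
    if protocol.task_kind != "sequential" or protocol.sequence is None:
        raise InvalidParameterError("protocol must be a sequential task with a sequence")
    if events is None:
        events = detect_taps(rec)
    out = []
    for i, cond in enumerate(protocol.conditions):
        taps = _events_in(events, cond.start, cond.end)
        out.append(
            score_sequence_trial(
                [e.finger for e in taps], protocol.sequence, trial_index=i, phase=cond.phase
            )
        )
    return out


@dataclass
class SequenceSummary:
    success_rate: dict[str, float]  # per phase
    first_half_correct_taps: float  # learning trials 1-5, mean of n_correct_taps
    second_half_correct_taps: float  # learning trials 6-10
    error_taps_per_finger: dict[str, int]


def summarize_sequence(trials: Sequence[SequenceTrialResult]) -> SequenceSummary:
    by_phase: dict[str, list[SequenceTrialResult]] = {}
    for tr in trials:
        by_phase.setdefault(tr.phase, []).append(tr)
    success = {
        phase: sum(t.is_correct for t in ts) / len(ts) for phase, ts in by_phase.items()
    }
    learning = by_phase.get("learning", [])
    half = len(learning) // 2
    first = float(np.mean([t.n_correct_taps for t in learning[:half]])) if half else float("nan")
    second = float(np.mean([t.n_correct_taps for t in learning[half:]])) if half else float("nan")
    errors = {f: 0 for f in FINGERS}
    for tr in trials:
        for f, n_err in tr.error_taps.items():
            errors[f] += n_err
    return SequenceSummary(success, first, second, errors)


def _lcs_alignment_counts(a: Sequence[str], b: Sequence[str]) -> dict[str, int]:
    """Per-finger count of user taps aligned by one LCS traceback."""
    m, n = len(a), len(b)
    dp = np.zeros((m + 1, n + 1), dtype=int)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            dp[i, j] = (
                dp[i - 1, j - 1] + 1 if a[i - 1] == b[j - 1] else max(dp[i - 1, j], dp[i, j - 1])
            )
    counts: dict[str, int] = {}
    i, j = m, n
    while i > 0 and j > 0:
        if a[i - 1] == b[j - 1] and dp[i, j] == dp[i - 1, j - 1] + 1:
            counts[a[i - 1]] = counts.get(a[i - 1], 0) + 1
            i -= 1
            j -= 1
        elif dp[i - 1, j] >= dp[i, j - 1]:
            i -= 1
        else:
            j -= 1
    return counts


# ---------------------------------------------------------------------------
# single finger tapping
# ---------------------------------------------------------------------------

@dataclass
class SingleTapConditionResult:
    finger: str
    target_freq: float
    phase: str  # "cued" | "uncued"
    n_taps: int
    rate: float  # Hz
    mean_iti: float  # s; NaN when < 2 lead taps
    iti_sd: float
    n_overflow: int
    n_unwanted: int
    duration: float


@dataclass
class RateSlope:
    finger: str
    slope: float
    intercept: float


def score_single_tap(
    events: Sequence[TapEvent],
    condition: Condition,
    coincidence_window: float = COINCIDENCE_WINDOW_S,
) -> SingleTapConditionResult:
    """Score one (finger, frequency, phase) condition window."""
    lead_finger = condition.fingers[0]
    window = _events_in(events, condition.start, condition.end)
    lead = [e for e in window if e.finger == lead_finger]
    nonlead = [e for e in window if e.finger != lead_finger]
    lead_times = np.array([e.peak_time for e in lead])
    n_overflow = n_unwanted = 0
    for e in nonlead:
        if lead_times.size and np.min(np.abs(lead_times - e.peak_time)) <= coincidence_window:
            n_overflow += 1
        else:
            n_unwanted += 1
    itis = np.diff(lead_times) if lead_times.size >= 2 else np.array([])
    return SingleTapConditionResult(
        finger=lead_finger,
        target_freq=float(condition.frequency),
        phase=condition.phase,
        n_taps=len(lead),
        rate=len(lead) / condition.duration,
        mean_iti=float(np.mean(itis)) if itis.size else float("nan"),
        iti_sd=float(np.std(itis, ddof=1)) if itis.size >= 2 else float("nan"),
        n_overflow=n_overflow,
        n_unwanted=n_unwanted,
        duration=condition.duration,
    )


def analyze_single_tap(
    rec: ForceRecording,
    protocol: TaskProtocol,
    events: Sequence[TapEvent] | None = None,
    coincidence_window: float = COINCIDENCE_WINDOW_S,
) -> list[SingleTapConditionResult]:
    if protocol.task_kind != "single_tap":
        raise InvalidParameterError("protocol.task_kind must be 'single_tap'")
    if events is None:
        events = detect_taps(rec)
    return [
        score_single_tap(events, cond, coincidence_window) for cond in protocol.conditions
    ]


def rate_slope(freqs: Sequence[float], rates: Sequence[float], finger: str = "") -> RateSlope:
    """OLS slope of achieved rate against target frequency."""
    freqs = np.asarray(freqs, dtype=float)
    rates = np.asarray(rates, dtype=float)
    ok = ~np.isnan(rates)
    if len(np.unique(freqs[ok])) < 2:
        return RateSlope(finger, float("nan"), float("nan"))
    slope, intercept = np.polyfit(freqs[ok], rates[ok], 1)
    return RateSlope(finger, float(slope), float(intercept))


def rate_slopes(results: Sequence[SingleTapConditionResult]) -> dict[str, RateSlope]:
    """Per-finger rate slope, pooling cued and uncued phases per frequency
    (total taps / total duration)."""
    pooled: dict[tuple[str, float], tuple[int, float]] = {}
    for r in results:
        key = (r.finger, r.target_freq)
        n, d = pooled.get(key, (0, 0.0))
        pooled[key] = (n + r.n_taps, d + r.duration)
    out: dict[str, RateSlope] = {}
    for finger in {f for f, _ in pooled}:
        freqs = sorted(fr for f, fr in pooled if f == finger)
        rates = [pooled[(finger, fr)][0] / pooled[(finger, fr)][1] for fr in freqs]
        out[finger] = rate_slope(freqs, rates, finger)
    return out


# ---------------------------------------------------------------------------
# multi-finger tapping
# ---------------------------------------------------------------------------

@dataclass
class MultiTapTrialResult:
    trial_index: int
    target_set: tuple[str, ...]
    response_set: tuple[str, ...]
    is_correct: bool
    omissions: tuple[str, ...]
    extras: tuple[str, ...]
    n_extra_events: int


def score_multi_trial(
    events: Sequence[TapEvent],
    cue: CueEvent,
    response_window: float,
    trial_index: int = 0,
) -> MultiTapTrialResult:
    """Score one cued trial: response set = fingers with >=1 tap peak in
    (cue.time, cue.time + response_window]."""
    start, end = cue.time, cue.time + response_window
    in_win = [e for e in events if start < e.peak_time <= end]
    response = tuple(sorted({e.finger for e in in_win}, key=FINGERS.index))
    target = tuple(sorted(cue.fingers, key=FINGERS.index))
    omissions = tuple(f for f in target if f not in response)
    extras = tuple(f for f in response if f not in target)
    n_extra_events = sum(1 for e in in_win if e.finger not in target)
    return MultiTapTrialResult(
        trial_index=trial_index,
        target_set=target,
        response_set=response,
        is_correct=response == target,
        omissions=omissions,
        extras=extras,
        n_extra_events=n_extra_events,
    )


def analyze_multi(
    rec: ForceRecording,
    protocol: TaskProtocol,
    events: Sequence[TapEvent] | None = None,
    response_window: float | None = None,
) -> list[MultiTapTrialResult]:
    """Score every cue trial. The response window defaults to the gap to the
    next cue, so overlapping windows cannot occur and each tap is assigned to
    the nearest preceding cue."""
    if protocol.task_kind != "multi_tap":
        raise InvalidParameterError("protocol.task_kind must be 'multi_tap'")
    if events is None:
        events = detect_taps(rec)
    out = []
    cues = protocol.cues
    for i, cue in enumerate(cues):
        gap = (cues[i + 1].time - cue.time) if i + 1 < len(cues) else (
            protocol.total_duration - cue.time
        )
        win = min(response_window, gap) if response_window is not None else gap
        out.append(score_multi_trial(events, cue, win, trial_index=i))
    return out


def _combo_label(fingers: tuple[str, ...]) -> str:
    return "-".join(str(FINGER_TO_DIGIT[f]) for f in fingers)


@dataclass
class MultiTapSummary:
    success_rate: float  # over one- and two-finger trials
    success_by_class: dict[str, float]
    omission_rate: float
    ueft_total: int
    ueft_one_finger: int
    ueft_two_finger: int
    error_matrix: pd.DataFrame  # % of combo trials with erroneous finger tap
    target_mask: pd.DataFrame  # True where the cell coincides with a target finger
    n_trials: int = 0


def summarize_multi(trials: Sequence[MultiTapTrialResult]) -> MultiTapSummary:
    """Aggregate scored trials into rates and the per-combination error
    matrix. Four-finger trials are excluded from every rate."""
    if not trials:
        raise AnalysisError("at least one scored trial is required")
    scored = [t for t in trials if len(t.target_set) in (1, 2)]
    n = len(scored)
    if n == 0:
        raise AnalysisError("no one- or two-finger trials to summarize")
    success = sum(t.is_correct for t in scored) / n
    by_class: dict[str, list[MultiTapTrialResult]] = {"one_finger": [], "two_finger": []}
    for t in scored:
        by_class["one_finger" if len(t.target_set) == 1 else "two_finger"].append(t)
    success_by_class = {
        k: (sum(t.is_correct for t in ts) / len(ts) if ts else float("nan"))
        for k, ts in by_class.items()
    }
    target_instances = sum(len(t.target_set) for t in scored)
    omitted = sum(len(t.omissions) for t in scored)
    omission_rate = omitted / target_instances if target_instances else float("nan")
    ueft_one = sum(t.n_extra_events for t in by_class["one_finger"])
    ueft_two = sum(t.n_extra_events for t in by_class["two_finger"])

    combos = [(f,) for f in FINGERS] + list(combinations(FINGERS, 2))
    labels = [_combo_label(c) for c in combos]
    mat = pd.DataFrame(np.nan, index=labels, columns=list(FINGERS))
    mask = pd.DataFrame(False, index=labels, columns=list(FINGERS))
    for combo, label in zip(combos, labels):
        for f in combo:
            mask.loc[label, f] = True
        combo_trials = [t for t in scored if t.target_set == combo]
        if not combo_trials:
            continue
        for f in FINGERS:
            if f in combo:
                continue
            n_err = sum(1 for t in combo_trials if f in t.extras)
            mat.loc[label, f] = 100.0 * n_err / len(combo_trials)
    return MultiTapSummary(
        success_rate=success,
        success_by_class=success_by_class,
        omission_rate=omission_rate,
        ueft_total=ueft_one + ueft_two,
        ueft_one_finger=ueft_one,
        ueft_two_finger=ueft_two,
        error_matrix=mat,
        target_mask=mask,
        n_trials=n,
    )
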