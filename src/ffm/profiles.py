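"""Individual dexterity profiling against control norms.

Six discriminatory measures characterise a subject, all oriented so that
larger means worse performance:

====================  =====================================================
tracking_error        index-finger tracking RMSE, ramp and hold pooled (N)
release_duration      index-finger 75→25% release time, 1 N and 2 N pooled (s)
one_minus_slope       1 − (rate-vs-frequency slope, index finger, 1–3 Hz)
overflow_taps_1hz     overflow taps summed over the 1 Hz conditions (count)
omission_rate         multi-finger omission rate (fraction)
ueft_one_finger       unwanted extra-finger-taps on one-finger trials (count)
====================  =====================================================

A measure is *pathological* when it strictly exceeds the control cohort's
mean + 2·SD for that measure. The module also carries the thin statistical
surface used for group comparisons (two-sample t) and clinical correlations
(Spearman / Pearson), plus the Moberg pick-up pathology flag (>18 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, InvalidParameterError
from .io import ForceRecording, SubjectClinical
from .protocol import TaskProtocol
from . import tracking as _tracking
from . import taps as _taps

MOBERG_PATHOLOGY_S = 18.0

MEASURES = (
    "tracking_error",
    "release_duration",
    "one_minus_slope",
    "overflow_taps_1hz",
    "omission_rate",
    "ueft_one_finger",
)


@dataclass
class DexterityProfile:
    subject_id: str = ""
    tracking_error: float = float("nan")
    release_duration: float = float("nan")
    one_minus_slope: float = float("nan")
    overflow_taps_1hz: float = float("nan")
    omission_rate: float = float("nan")
    ueft_one_finger: float = float("nan")
    flags: dict[str, bool | None] = field(default_factory=dict)

    def measure(self, name: str) -> float:
        if name not in MEASURES:
            raise InvalidParameterError(f"unknown measure {name!r}")
        return getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MEASURES}


@dataclass
class ControlNorms:
    """Per-measure control mean, SD and mean+2SD pathology threshold."""

    mean: dict[str, float]
    sd: dict[str, float]
    threshold: dict[str, float]
    n_controls: int


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def compute_profile(
    tracking_summary: _tracking.TrackingSubjectSummary | None = None,
    single_results: Sequence[_taps.SingleTapConditionResult] | None = None,
    multi_summary: _taps.MultiTapSummary | None = None,
    subject_id: str = "",
    index_slope: _taps.RateSlope | None = None,
) -> DexterityProfile:
    """Assemble the six-measure profile from per-task analysis outputs.

    Any task not provided leaves its measures NaN (a subject may not have
    performed every task).
    """
    p = DexterityProfile(subject_id=subject_id)
    if tracking_summary is not None:
        df = tracking_summary._trials
        p.tracking_error = float(
            np.nanmean(np.concatenate([df["rmse_ramp"].to_numpy(), df["rmse_hold"].to_numpy()]))
        )
        p.release_duration = float(df["release_duration"].mean())
    if single_results is not None:
        if index_slope is None:
            index_slope = _taps.rate_slopes(single_results).get("index")
        if index_slope is not None:
            p.one_minus_slope = 1.0 - index_slope.slope
        p.overflow_taps_1hz = float(
            sum(r.n_overflow for r in single_results if r.target_freq == 1.0)
        )
    if multi_summary is not None:
        p.omission_rate = multi_summary.omission_rate
        p.ueft_one_finger = float(multi_summary.ueft_one_finger)
    return p


def profile_subject(
    recordings: dict[str, tuple[ForceRecording, object, TaskProtocol]],
    subject_id: str = "",
    tracking_finger: str = "index",
) -> DexterityProfile:
    """Run the full analysis pipeline on a subject's recordings.

    ``recordings`` maps task kind to ``(recording, ground_truth, protocol)``
    as produced by :func:`ffm.synthetic.make_cohort`; ground truth is ignored
    here.
    """
    tr_summary = None
    single = None
    multi = None
    if "tracking" in recordings:
        rec, _, proto = recordings["tracking"]
        tr_summary = _tracking.summarize_tracking(
            _tracking.analyze_tracking(rec, proto, finger=tracking_finger)
        )
    if "single_tap" in recordings:
        rec, _, proto = recordings["single_tap"]
        single = _taps.analyze_single_tap(rec, proto)
    if "multi_tap" in recordings:
        rec, _, proto = recordings["multi_tap"]
        multi = _taps.summarize_multi(_taps.analyze_multi(rec, proto))
    return compute_profile(tr_summary, single, multi, subject_id=subject_id)


# ---------------------------------------------------------------------------
# norms and flags
# ---------------------------------------------------------------------------

def compute_norms(control_profiles: Sequence[DexterityProfile]) -> ControlNorms:
    """Mean, sample SD and mean+2SD threshold per measure from controls.

    Measures with fewer than two defined control values are left out
    (NaN mean/sd/threshold).
    """
    if not control_profiles:
        raise AnalysisError("at least one control profile is required")
    mean, sd, thr = {}, {}, {}
    for m in MEASURES:
        vals = np.array([p.measure(m) for p in control_profiles], dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            mean[m] = sd[m] = thr[m] = float("nan")
            continue
        mean[m] = float(np.mean(vals))
        sd[m] = float(np.std(vals, ddof=1))
        thr[m] = mean[m] + 2.0 * sd[m]
    return ControlNorms(mean, sd, thr, n_controls=len(control_profiles))


def flag_pathology(profile: DexterityProfile, norms: ControlNorms) -> DexterityProfile:
    """Set per-measure pathology flags: strictly above mean+2SD.

    A flag is ``None`` when either the measure or its norm is undefined.
    """
    for m in MEASURES:
        v = profile.measure(m)
        thr = norms.threshold.get(m, float("nan"))
        if math.isnan(v) or math.isnan(thr):
            profile.flags[m] = None
        else:
            profile.flags[m] = bool(v > thr)
    return profile


def flag_clinical(clinical: SubjectClinical) -> dict[str, bool | None]:
    """Clinical pathology flags; currently the Moberg affected-hand >18 s rule."""
    moberg = None
    if clinical.moberg_s is not None:
        moberg = clinical.moberg_s[0] > MOBERG_PATHOLOGY_S
    return {"moberg_affected": moberg}


def profiles_frame(profiles: Sequence[DexterityProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row: dict = {"subject_id": p.subject_id, **p.as_dict()}
        for m in MEASURES:
            row[f"flag_{m}"] = p.flags.get(m)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# thin statistics
# ---------------------------------------------------------------------------

def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "spearman",
) -> tuple[float, float, int]:
    """Correlation between paired vectors with pairwise NaN removal.

    Returns (coefficient, p-value, n complete pairs). Undefined (NaN
    coefficient) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise InvalidParameterError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), n
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise InvalidParameterError("method must be 'spearman' or 'pearson'")
    return float(r), float(p), n


def correlation_report(profiles: Sequence[DexterityProfile]) -> pd.DataFrame:
    """Pairwise Pearson r and R² between the six profile measures, mirroring
    a lower-triangular component-correlation table."""
    df = pd.DataFrame([p.as_dict() for p in profiles])
    rows = []
    for i, a in enumerate(MEASURES):
        for b in MEASURES[:i]:
            sub = df[[a, b]].dropna()
            if len(sub) < 3 or sub[a].std() == 0 or sub[b].std() == 0:
                r, p, n = float("nan"), float("nan"), len(sub)
            else:
                r, p, n = correlate(sub[a], sub[b], "pearson")
            rows.append(
                {"measure_a": a, "measure_b": b, "r": r, "r2": r * r, "p": p, "n": n}
            )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    t_statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int


def group_compare(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sample t-test (pooled variance by default) with descriptives.

    NaNs are dropped per group; degenerate groups (<2 values) raise. A zero
    pooled variance yields a NaN t statistic rather than an exception.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise InvalidParameterError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        t_statistic=float(t),
        p_value=float(p),
        mean_a=float(np.mean(a)),
        sd_a=float(np.std(a, ddof=1)),
        mean_b=float(np.mean(b)),
        sd_b=float(np.std(b, ddof=1)),
        n_a=len(a),
        n_b=len(b),
    )
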