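"""Seedable generative model of control-like and paretic-like force traces.

No public recordings exist for this device, so every analysis stage is
exercised against simulated traces with exported ground truth. The generator
reproduces the phenomenology that the analysis modules quantify:

* tracking — the lead finger follows the trapezoid target with a visuo-motor
  lag, additive white sensor noise, an elevated inter-trial baseline, and an
  exponential (time-constant ``release_tau``) force release instead of the
  commanded instantaneous drop;
* tapping — each cue elicits a raised-cosine force pulse; impairment features
  are tap-time jitter, amplitude variability, cue omissions, spurious extra
  taps, a tapping-rate ceiling (cues faster than ``max_rate`` are thinned),
  and *enslaving*: each pulse leaks onto the other fingers scaled by a 4x4
  coupling matrix that decays with anatomical distance in the paretic preset.

An enslaved pulse whose peak crosses the 0.5 N detection threshold appears in
the ground truth as an overflow/error tap — tying the generative model to the
analyzer's event definition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidParameterError
from .io import ForceRecording, RecordingMeta, SubjectClinical, ANALYSIS_RATE
from .protocol import (
    FINGERS,
    Condition,
    CueEvent,
    TaskProtocol,
    build_multi_tap_protocol,
    build_single_tap_protocol,
    build_tracking_protocol,
    finger_distance,
)

#: Tap detection threshold shared with the analyzer (N).
DETECTION_THRESHOLD = 0.5


def _identity_enslaving() -> np.ndarray:
    return np.eye(len(FINGERS))


@dataclass
class SimParams:
    """Generative parameters for one simulated subject.

    Units: forces in N, times in s, rates in Hz. ``enslaving[i, j]`` is the
    unitless fraction of finger *i*'s force appearing on finger *j*
    (diagonal 1). ``tap_amplitude_cv`` is the sigma of a log-normal
    multiplicative amplitude jitter.
    """

    tracking_noise_sd: float = 0.03
    tracking_lag: float = 0.12
    release_tau: float = 0.1
    baseline_offset: float = 0.0
    tap_amplitude: float = 2.0
    tap_amplitude_cv: float = 0.0
    tap_width: float = 0.2
    tap_jitter_sd: float = 0.0
    tempo_drift_sd: float = 0.0  # relative rate error of self-paced (uncued) tapping
    max_rate: float = 5.0
    enslaving: np.ndarray = field(default_factory=_identity_enslaving)
    omission_prob: float = 0.0
    extra_tap_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.enslaving = np.asarray(self.enslaving, dtype=float)
        if self.enslaving.shape != (4, 4):
            raise InvalidParameterError("enslaving must be a 4x4 matrix")
        if not np.allclose(np.diag(self.enslaving), 1.0):
            raise InvalidParameterError("enslaving diagonal must be 1")
        if np.any(self.enslaving < 0) or np.any(self.enslaving > 1):
            raise InvalidParameterError("enslaving entries must be in [0, 1]")
        for name in (
            "tracking_noise_sd",
            "release_tau",
            "baseline_offset",
            "tap_amplitude_cv",
            "tap_jitter_sd",
            "tempo_drift_sd",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.tap_width <= 0 or self.tap_amplitude <= 0 or self.max_rate <= 0:
            raise InvalidParameterError("tap_width, tap_amplitude, max_rate must be > 0")
        for name in ("omission_prob", "extra_tap_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise InvalidParameterError(f"{name} must be in [0, 1]")

    # -- (de)serialization -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "enslaving"}
        d["enslaving"] = self.enslaving.tolist()
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SimParams":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls(**json.loads(text))


@dataclass(frozen=True)
class TruthTap:
    """A ground-truth force event: peak time/amplitude and provenance."""

    finger: str
    time: float  # peak time, s
    amplitude: float  # peak force, N
    source: str = "cued"  # "cued" | "enslaved" | "extra"


@dataclass
class GroundTruth:
    taps: list[TruthTap] = field(default_factory=list)
    omitted_cues: list[int] = field(default_factory=list)
    injected_extras: list[TruthTap] = field(default_factory=list)


def enslaving_matrix(neighbor: float, second: float, third: float) -> np.ndarray:
    """Coupling matrix decaying with anatomical distance between digits."""
    E = np.eye(4)
    decay = {1: neighbor, 2: second, 3: third}
    for i, fi in enumerate(FINGERS):
        for j, fj in enumerate(FINGERS):
            if i != j:
                E[i, j] = decay[finger_distance(fi, fj)]
    return E


def preset(group: str) -> SimParams:
    """Parameter presets emulating a healthy control or a paretic subject.

    ``control_like``: low noise, fast release, near-zero baseline, rate
    ceiling above 3 Hz, near-diagonal enslaving, rare omissions/extras.
    ``paretic_like``: irregular tracking, slow release, elevated baseline,
    rate ceiling below 3 Hz, distance-decaying enslaving (anatomical
    neighbors couple most) and frequent omissions/extras.
    """
    if group == "control_like":
        return SimParams(
            tracking_noise_sd=0.03,
            tracking_lag=0.12,
            release_tau=0.10,
            baseline_offset=0.02,
            tap_amplitude=2.0,
            tap_amplitude_cv=0.10,
            tap_width=0.20,
            tap_jitter_sd=0.02,
            tempo_drift_sd=0.04,
            max_rate=5.0,
            enslaving=enslaving_matrix(0.10, 0.05, 0.02),
            omission_prob=0.01,
            extra_tap_prob=0.01,
        )
    if group == "paretic_like":
        return SimParams(
            tracking_noise_sd=0.12,
            tracking_lag=0.25,
            release_tau=0.60,
            baseline_offset=0.28,
            tap_amplitude=2.0,
            tap_amplitude_cv=0.25,
            tap_width=0.25,
            tap_jitter_sd=0.05,
            tempo_drift_sd=0.08,
            max_rate=2.4,
            enslaving=enslaving_matrix(0.35, 0.24, 0.12),
            omission_prob=0.18,
            extra_tap_prob=0.12,
        )
    raise InvalidParameterError("group must be 'control_like' or 'paretic_like'")


def interpolate_params(severity: float, seed: int = 0) -> SimParams:
    """Linear interpolation between the control (0) and paretic (1) presets."""
    if not 0 <= severity <= 1:
        raise InvalidParameterError("severity must be in [0, 1]")
    a, b = preset("control_like"), preset("paretic_like")
    kw = {}
    for name in (
        "tracking_noise_sd",
        "tracking_lag",
        "release_tau",
        "baseline_offset",
        "tap_amplitude",
        "tap_amplitude_cv",
        "tap_width",
        "tap_jitter_sd",
        "tempo_drift_sd",
        "max_rate",
        "omission_prob",
        "extra_tap_prob",
    ):
        kw[name] = (1 - severity) * getattr(a, name) + severity * getattr(b, name)
    E = (1 - severity) * a.enslaving + severity * b.enslaving
    np.fill_diagonal(E, 1.0)
    return SimParams(enslaving=E, seed=seed, **kw)


# ---------------------------------------------------------------------------
# trace rendering
# ---------------------------------------------------------------------------

def render_tap_events(
    events: Iterable[TruthTap],
    duration: float,
    sample_rate: float = ANALYSIS_RATE,
    tap_width: float = 0.2,
) -> np.ndarray:
    """Render raised-cosine pulses (peak at ``time``, width ``tap_width``)
    into a (n, 4) force array."""
    n = int(np.ceil(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    out = np.zeros((n, len(FINGERS)))
    for ev in events:
        ch = FINGERS.index(ev.finger)
        t0 = ev.time - tap_width / 2
        i0 = max(0, int(np.floor(t0 * sample_rate)))
        i1 = min(n, int(np.ceil((t0 + tap_width) * sample_rate)) + 1)
        if i1 <= i0:
            continue
        phase = (t[i0:i1] - t0) / tap_width
        mask = (phase >= 0) & (phase <= 1)
        pulse = np.where(mask, 0.5 * ev.amplitude * (1 - np.cos(2 * np.pi * phase)), 0.0)
        out[i0:i1, ch] += pulse
    return out


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_tracking(
    protocol: TaskProtocol,
    params: SimParams,
    finger: str = "index",
    sample_rate: float = ANALYSIS_RATE,
) -> tuple[ForceRecording, GroundTruth]:
    """Simulate one run of the force-tracking task with ``finger`` as lead.

    The lead trace follows the commanded trapezoid delayed by
    ``tracking_lag``, rests at ``baseline_offset`` between trials, and decays
    exponentially (``release_tau``) from the hold level toward baseline after
    each hold. Non-lead channels carry ``enslaving[lead, d]`` times the lead
    trace plus noise.
    """
    if protocol.task_kind != "tracking":
        raise InvalidParameterError("protocol.task_kind must be 'tracking'")
    rng = np.random.default_rng(params.seed)
    n = int(np.ceil(protocol.total_duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    b = float(params.baseline_offset)
    lag = float(params.tracking_lag)
    tau = float(params.release_tau)

    lead = np.full(n, b, dtype=float)
    for trial in protocol.trials:
        r0, h0, h1 = trial.ramp_start + lag, trial.hold_start + lag, trial.hold_end + lag
        end = trial.end + lag
        ramp = (t >= r0) & (t < h0)
        lead[ramp] = b + (trial.target_force - b) * (t[ramp] - r0) / trial.ramp_duration
        hold = (t >= h0) & (t < h1)
        lead[hold] = trial.target_force
        rel = (t >= h1) & (t < end)
        if tau > 0:
            lead[rel] = b + (trial.target_force - b) * np.exp(-(t[rel] - h1) / tau)
        else:
            lead[rel] = b

    samples = np.empty((n, len(FINGERS)))
    li = FINGERS.index(finger)
    for d in range(len(FINGERS)):
        gain = 1.0 if d == li else params.enslaving[li, d]
        samples[:, d] = gain * lead + rng.normal(0.0, params.tracking_noise_sd, n)

    meta = RecordingMeta(task_kind="tracking")
    return ForceRecording(samples, sample_rate, meta=meta), GroundTruth()


def _intended_cues(
    protocol: TaskProtocol, rng: np.random.Generator, tempo_drift_sd: float = 0.0
) -> list[CueEvent]:
    """Cue list extended with the subject's self-paced taps in uncued/recall
    phases. Without a metronome the maintained tempo carries a relative error
    drawn per condition (sd ``tempo_drift_sd``)."""
    cues = list(protocol.cues)
    if protocol.task_kind == "single_tap":
        for cond in protocol.conditions:
            if cond.phase != "uncued" or cond.frequency is None:
                continue
            drift = rng.normal(0.0, tempo_drift_sd) if tempo_drift_sd > 0 else 0.0
            f_eff = max(0.1, cond.frequency * (1.0 + drift))
            n = int(round(cond.duration * f_eff))
            for k in range(n):
                t_k = cond.start + k / f_eff
                if t_k >= cond.end:
                    break
                cues.append(CueEvent(t_k, cond.fingers, "self_paced", cond.frequency))
    elif protocol.task_kind == "sequential" and protocol.sequence is not None:
        rate = next(
            (c.frequency for c in protocol.conditions if c.frequency), 1.0
        )
        for cond in protocol.conditions:
            if cond.phase != "recall":
                continue
            for i, f in enumerate(protocol.sequence.fingers):
                cues.append(CueEvent(cond.start + i / rate, (f,), "self_paced", rate))
    cues.sort(key=lambda c: c.time)
    return cues


def simulate_tapping(
    protocol: TaskProtocol,
    params: SimParams,
    sample_rate: float = ANALYSIS_RATE,
) -> tuple[ForceRecording, GroundTruth]:
    """Simulate a tapping task (sequential, single_tap or multi_tap) run.

    Every non-omitted intended tap produces a raised-cosine pulse; pulses leak
    onto other fingers through the enslaving matrix, intended trains faster
    than ``max_rate`` are thinned, and extra taps are injected with
    ``extra_tap_prob`` per cue. Ground truth lists every event whose rendered
    peak exceeds the 0.5 N detection threshold.
    """
    if protocol.task_kind not in ("sequential", "single_tap", "multi_tap"):
        raise InvalidParameterError(
            "protocol.task_kind must be a tapping task, got " + protocol.task_kind
        )
    rng = np.random.default_rng(params.seed)
    cues = _intended_cues(protocol, rng, params.tempo_drift_sd)
    min_iti = 1.0 / params.max_rate
    last_tap: dict[str, float] = {}
    truth = GroundTruth()
    events: list[TruthTap] = []

    def draw_amp(base: float) -> float:
        if params.tap_amplitude_cv > 0:
            return base * float(np.exp(rng.normal(0.0, params.tap_amplitude_cv)))
        return base

    for idx, cue in enumerate(cues):
        if params.omission_prob > 0 and rng.random() < params.omission_prob:
            truth.omitted_cues.append(idx)
            continue
        jitter = rng.normal(0.0, params.tap_jitter_sd) if params.tap_jitter_sd > 0 else 0.0
        for f in cue.fingers:
            t_tap = cue.time + jitter + params.tap_width / 2
            if f in last_tap and (t_tap - last_tap[f]) < min_iti - 1e-9:
                truth.omitted_cues.append(idx)  # thinned by the rate ceiling
                continue
            last_tap[f] = t_tap
            amp = draw_amp(params.tap_amplitude)
            lead_ev = TruthTap(f, t_tap, amp, "cued")
            events.append(lead_ev)
            if amp > DETECTION_THRESHOLD:
                truth.taps.append(lead_ev)
            li = FINGERS.index(f)
            for d, fd in enumerate(FINGERS):
                if fd == f or fd in cue.fingers:
                    continue
                e = params.enslaving[li, d]
                if e <= 0:
                    continue
                c_amp = e * amp
                ev = TruthTap(fd, t_tap, c_amp, "enslaved")
                events.append(ev)
                if c_amp > DETECTION_THRESHOLD:
                    truth.taps.append(ev)
        others = [f for f in FINGERS if f not in cue.fingers]
        if others and params.extra_tap_prob > 0 and rng.random() < params.extra_tap_prob:
            f_extra = others[rng.integers(len(others))]
            t_extra = cue.time + rng.uniform(0.25, 0.85)
            amp = draw_amp(0.8 * params.tap_amplitude)
            ev = TruthTap(f_extra, t_extra, amp, "extra")
            events.append(ev)
            truth.injected_extras.append(ev)
            if amp > DETECTION_THRESHOLD:
                truth.taps.append(ev)

    duration = protocol.total_duration + 1.0
    samples = render_tap_events(events, duration, sample_rate, params.tap_width)
    if params.tracking_noise_sd > 0:
        samples = samples + rng.normal(0.0, params.tracking_noise_sd, samples.shape)
    truth.taps.sort(key=lambda e: e.time)
    meta = RecordingMeta(task_kind=protocol.task_kind)
    return ForceRecording(samples, sample_rate, meta=meta), truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSubject:
    subject_id: str
    group: str  # "control" | "patient"
    severity: float
    params: SimParams
    recordings: dict[str, tuple[ForceRecording, GroundTruth, TaskProtocol]]
    clinical: SubjectClinical


#: Relative sd of the per-subject log-normal parameter jitter in cohorts.
COHORT_PARAM_JITTER = 0.08


def _jitter_params(p: SimParams, rng: np.random.Generator) -> SimParams:
    """Per-subject draw around interpolated preset values (log-normal,
    relative sd :data:`COHORT_PARAM_JITTER`); probabilities clipped to [0, 1]
    and enslaving off-diagonals to [0, 1]."""
    s = COHORT_PARAM_JITTER

    def ln() -> float:
        return float(np.exp(rng.normal(0.0, s)))

    E = p.enslaving * ln()
    np.fill_diagonal(E, 1.0)
    E = np.clip(E, 0.0, 1.0)
    return replace(
        p,
        tracking_noise_sd=p.tracking_noise_sd * ln(),
        tracking_lag=p.tracking_lag * ln(),
        release_tau=p.release_tau * ln(),
        baseline_offset=p.baseline_offset * ln(),
        tap_amplitude=p.tap_amplitude * ln(),
        tap_amplitude_cv=p.tap_amplitude_cv * ln(),
        tap_jitter_sd=p.tap_jitter_sd * ln(),
        tempo_drift_sd=p.tempo_drift_sd * ln(),
        max_rate=p.max_rate * ln(),
        omission_prob=float(np.clip(p.omission_prob * ln(), 0.0, 1.0)),
        extra_tap_prob=float(np.clip(p.extra_tap_prob * ln(), 0.0, 1.0)),
        enslaving=E,
    )


def make_cohort(
    n_controls: int,
    n_patients: int,
    seed: int = 0,
    tasks: Sequence[str] = ("tracking", "single_tap", "multi_tap"),
    protocols: dict[str, TaskProtocol] | None = None,
) -> list[CohortSubject]:
    """Simulate a cohort with per-subject parameter draws around the presets.

    Controls draw severity ~ U(0, 0.08), patients ~ U(0.4, 1.0); generative
    parameters interpolate between the two presets with severity, receive a
    per-subject log-normal draw around those values, and the
    synthetic clinical scores (ARAT, Moberg, grip) degrade with severity so
    correlation analyses have signal by construction.
    """
    if n_controls < 0 or n_patients < 0:
        raise InvalidParameterError("cohort sizes must be >= 0")
    if protocols is None:
        protocols = {
            "tracking": build_tracking_protocol(),
            "single_tap": build_single_tap_protocol(),
            "multi_tap": build_multi_tap_protocol(seed=seed),
        }
    rng = np.random.default_rng(seed)
    subjects: list[CohortSubject] = []
    groups = ["control"] * n_controls + ["patient"] * n_patients
    for i, group in enumerate(groups):
        severity = (
            float(rng.uniform(0.0, 0.08))
            if group == "control"
            else float(rng.uniform(0.4, 1.0))
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        params = _jitter_params(interpolate_params(severity, seed=sub_seed), rng)
        recs: dict[str, tuple[ForceRecording, GroundTruth, TaskProtocol]] = {}
        for j, task in enumerate(tasks):
            proto = protocols[task]
            task_params = replace(params, seed=(sub_seed + 7919 * (j + 1)) % (2**31 - 1))
            if task == "tracking":
                rec, gt = simulate_tracking(proto, task_params, finger="index")
            else:
                rec, gt = simulate_tapping(proto, task_params)
            recs[task] = (rec, gt, proto)
        arat = int(np.clip(round(57 - 28 * severity + rng.normal(0, 2)), 0, 57))
        moberg_aff = float(max(5.0, 12 + 45 * severity + rng.normal(0, 2)))
        moberg_non = float(max(5.0, 12 + rng.normal(0, 1)))
        grip_aff = float(max(2.0, 35 - 20 * severity + rng.normal(0, 2)))
        grip_non = float(max(2.0, 35 + rng.normal(0, 2)))
        clinical = SubjectClinical(
            arat_total=arat,
            grip_force_kg=(grip_aff, grip_non),
            moberg_s=(moberg_aff, moberg_non),
        )
        subjects.append(
            CohortSubject(
                subject_id=f"{'C' if group == 'control' else 'P'}{i:02d}",
                group=group,
                severity=severity,
                params=params,
                recordings=recs,
                clinical=clinical,
            )
        )
    return subjects
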