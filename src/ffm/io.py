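"""Data model and file I/O for four-channel fingertip force recordings.

A recording is a delimited-text trace (columns ``t,index,middle,ring,little``;
time in seconds, forces in newtons) plus a JSON sidecar holding
:class:`RecordingMeta` and optional :class:`SubjectClinical`. The strain-gauge
sensors have a nominal 0–9 N range and <0.01 N precision; validation treats
forces outside [-0.5, 9.5] N (range plus noise margin) as warnings rather than
errors, since paretic subjects may transiently exceed the nominal range.

Analysis always runs at 100 Hz; :func:`resample_to` provides anti-aliased
down-sampling from any higher acquisition rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import FormatError, InvalidParameterError
from .protocol import FINGERS

SCHEMA_VERSION = 1
ANALYSIS_RATE = 100.0  # Hz
SENSOR_RANGE = (-0.5, 9.5)  # N, nominal 0-9 N plus noise margin


@dataclass
class RecordingMeta:
    subject_id: str = "anonymous"
    group: str = "control"  # "patient" | "control"
    hand: str = "right"
    task_kind: str = "tracking"
    digit_map: dict[str, str] = field(
        default_factory=lambda: {f: f for f in FINGERS}
    )  # file column -> finger
    acquisition_rate_native: float | None = None

    def __post_init__(self) -> None:
        if sorted(self.digit_map.values()) != sorted(FINGERS):
            raise InvalidParameterError(
                f"digit_map must be a bijection onto {FINGERS}"
            )


@dataclass
class SubjectClinical:
    """Clinical metadata consumed by the correlation/profiling operations.

    ARAT is the 0-57 Action Research Arm Test total; Moberg is the pick-up
    test time in seconds (affected, non-affected); grip force in kg;
    monofilament thresholds in grams.
    """

    arat_total: int | None = None
    grip_force_kg: tuple[float, float] | None = None
    moberg_s: tuple[float, float] | None = None
    monofilament_g: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.arat_total is not None and not 0 <= self.arat_total <= 57:
            raise InvalidParameterError("arat_total must be within [0, 57]")
        for name in ("grip_force_kg", "moberg_s", "monofilament_g"):
            v = getattr(self, name)
            if v is not None and min(v) < 0:
                raise InvalidParameterError(f"{name} values must be >= 0")


@dataclass
class ForceRecording:
    """Four-channel force trace in newtons at a uniform sample rate.

    ``samples`` has shape (n_samples, 4) with columns ordered
    (index, middle, ring, little).
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0
    meta: RecordingMeta = field(default_factory=RecordingMeta)
    clinical: SubjectClinical | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(FINGERS):
            raise InvalidParameterError("samples must have shape (n, 4)")
        if self.samples.shape[0] < 1:
            raise InvalidParameterError("recording must contain >= 1 sample")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be > 0")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def channel(self, finger: str) -> np.ndarray:
        return self.samples[:, FINGERS.index(finger)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=list(FINGERS)).assign(t=self.times)[
            ["t", *FINGERS]
        ]


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "warning" | "error"
    message: str
    sample_index: int | None = None
    channel: str | None = None


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_recording(rec: ForceRecording, trace_path: str | Path, meta_path: str | Path) -> None:
    """Write the trace CSV and its JSON sidecar (bit-stable for fixed input)."""
    df = rec.to_frame()
    df.to_csv(trace_path, index=False, float_format="%.9g")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "sample_rate": rec.sample_rate,
        "start_time": rec.start_time,
        "meta": asdict(rec.meta),
        "clinical": asdict(rec.clinical) if rec.clinical is not None else None,
    }
    Path(meta_path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_recording(trace_path: str | Path, meta_path: str | Path) -> ForceRecording:
    """Read a trace CSV + JSON sidecar into a validated :class:`ForceRecording`.

    Channel order is normalized to (index, middle, ring, little) through the
    sidecar's ``digit_map``. The time column is optional when the sidecar
    declares ``sample_rate``.
    """
    sidecar = json.loads(Path(meta_path).read_text())
    meta_dict = dict(sidecar.get("meta", {}))
    meta_dict["digit_map"] = dict(meta_dict.get("digit_map", {f: f for f in FINGERS}))
    meta = RecordingMeta(**meta_dict)
    clin = sidecar.get("clinical")
    clinical = None
    if clin is not None:
        clinical = SubjectClinical(
            arat_total=clin.get("arat_total"),
            grip_force_kg=tuple(clin["grip_force_kg"]) if clin.get("grip_force_kg") else None,
            moberg_s=tuple(clin["moberg_s"]) if clin.get("moberg_s") else None,
            monofilament_g=tuple(clin["monofilament_g"]) if clin.get("monofilament_g") else None,
        )

    df = pd.read_csv(trace_path)
    missing = [col for col in meta.digit_map if col not in df.columns]
    if missing:
        raise FormatError(f"missing channel column(s): {', '.join(missing)}")

    declared_rate = sidecar.get("sample_rate")
    start_time = float(sidecar.get("start_time", 0.0))
    if "t" in df.columns:
        t = df["t"].to_numpy(dtype=float)
        if np.any(np.isnan(t)):
            raise FormatError(f"NaN in time column at row {int(np.isnan(t).argmax())}")
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise FormatError(
                    f"non-monotonic time at row {int(np.argmax(dt <= 0)) + 1}"
                )
            rate = 1.0 / float(np.median(dt))
        elif declared_rate:
            rate = float(declared_rate)
        else:
            raise FormatError("single-sample file without declared sample_rate")
        start_time = float(t[0])
    elif declared_rate:
        rate = float(declared_rate)
    else:
        raise FormatError("no time column and no declared sample_rate in sidecar")

    samples = np.empty((len(df), len(FINGERS)), dtype=float)
    for col, finger in meta.digit_map.items():
        vals = df[col].to_numpy(dtype=float)
        if np.any(np.isnan(vals)):
            row = int(np.isnan(vals).argmax())
            raise FormatError(f"NaN force in column '{col}' at row {row}")
        samples[:, FINGERS.index(finger)] = vals

    return ForceRecording(samples, rate, start_time, meta=meta, clinical=clinical)


# ---------------------------------------------------------------------------
# resampling and validation
# ---------------------------------------------------------------------------

def resample_to(rec: ForceRecording, target_rate: float = ANALYSIS_RATE) -> ForceRecording:
    """Anti-aliased down-sampling onto a uniform grid at ``target_rate``.

    A zero-phase low-pass (4th-order Butterworth at 0.45 × target rate) is
    applied before linear interpolation onto the new grid. Up-sampling is
    explicitly unsupported.
    """
    if target_rate <= 0:
        raise InvalidParameterError("target_rate must be > 0")
    if target_rate > rec.sample_rate:
        raise InvalidParameterError(
            f"upsampling not supported ({rec.sample_rate} -> {target_rate} Hz)"
        )
    if target_rate == rec.sample_rate:
        return ForceRecording(
            rec.samples.copy(), rec.sample_rate, rec.start_time, rec.meta, rec.clinical
        )

    cutoff = 0.45 * target_rate / (rec.sample_rate / 2.0)
    sos = signal.butter(4, cutoff, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=0)

    old_t = rec.times
    n_out = int(np.floor((rec.n_samples - 1) / rec.sample_rate * target_rate)) + 1
    new_t = rec.start_time + np.arange(n_out) / target_rate
    out = np.column_stack(
        [np.interp(new_t, old_t, filtered[:, i]) for i in range(filtered.shape[1])]
    )
    return ForceRecording(out, float(target_rate), rec.start_time, rec.meta, rec.clinical)


def validate(rec: ForceRecording) -> list[ValidationIssue]:
    """Report invariant violations; an empty list means the recording is clean."""
    issues: list[ValidationIssue] = []
    lo, hi = SENSOR_RANGE
    for ch, finger in enumerate(FINGERS):
        col = rec.samples[:, ch]
        bad = ~np.isfinite(col)
        if bad.any():
            issues.append(
                ValidationIssue(
                    "error",
                    f"non-finite force on '{finger}' at sample {int(bad.argmax())}",
                    int(bad.argmax()),
                    finger,
                )
            )
            col = np.where(bad, 0.0, col)
        out = (col < lo) | (col > hi)
        if out.any():
            k = int(out.argmax())
            issues.append(
                ValidationIssue(
                    "warning",
                    f"force out of sensor range on '{finger}' at sample {k} "
                    f"({rec.samples[k, ch]:.2f} N outside [{lo}, {hi}] N)",
                    k,
                    finger,
                )
            )
    return issues
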