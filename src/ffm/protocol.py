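"""Machine-readable schedules for the four Finger Force Manipulandum tasks.

The manipulandum instruments four digits (index, middle, ring, little; digit
numbers 2-5). Four visuo-motor tasks are run on it:

* **tracking** — ramp/hold/release force tracking against a trapezoid target,
  repeated in blocks at two target force levels (1 N and 2 N by default);
* **sequential** — a five-tap finger sequence, first cued visually at 1 Hz
  (learning phase), then reproduced from memory (recall phase);
* **single_tap** — metronome-cued repetitive tapping of one finger at 1, 2 and
  3 Hz, each cued phase followed by an uncued phase of equal duration;
* **multi_tap** — cued one-, two- and four-finger tap combinations in
  pseudo-random order.

Builders return a :class:`TaskProtocol`, the single source of truth for trial
windows, cue times and condition labels consumed by the simulator and the
analysis modules. All times are seconds from task start; phase intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidParameterError

SCHEMA_VERSION = 1

#: Instrumented digits in channel order.
FINGERS: tuple[str, ...] = ("index", "middle", "ring", "little")

#: Digit-number convention: 2 = index ... 5 = little.
DIGIT_TO_FINGER: dict[int, str] = {2: "index", 3: "middle", 4: "ring", 5: "little"}
FINGER_TO_DIGIT: dict[str, int] = {f: d for d, f in DIGIT_TO_FINGER.items()}


def finger_distance(a: str, b: str) -> int:
    """Anatomical distance between two instrumented digits (0 for identity)."""
    return abs(FINGER_TO_DIGIT[a] - FINGER_TO_DIGIT[b])


@dataclass(frozen=True)
class TrackingTrialSpec:
    """One ramp-hold-release tracking trial.

    The commanded target rises linearly from 0 to ``target_force`` over the
    ramp, stays constant during the hold, and returns instantaneously to 0 at
    the end of the hold; the rest phase separates trials.
    """

    trial_index: int
    block_index: int
    target_force: float
    ramp_start: float
    ramp_duration: float
    hold_duration: float
    rest_duration: float

    def __post_init__(self) -> None:
        if self.target_force <= 0:
            raise InvalidParameterError("target_force must be > 0")
        if min(self.ramp_duration, self.hold_duration) <= 0 or self.rest_duration < 0:
            raise InvalidParameterError("trial phase durations must be positive")

    @property
    def hold_start(self) -> float:
        return self.ramp_start + self.ramp_duration

    @property
    def hold_end(self) -> float:
        return self.hold_start + self.hold_duration

    @property
    def end(self) -> float:
        return self.hold_end + self.rest_duration


@dataclass(frozen=True)
class CueEvent:
    """A timed instruction to tap one or more fingers."""

    time: float
    fingers: tuple[str, ...]
    kind: str  # "visual_tap_cue" | "auditory_metronome"
    nominal_rate: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InvalidParameterError("cue time must be >= 0")
        if not self.fingers or any(f not in FINGERS for f in self.fingers):
            raise InvalidParameterError(
                f"cue fingers must be a non-empty subset of {FINGERS}"
            )


@dataclass(frozen=True)
class SequenceSpec:
    """A five-digit tap sequence, given in digit numbers (2=index .. 5=little)."""

    digits: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.digits) != 5:
            raise InvalidParameterError("sequence must contain exactly 5 digits")
        if any(d not in DIGIT_TO_FINGER for d in self.digits):
            raise InvalidParameterError("sequence digits must be in 2..5")

    @property
    def fingers(self) -> tuple[str, ...]:
        return tuple(DIGIT_TO_FINGER[d] for d in self.digits)


#: The three sequences used in the reference protocol (first digit == last).
PAPER_SEQUENCES: dict[str, SequenceSpec] = {
    "A": SequenceSpec((2, 5, 3, 4, 2), "A"),
    "B": SequenceSpec((4, 3, 5, 2, 4), "B"),
    "C": SequenceSpec((3, 2, 4, 5, 3), "C"),
}


@dataclass(frozen=True)
class Condition:
    """A labelled analysis window: which finger set, rate and phase it tests."""

    fingers: tuple[str, ...]
    frequency: float | None
    phase: str
    start: float
    end: float
    label: str = ""

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class TaskProtocol:
    """Full timed schedule of one task run."""

    task_kind: str  # "tracking" | "sequential" | "single_tap" | "multi_tap"
    trials: list[TrackingTrialSpec] = field(default_factory=list)
    cues: list[CueEvent] = field(default_factory=list)
    conditions: list[Condition] = field(default_factory=list)
    total_duration: float = 0.0
    sequence: SequenceSpec | None = None

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "task_kind": self.task_kind,
            "total_duration": self.total_duration,
            "sequence": (
                {"digits": list(self.sequence.digits), "label": self.sequence.label}
                if self.sequence
                else None
            ),
            "trials": [
                {
                    "trial_index": t.trial_index,
                    "block_index": t.block_index,
                    "target_force": t.target_force,
                    "ramp_start": t.ramp_start,
                    "ramp_duration": t.ramp_duration,
                    "hold_duration": t.hold_duration,
                    "rest_duration": t.rest_duration,
                }
                for t in self.trials
            ],
            "cues": [
                {
                    "time": c.time,
                    "fingers": list(c.fingers),
                    "kind": c.kind,
                    "nominal_rate": c.nominal_rate,
                }
                for c in self.cues
            ],
            "conditions": [
                {
                    "fingers": list(c.fingers),
                    "frequency": c.frequency,
                    "phase": c.phase,
                    "start": c.start,
                    "end": c.end,
                    "label": c.label,
                }
                for c in self.conditions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskProtocol":
        seq = d.get("sequence")
        return cls(
            task_kind=d["task_kind"],
            trials=[TrackingTrialSpec(**t) for t in d.get("trials", [])],
            cues=[
                CueEvent(c["time"], tuple(c["fingers"]), c["kind"], c.get("nominal_rate"))
                for c in d.get("cues", [])
            ],
            conditions=[
                Condition(
                    tuple(c["fingers"]),
                    c["frequency"],
                    c["phase"],
                    c["start"],
                    c["end"],
                    c.get("label", ""),
                )
                for c in d.get("conditions", [])
            ],
            total_duration=d["total_duration"],
            sequence=SequenceSpec(tuple(seq["digits"]), seq.get("label", "")) if seq else None,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TaskProtocol":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_tracking_protocol(
    target_forces: Sequence[float] = (1.0, 2.0),
    trials_per_block: int = 6,
    blocks_per_force: int = 2,
    ramp_s: float = 1.5,
    hold_s: float = 4.0,
    rest_s: float = 2.0,
) -> TaskProtocol:
    """Ramp-hold-release tracking schedule.

    Defaults reproduce the reference protocol: 24 trials in 4 blocks of 6,
    two blocks at 1 N and two at 2 N, each trial 1.5 s ramp + 4 s hold + 2 s
    rest.
    """
    if min(ramp_s, hold_s, rest_s) <= 0:
        raise InvalidParameterError("phase durations must be > 0")
    if any(f <= 0 for f in target_forces):
        raise InvalidParameterError("target forces must be > 0")
    if trials_per_block < 1 or blocks_per_force < 1:
        raise InvalidParameterError("trial/block counts must be >= 1")

    trials: list[TrackingTrialSpec] = []
    t = 0.0
    idx = 0
    block = 0
    for force in target_forces:
        for _ in range(blocks_per_force):
            for _ in range(trials_per_block):
                trials.append(
                    TrackingTrialSpec(idx, block, float(force), t, ramp_s, hold_s, rest_s)
                )
                t += ramp_s + hold_s + rest_s
                idx += 1
            block += 1
    conditions = [
        Condition((), float(force), "tracking", 0.0, t, f"{force:g}N")
        for force in target_forces
    ]
    return TaskProtocol("tracking", trials=trials, conditions=conditions, total_duration=t)


def build_sequence_protocol(
    sequence: SequenceSpec,
    cued_repeats: int = 10,
    recall_repeats: int = 5,
    cue_rate: float = 1.0,
) -> TaskProtocol:
    """Sequential five-tap schedule: cued learning trials then uncued recall.

    Each trial occupies a window of ``len(sequence)/cue_rate`` seconds (5 s at
    the default 1 Hz); cued trials carry one visual cue per sequence element.
    """
    if cued_repeats < 0 or recall_repeats < 0:
        raise InvalidParameterError("repeat counts must be >= 0")
    if cue_rate <= 0:
        raise InvalidParameterError("cue_rate must be > 0")

    n_taps = len(sequence.digits)
    trial_dur = n_taps / cue_rate
    cues: list[CueEvent] = []
    conditions: list[Condition] = []
    t = 0.0
    for r in range(cued_repeats):
        for i, finger in enumerate(sequence.fingers):
            cues.append(CueEvent(t + i / cue_rate, (finger,), "visual_tap_cue", cue_rate))
        conditions.append(
            Condition((), cue_rate, "learning", t, t + trial_dur, f"learning{r}")
        )
        t += trial_dur
    for r in range(recall_repeats):
        conditions.append(
            Condition((), cue_rate, "recall", t, t + trial_dur, f"recall{r}")
        )
        t += trial_dur
    return TaskProtocol(
        "sequential", cues=cues, conditions=conditions, total_duration=t, sequence=sequence
    )


def build_single_tap_protocol(
    frequencies: Sequence[float] = (1.0, 2.0, 3.0),
    fingers: Sequence[str] = FINGERS,
    taps_per_cued_phase: int = 15,
) -> TaskProtocol:
    """Single-finger tapping schedule: per (frequency, finger) condition a
    metronome-cued phase of ``taps_per_cued_phase`` taps, then an uncued phase
    of equal duration at the same intended rate.

    Conditions are ordered frequency-major, finger-minor (index→little at
    1 Hz, then 2 Hz, then 3 Hz with the defaults).
    """
    if not fingers:
        raise InvalidParameterError("finger list must be non-empty")
    if any(f not in FINGERS for f in fingers):
        raise InvalidParameterError(f"fingers must be in {FINGERS}")
    if any(f <= 0 for f in frequencies):
        raise InvalidParameterError("frequencies must be > 0")
    if taps_per_cued_phase < 1:
        raise InvalidParameterError("taps_per_cued_phase must be >= 1")

    cues: list[CueEvent] = []
    conditions: list[Condition] = []
    t = 0.0
    for freq in frequencies:
        phase_dur = taps_per_cued_phase / freq
        for finger in fingers:
            for k in range(taps_per_cued_phase):
                cues.append(
                    CueEvent(t + k / freq, (finger,), "auditory_metronome", float(freq))
                )
            conditions.append(
                Condition((finger,), float(freq), "cued", t, t + phase_dur)
            )
            conditions.append(
                Condition((finger,), float(freq), "uncued", t + phase_dur, t + 2 * phase_dur)
            )
            t += 2 * phase_dur
    return TaskProtocol("single_tap", cues=cues, conditions=conditions, total_duration=t)


def _class_of(fingers: tuple[str, ...]) -> str:
    return {1: "one_finger", 2: "two_finger", 4: "four_finger"}[len(fingers)]


def _transition_balanced(order: Sequence[tuple[str, ...]]) -> bool:
    """|#(1F→2F) − #(2F→1F)| <= 1 over adjacent trial pairs."""
    up = down = 0
    for a, b in zip(order, order[1:]):
        if len(a) == 1 and len(b) == 2:
            up += 1
        elif len(a) == 2 and len(b) == 1:
            down += 1
    return abs(up - down) <= 1


def build_multi_tap_protocol(
    one_finger_repeats: int = 8,
    two_finger_repeats: int = 5,
    four_finger_repeats: int = 2,
    inter_trial_s: float = 4.375,
    seed: int = 0,
    max_retries: int = 10_000,
) -> TaskProtocol:
    """Multi-finger tapping schedule.

    Defaults give 4×8 one-finger + 6×5 two-finger + 2 four-finger = 64 cue
    trials. Trial order is a seeded permutation accepted only if the numbers
    of one→two and two→one finger transitions differ by at most one (seeded
    rejection sampling; best-effort with a warning if no permutation within
    ``max_retries`` satisfies the constraint).
    """
    if min(one_finger_repeats, two_finger_repeats, four_finger_repeats) < 0:
        raise InvalidParameterError("repeat counts must be >= 0")
    if inter_trial_s <= 0:
        raise InvalidParameterError("inter_trial_s must be > 0")

    configs: list[tuple[str, ...]] = []
    configs += [(f,) for f in FINGERS for _ in range(one_finger_repeats)]
    configs += [
        pair for pair in combinations(FINGERS, 2) for _ in range(two_finger_repeats)
    ]
    configs += [FINGERS for _ in range(four_finger_repeats)]

    rng = np.random.default_rng(seed)
    order = list(configs)
    ok = False
    for _ in range(max_retries):
        perm = rng.permutation(len(order))
        candidate = [configs[i] for i in perm]
        if _transition_balanced(candidate):
            order = candidate
            ok = True
            break
    if not ok and configs:
        warnings.warn(
            "could not satisfy the one/two-finger transition balance; "
            "using the last sampled order",
            stacklevel=2,
        )
        order = candidate  # type: ignore[possibly-undefined]

    cues: list[CueEvent] = []
    conditions: list[Condition] = []
    for k, fingers in enumerate(order):
        t = k * inter_trial_s
        cues.append(CueEvent(t, fingers, "visual_tap_cue"))
        conditions.append(
            Condition(fingers, None, _class_of(fingers), t, t + inter_trial_s)
        )
    total = len(order) * inter_trial_s
    return TaskProtocol("multi_tap", cues=cues, conditions=conditions, total_duration=total)
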