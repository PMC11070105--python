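"""Core domain types shared across the pipeline.

All times are expressed in seconds from lights-off (t = 0).  Events are
half-open intervals ``[start, end)`` so that overlap and tiling tests are
unambiguous.  A hypnogram is a sequence of 30-s epoch stage labels drawn
from ``{"W", "N1", "N2", "N3", "REM"}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

EPOCH_S = 30.0
#: Sleep stages mapped to the binary "sleep" class (wake is the complement).
SLEEP_STAGES = ("N1", "N2", "N3", "REM")
STAGES = ("W",) + SLEEP_STAGES

__all__ = [
    "EPOCH_S",
    "SLEEP_STAGES",
    "STAGES",
    "EventInterval",
    "SimConfig",
    "SubjectRecord",
    "RRSeries",
    "EffortSeries",
    "SegmentTensor",
    "SegmentStore",
    "FoldPlan",
    "Thresholds",
]


@dataclass(frozen=True)
class EventInterval:
    """One scored or detected respiratory event, half-open ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    kind: str = "apnea"  # "apnea" | "hypopnea" | "detected"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.start_s) and math.isfinite(self.end_s)):
            raise ValueError("event bounds must be finite")
        if self.end_s <= self.start_s:
            raise ValueError(
                f"event end ({self.end_s}) must exceed start ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlap_s(self, other: "EventInterval") -> float:
        return max(
            0.0, min(self.end_s, other.end_s) - max(self.start_s, other.start_s)
        )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated overnight record.

    Parameters
    ----------
    tib_hours
        Time in bed (lights-off to lights-on), hours.
    sleep_efficiency
        Target TST/TIB in [0, 1]; realized efficiency is random around it.
    ahi_target
        Target event rate, events per hour of sleep (>= 0).
    event_duration_s
        ``(min, max)`` event duration in seconds; the scoring minimum of
        10 s applies, so ``min >= 10``.
    hypopnea_fraction
        Probability that an event is a hypopnea (partial effort reduction)
        rather than an apnea (near-complete reduction).
    hr_base_bpm
        Resting heart rate, beats per minute.
    hrv_sd_ms
        Scale of beat-to-beat RR variability during sleep, milliseconds.
    wake_hrv_multiplier
        Multiplicative inflation of RR variability during wake (> 1).
    effort_fs_hz
        Sampling rate of the raw respiratory-effort waveform, Hz.
    noise_sd
        Additive broadband noise on the effort trace (signal units; the
        clean breathing oscillation has unit amplitude).
    seed
        Seed for the subject's private random stream.
    """

    tib_hours: float = 8.0
    sleep_efficiency: float = 0.85
    ahi_target: float = 15.0
    event_duration_s: tuple[float, float] = (10.0, 40.0)
    hypopnea_fraction: float = 0.5
    hr_base_bpm: float = 65.0
    hrv_sd_ms: float = 40.0
    wake_hrv_multiplier: float = 2.5
    effort_fs_hz: float = 32.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [
            self.tib_hours,
            self.sleep_efficiency,
            self.ahi_target,
            *self.event_duration_s,
            self.hypopnea_fraction,
            self.hr_base_bpm,
            self.hrv_sd_ms,
            self.wake_hrv_multiplier,
            self.effort_fs_hz,
            self.noise_sd,
        ]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all SimConfig values must be finite")
        if self.tib_hours <= 0:
            raise ValueError("tib_hours must be positive")
        if not 0.0 <= self.sleep_efficiency <= 1.0:
            raise ValueError("sleep_efficiency must lie in [0, 1]")
        if self.ahi_target < 0:
            raise ValueError("ahi_target must be non-negative")
        lo, hi = self.event_duration_s
        if lo < 10.0 or hi < lo:
            raise ValueError("event durations must satisfy 10 <= min <= max")
        if not 0.0 <= self.hypopnea_fraction <= 1.0:
            raise ValueError("hypopnea_fraction must lie in [0, 1]")
        if self.hr_base_bpm <= 0 or self.hrv_sd_ms < 0 or self.noise_sd < 0:
            raise ValueError("rates and scales must be non-negative")
        if self.wake_hrv_multiplier <= 1.0:
            raise ValueError("wake_hrv_multiplier must exceed 1")
        if self.effort_fs_hz < 4.0:
            raise ValueError("effort_fs_hz must be at least 4 Hz")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SubjectRecord:
    """One overnight record: cardiac beats, effort, hypnogram, scored events."""

    subject_id: str
    beat_times_s: np.ndarray
    beat_artifact_mask: np.ndarray  # True = artifact/ectopic, excluded
    effort: np.ndarray
    effort_fs_hz: float
    hypnogram: list[str]
    events: list[EventInterval]
    lights_off_s: float
    lights_on_s: float
    ahi_ref: float

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.beat_artifact_mask = np.asarray(self.beat_artifact_mask, dtype=bool)
        self.effort = np.asarray(self.effort, dtype=float)
        if self.beat_times_s.size != self.beat_artifact_mask.size:
            raise ValueError("beat times and artifact mask lengths differ")
        if self.beat_times_s.size >= 2 and not np.all(
            np.diff(self.beat_times_s) > 0
        ):
            raise ValueError("beat times must be strictly increasing")
        if self.effort_fs_hz <= 0:
            raise ValueError("effort sampling rate must be positive")
        n_epochs = int((self.lights_on_s - self.lights_off_s) // EPOCH_S)
        if len(self.hypnogram) != n_epochs:
            raise ValueError(
                f"hypnogram length {len(self.hypnogram)} does not match "
                f"floor(TIB/30) = {n_epochs}"
            )
        bad = set(self.hypnogram) - set(STAGES)
        if bad:
            raise ValueError(f"unknown sleep stages: {sorted(bad)}")
        for ev in self.events:
            if ev.start_s < self.lights_off_s or ev.end_s > self.lights_on_s:
                raise ValueError(
                    f"event [{ev.start_s}, {ev.end_s}) outside lights window "
                    f"[{self.lights_off_s}, {self.lights_on_s})"
                )

    @property
    def tib_hours(self) -> float:
        return (self.lights_on_s - self.lights_off_s) / 3600.0

    @property
    def tst_ref_hours(self) -> float:
        n_sleep = sum(1 for s in self.hypnogram if s in SLEEP_STAGES)
        return n_sleep * EPOCH_S / 3600.0

    @property
    def sleep_efficiency_ref(self) -> float:
        tib = self.tib_hours
        return self.tst_ref_hours / tib if tib > 0 else float("nan")


@dataclass
class RRSeries:
    """RR-interval tachogram on a uniform 4 Hz grid (values in seconds)."""

    values: np.ndarray
    t0_s: float
    fs: float = 4.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs != 4.0:
            raise ValueError("RR series must be sampled at exactly 4 Hz")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RR series contains non-finite values")


@dataclass
class EffortSeries:
    """Conditioned respiratory-effort trace on a uniform 4 Hz grid."""

    values: np.ndarray
    t0_s: float
    fs: float = 4.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs != 4.0:
            raise ValueError("effort series must be sampled at exactly 4 Hz")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("effort series contains non-finite values")


SEGMENT_LEN_S = 300
SEGMENT_STEP_S = 180
SEGMENT_X_LEN = 1200  # 300 s at 4 Hz
SEGMENT_EVENT_LEN = 300  # 1 Hz event labels
SEGMENT_SLEEP_LEN = 10  # 1/30 Hz sleep labels


@dataclass
class SegmentTensor:
    """One 5-min training window with dual-resolution labels."""

    X: np.ndarray  # (1200, 2): col 0 = RR, col 1 = effort
    y_event: np.ndarray  # (300,) binary
    y_sleep: np.ndarray  # (10,) binary
    start_s: float
    subject_id: str
    usable: bool = True

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y_event = np.asarray(self.y_event, dtype=np.int8)
        self.y_sleep = np.asarray(self.y_sleep, dtype=np.int8)
        if self.X.shape != (SEGMENT_X_LEN, 2):
            raise ValueError(f"X must have shape (1200, 2), got {self.X.shape}")
        if self.y_event.shape != (SEGMENT_EVENT_LEN,):
            raise ValueError(f"y_event must have shape (300,), got {self.y_event.shape}")
        if self.y_sleep.shape != (SEGMENT_SLEEP_LEN,):
            raise ValueError(f"y_sleep must have shape (10,), got {self.y_sleep.shape}")
        for name, y in (("y_event", self.y_event), ("y_sleep", self.y_sleep)):
            if not np.isin(y, (0, 1)).all():
                raise ValueError(f"{name} must be binary")


@dataclass
class SegmentStore:
    """Stacked segments of one or more subjects."""

    X: np.ndarray  # (n, 1200, 2)
    y_event: np.ndarray  # (n, 300)
    y_sleep: np.ndarray  # (n, 10)
    start_times_s: np.ndarray  # (n,)
    subject_ids: np.ndarray  # (n,) str
    usable: np.ndarray | None = None  # (n,) bool

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y_event = np.asarray(self.y_event, dtype=np.int8)
        self.y_sleep = np.asarray(self.y_sleep, dtype=np.int8)
        self.start_times_s = np.asarray(self.start_times_s, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids, dtype=str)
        if self.usable is None:
            self.usable = np.ones(len(self.X), dtype=bool)
        self.usable = np.asarray(self.usable, dtype=bool)
        n = len(self.X)
        if self.X.shape != (n, SEGMENT_X_LEN, 2):
            raise ValueError(f"X must have shape (n, 1200, 2), got {self.X.shape}")
        if self.y_event.shape != (n, SEGMENT_EVENT_LEN):
            raise ValueError(
                f"y_event must have shape (n, 300), got {self.y_event.shape}"
            )
        if self.y_sleep.shape != (n, SEGMENT_SLEEP_LEN):
            raise ValueError(
                f"y_sleep must have shape (n, 10), got {self.y_sleep.shape}"
            )
        for arr, nm in (
            (self.start_times_s, "start_times_s"),
            (self.subject_ids, "subject_ids"),
            (self.usable, "usable"),
        ):
            if len(arr) != n:
                raise ValueError(f"{nm} length {len(arr)} != n segments {n}")
        for name, y in (("y_event", self.y_event), ("y_sleep", self.y_sleep)):
            if y.size and not np.isin(y, (0, 1)).all():
                raise ValueError(f"{name} must be binary")

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, index) -> "SegmentStore":
        return SegmentStore(
            X=self.X[index],
            y_event=self.y_event[index],
            y_sleep=self.y_sleep[index],
            start_times_s=self.start_times_s[index],
            subject_ids=self.subject_ids[index],
            usable=self.usable[index],
        )

    def for_subjects(self, subjects) -> "SegmentStore":
        mask = np.isin(self.subject_ids, list(subjects))
        return self.subset(mask)

    @staticmethod
    def from_segments(segments: list[SegmentTensor]) -> "SegmentStore":
        if not segments:
            return SegmentStore(
                X=np.zeros((0, SEGMENT_X_LEN, 2), np.float32),
                y_event=np.zeros((0, SEGMENT_EVENT_LEN), np.int8),
                y_sleep=np.zeros((0, SEGMENT_SLEEP_LEN), np.int8),
                start_times_s=np.zeros(0),
                subject_ids=np.array([], dtype=str),
                usable=np.zeros(0, bool),
            )
        return SegmentStore(
            X=np.stack([s.X for s in segments]),
            y_event=np.stack([s.y_event for s in segments]),
            y_sleep=np.stack([s.y_sleep for s in segments]),
            start_times_s=np.array([s.start_s for s in segments]),
            subject_ids=np.array([s.subject_id for s in segments]),
            usable=np.array([s.usable for s in segments]),
        )


@dataclass
class FoldPlan:
    """Subject role assignment for each cross-validation iteration."""

    iterations: list[dict[str, list[str]]] = field(default_factory=list)
    # each dict has keys "train", "val", "test" -> sorted subject-id lists

    def roles(self, iteration: int) -> dict[str, list[str]]:
        return self.iterations[iteration]

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def validate(self) -> None:
        all_subjects = None
        for it in self.iterations:
            sets = {k: set(v) for k, v in it.items()}
            union = sets["train"] | sets["val"] | sets["test"]
            if sum(len(s) for s in sets.values()) != len(union):
                raise ValueError("subject assigned to multiple roles in one iteration")
            if all_subjects is None:
                all_subjects = union
            elif union != all_subjects:
                raise ValueError("iterations do not cover the same subject set")
        test_union: set[str] = set()
        for it in self.iterations:
            tset = set(it["test"])
            if test_union & tset:
                raise ValueError("test folds overlap across iterations")
            test_union |= tset
        if all_subjects is not None and test_union != all_subjects:
            raise ValueError("test folds do not partition the subjects")


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds selected on validation data only."""

    sleep_thr: float
    event_thr: float

    def __post_init__(self) -> None:
        for v in (self.sleep_thr, self.event_thr):
            if not 0.0 < v < 1.0:
                raise ValueError("thresholds must lie strictly in (0, 1)")
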