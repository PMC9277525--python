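"""Shared domain types for the active-test monitoring pipeline.

The vocabulary follows the remote-monitoring design: eight brief
self-administered *active tests* (two cognitive, six motor), each yielding a
single scalar feature per session, administered on a 4-week daily/weekly
schedule across three study contexts and three cohorts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np


class Study(str, enum.Enum):
    OLE = "OLE"
    HD_NHS = "HD_NHS"
    DIGITAL_HD = "DIGITAL_HD"


class Cohort(str, enum.Enum):
    CONTROL = "control"
    PREMANIFEST = "premanifest"
    MANIFEST = "manifest"


class TestType(str, enum.Enum):
    SDMT = "sdmt"
    SWR = "swr"
    SPEEDED_TAPPING = "speeded_tapping"
    DRAW_A_SHAPE = "draw_a_shape"
    CHOREA = "chorea"
    BALANCE = "balance"
    U_TURN = "u_turn"
    WALKING = "walking"


#: Tests administered once per hand.
PER_HAND_TESTS = frozenset(
    {TestType.SPEEDED_TAPPING, TestType.DRAW_A_SHAPE, TestType.CHOREA}
)

#: Tests performed with the device worn at the waist (placement-sensitive).
AMBULATORY_TESTS = frozenset({TestType.WALKING, TestType.U_TURN, TestType.BALANCE})

#: Tests scheduled weekly rather than daily.
WEEKLY_TESTS = frozenset({TestType.SDMT, TestType.SWR})

#: Nominal test duration in seconds.
TEST_DURATION_S = {
    TestType.SDMT: 90.0,
    TestType.SWR: 45.0,
    TestType.SPEEDED_TAPPING: 30.0,
    TestType.DRAW_A_SHAPE: 30.0,
    TestType.CHOREA: 30.0,
    TestType.BALANCE: 30.0,
    TestType.U_TURN: 60.0,
    TestType.WALKING: 120.0,
}


class Hand(str, enum.Enum):
    DOMINANT = "D"
    NONDOMINANT = "ND"


class Placement(str, enum.Enum):
    POUCH = "pouch"
    POCKET = "pocket"


class FeatureName(str, enum.Enum):
    SDMT_CORRECT = "sdmt_correct"
    SWR_CORRECT = "swr_correct"
    INTERTAP_MEAN_MS = "intertap_mean_ms"
    SPIRAL_SPEED_CV = "spiral_speed_cv"
    SWAY_PATH = "sway_path"
    TURN_SPEED_MEDIAN = "turn_speed_median"
    STEP_FREQ_VARIANCE = "step_freq_variance"


#: Units printed alongside each feature.
FEATURE_UNITS = {
    FeatureName.SDMT_CORRECT: "count",
    FeatureName.SWR_CORRECT: "count",
    FeatureName.INTERTAP_MEAN_MS: "ms",
    FeatureName.SPIRAL_SPEED_CV: "unitless",
    FeatureName.SWAY_PATH: "m/s^2",
    FeatureName.TURN_SPEED_MEDIAN: "rad/s",
    FeatureName.STEP_FREQ_VARIANCE: "Hz^2",
}

#: Feature produced by each test.
TEST_FEATURE = {
    TestType.SDMT: FeatureName.SDMT_CORRECT,
    TestType.SWR: FeatureName.SWR_CORRECT,
    TestType.SPEEDED_TAPPING: FeatureName.INTERTAP_MEAN_MS,
    TestType.DRAW_A_SHAPE: FeatureName.SPIRAL_SPEED_CV,
    TestType.CHOREA: FeatureName.SWAY_PATH,
    TestType.BALANCE: FeatureName.SWAY_PATH,
    TestType.U_TURN: FeatureName.TURN_SPEED_MEDIAN,
    TestType.WALKING: FeatureName.STEP_FREQ_VARIANCE,
}


class ConfigurationError(ValueError):
    """Raised for invalid specifications, unknown enums or missing rules."""


class InsufficientDataError(ValueError):
    """Raised when an analysis has fewer observations than its minimum."""


@dataclass
class SensorRecording:
    """Uniformly sampled tri-axial IMU streams for one session.

    Parameters
    ----------
    t : array of float
        Seconds from session start, strictly increasing.
    acc : (n, 3) array or None
        Tri-axial acceleration in m/s^2.
    gyro : (n, 3) array or None
        Tri-axial angular rate in rad/s.
    """

    t: np.ndarray
    acc: Optional[np.ndarray] = None
    gyro: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.acc is not None:
            self.acc = np.asarray(self.acc, dtype=float)
        if self.gyro is not None:
            self.gyro = np.asarray(self.gyro, dtype=float)
        if self.t.size < 2:
            raise ValueError("sensor recording needs at least 2 samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        for name, arr in (("acc", self.acc), ("gyro", self.gyro)):
            if arr is None:
                continue
            if arr.shape != (self.t.size, 3):
                raise ValueError(f"{name} must have shape (n, 3) matching t")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class TestSession:
    """One administration of one active test."""

    participant_id: str
    test: TestType
    day: int
    hand: Optional[Hand] = None
    placement: Placement = Placement.POUCH
    payload: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.test = TestType(self.test)
        if self.hand is not None:
            self.hand = Hand(self.hand)
        self.placement = Placement(self.placement)


@dataclass
class QcStatus:
    passed: bool
    reason: Optional[str] = None

    @classmethod
    def ok(cls) -> "QcStatus":
        return cls(True)

    @classmethod
    def fail(cls, reason: str) -> "QcStatus":
        return cls(False, reason)

    def __str__(self) -> str:
        return "pass" if self.passed else f"fail({self.reason})"


@dataclass
class FeatureValue:
    """A session's scalar feature readout with its QC status."""

    participant_id: str
    test: TestType
    day: int
    feature: FeatureName
    value: Optional[float]
    units: str
    hand: Optional[Hand] = None
    qc_status: QcStatus = field(default_factory=QcStatus.ok)

    def __post_init__(self) -> None:
        if self.qc_status.passed:
            if self.value is None or not np.isfinite(self.value):
                raise ValueError("passing feature values must be finite")
        expected = FEATURE_UNITS[FeatureName(self.feature)]
        if self.units != expected:
            raise ValueError(
                f"units for {self.feature} must be {expected!r}, got {self.units!r}"
            )


#: Clinical score scale ranges (inclusive), used by generator invariant checks.
CLINICAL_RANGES = {
    "tms": (0, 124),
    "tfc": (0, 13),
    "chorea_d": (0, 4),
    "chorea_nd": (0, 4),
    "finger_taps_d": (0, 4),
    "finger_taps_nd": (0, 4),
    "balance_score": (0, 8),
    "swr_clinic": (0, 130),
    "sdmt_clinic": (0, 110),
    "intertap_clinic_ms": (50, 2000),
}


@dataclass
class ParticipantRecord:
    """Study membership, demographics and in-clinic scores for one person."""

    id: str
    study: Study
    cohort: Cohort
    age: float
    dominant_hand: str
    severity: float
    clinical: dict[str, float]
    seed: int = 0

    def __post_init__(self) -> None:
        self.study = Study(self.study)
        self.cohort = Cohort(self.cohort)
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        for key, (lo, hi) in CLINICAL_RANGES.items():
            if key in self.clinical and not lo <= self.clinical[key] <= hi:
                raise ValueError(f"clinical score {key}={self.clinical[key]} outside [{lo}, {hi}]")


@dataclass
class ScheduleEntry:
    day: int
    test: TestType
    hand: Optional[Hand]
    scheduled: bool
    completed: bool
    placement: Placement

    def __post_init__(self) -> None:
        if self.completed and not self.scheduled:
            raise ValueError("completed implies scheduled")


@dataclass
class Schedule:
    participant_id: str
    entries: list[ScheduleEntry]

    @property
    def n_scheduled(self) -> int:
        return sum(e.scheduled for e in self.entries)

    @property
    def n_completed(self) -> int:
        return sum(e.completed for e in self.entries)
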