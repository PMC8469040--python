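"""Domain types for posture observations, RULA scores, and exposure results.

Angle conventions: all body-segment angles are in degrees, flexion positive.
The upper arm admits extension as a negative angle; wrist deviation from
neutral is taken as an absolute value (flexion vs. extension is irrelevant
to the banding). Neck extension and trunk support are carried as flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Annotated

from pydantic import BaseModel, ConfigDict, Field


class DomainError(ValueError):
    """An argument fell outside the ordinal domain an operation is defined on."""


class InvalidObservationError(ValueError):
    """A posture observation violates its invariants (non-finite angle, ...)."""


class SchemaError(ValueError):
    """An observation table does not conform to the published column schema."""


Angle = Annotated[float, Field(allow_inf_nan=False)]


class PostureObservation(BaseModel):
    """One observed worker-task posture episode.

    Defaults encode a neutral standing posture (all angles zero, feet
    supported, no load, no repetition) so that tests and examples only
    need to state what deviates from neutral.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    worker_id: str = Field(min_length=1)
    task_id: str = Field(min_length=1)
    observer_id: str = "obs1"

    upper_arm_flexion: Angle = 0.0  # degrees; negative = extension
    shoulder_raised: bool = False
    upper_arm_abducted: bool = False
    arm_supported_or_leaning: bool = False

    lower_arm_flexion: Angle = 80.0  # degrees; 60-100 is the neutral band
    arm_across_midline_or_out: bool = False

    wrist_flexion: Angle = 0.0  # absolute deviation from neutral, degrees
    wrist_deviated: bool = False  # ulnar/radial bend
    wrist_twist_end_range: bool = False

    neck_flexion: Angle = 0.0
    neck_in_extension: bool = False
    neck_twisted: bool = False
    neck_side_bent: bool = False

    trunk_flexion: Angle = 0.0
    trunk_twisted: bool = False
    trunk_side_bent: bool = False

    legs_and_feet_supported: bool = True

    posture_static_over_1min: bool = False
    repetitions_per_min: float = Field(default=0.0, ge=0, allow_inf_nan=False)
    load_kg: float = Field(default=0.0, ge=0, allow_inf_nan=False)
    load_static_or_repeated: bool = False
    shock_or_rapid_force: bool = False

    task_hours: float = Field(default=1.0, gt=0, allow_inf_nan=False)
    vibration_present: bool = False


def _check_range(name: str, value: int, lo: int, hi: int) -> None:
    if not isinstance(value, int) or isinstance(value, bool):
        raise DomainError(f"{name} must be an integer, got {value!r}")
    if not lo <= value <= hi:
        raise DomainError(f"{name}={value} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class ArmWristScores:
    """Segment scores for the arm/wrist (group A) side."""

    upper_arm: int
    lower_arm: int
    wrist: int
    wrist_twist: int

    def __post_init__(self) -> None:
        _check_range("upper_arm", self.upper_arm, 1, 6)
        _check_range("lower_arm", self.lower_arm, 1, 3)
        _check_range("wrist", self.wrist, 1, 4)
        _check_range("wrist_twist", self.wrist_twist, 1, 2)


@dataclass(frozen=True)
class NeckTrunkLegsScores:
    """Segment scores for the neck/trunk/legs (group B) side."""

    neck: int
    trunk: int
    legs: int

    def __post_init__(self) -> None:
        _check_range("neck", self.neck, 1, 6)
        _check_range("trunk", self.trunk, 1, 6)
        _check_range("legs", self.legs, 1, 2)


@dataclass(frozen=True)
class RulaScoreBreakdown:
    """Every intermediate RULA score for one worker-task observation.

    score_c = posture_a + muscle_a + force_a (arm/wrist side) and
    score_d = posture_b + muscle_b + force_b (neck/trunk/legs side);
    the grand score combines them and the action level bands the grand
    score into the four intervention urgencies.
    """

    worker_id: str
    task_id: str
    arm_wrist: ArmWristScores
    neck_trunk_legs: NeckTrunkLegsScores
    posture_a: int
    posture_b: int
    muscle_a: int
    muscle_b: int
    force_a: int
    force_b: int
    score_c: int
    score_d: int
    grand: int
    action_level: int

    def __post_init__(self) -> None:
        _check_range("posture_a", self.posture_a, 1, 9)
        _check_range("posture_b", self.posture_b, 1, 9)
        _check_range("muscle_a", self.muscle_a, 0, 1)
        _check_range("muscle_b", self.muscle_b, 0, 1)
        _check_range("force_a", self.force_a, 0, 3)
        _check_range("force_b", self.force_b, 0, 3)
        _check_range("grand", self.grand, 1, 7)
        _check_range("action_level", self.action_level, 1, 4)
        if self.score_c != self.posture_a + self.muscle_a + self.force_a:
            raise DomainError("score_c != posture_a + muscle_a + force_a")
        if self.score_d != self.posture_b + self.muscle_b + self.force_b:
            raise DomainError("score_d != posture_b + muscle_b + force_b")


class ExposureClass(str, Enum):
    """Ordinal exposure classification of an exposure value."""

    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"
    VERY_HIGH = "very_high"

    @property
    def rank(self) -> int:
        return _EC_RANK[self]


_EC_RANK = {
    ExposureClass.LOW: 0,
    ExposureClass.MEDIUM: 1,
    ExposureClass.HIGH: 2,
    ExposureClass.VERY_HIGH: 3,
}


DURATION_BAND_LABELS: dict[int, str] = {1: "<1 h", 2: "1-3 h", 3: "3-7 h", 4: "7+ h"}


@dataclass(frozen=True)
class DurationBand:
    """Ordinal coding of hours spent on a task over one working day."""

    band: int

    def __post_init__(self) -> None:
        _check_range("band", self.band, 1, 4)

    @property
    def hour_range(self) -> str:
        return DURATION_BAND_LABELS[self.band]


@dataclass(frozen=True)
class TaskExposure:
    """Per-task extended result: exposure value and its classification."""

    task_id: str
    ral: int
    duration_band: int
    vibration: int
    exposure_value: int
    classification: ExposureClass
    in_gap_bin: bool = False  # EV fell in a gap of the printed bin edges

    def __post_init__(self) -> None:
        _check_range("ral", self.ral, 1, 4)
        _check_range("duration_band", self.duration_band, 1, 4)
        _check_range("vibration", self.vibration, 0, 1)
        if self.exposure_value != self.duration_band * self.ral + self.vibration:
            raise DomainError("exposure_value != duration_band * ral + vibration")


@dataclass(frozen=True)
class DescriptiveStats:
    """Mean/SD/median/min/max summary of action levels across workers."""

    mean: float
    sd: float  # sample SD (n-1); 0 with single_observation flag when n == 1
    median: float
    minimum: int
    maximum: int
    n: int
    single_observation: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("n must be >= 1")
        if not (self.minimum <= self.median <= self.maximum):
            raise DomainError("expected minimum <= median <= maximum")
        if self.sd < 0:
            raise DomainError("sd must be >= 0")


class ECGroup(str, Enum):
    """Exposure group: A = any high/very-high task, B = low/medium only."""

    A = "A"
    B = "B"


class PriorityAction(str, Enum):
    """The four intervention actions of the priority matrix."""

    ELIMINATE_IMMEDIATELY = "eliminate_immediately"
    ELIMINATE_SOON = "eliminate_soon"
    INVESTIGATE_FURTHER = "investigate_further"
    ACCEPTABLE = "acceptable"

    @property
    def severity(self) -> int:
        return _ACTION_SEVERITY[self]


_ACTION_SEVERITY = {
    PriorityAction.ACCEPTABLE: 0,
    PriorityAction.INVESTIGATE_FURTHER: 1,
    PriorityAction.ELIMINATE_SOON: 2,
    PriorityAction.ELIMINATE_IMMEDIATELY: 3,
}


@dataclass(frozen=True)
class WorkerProfile:
    """A worker's tasks over one working day: exposures plus hours per task."""

    worker_id: str
    task_exposures: list[TaskExposure]
    task_hours: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.task_exposures:
            raise DomainError(f"worker {self.worker_id}: empty task list")
        for task_id, hours in self.task_hours.items():
            if not (math.isfinite(hours) and hours > 0):
                raise DomainError(
                    f"worker {self.worker_id}, task {task_id}: hours must be > 0"
                )


@dataclass(frozen=True)
class WorkerPriority:
    """Worker-level aggregation: exposure group, daily hours, and action."""

    worker_id: str
    ec_group: ECGroup
    total_daily_hours: float
    action: PriorityAction
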