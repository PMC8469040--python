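"""The exposure-value extension of RULA for unstructured work.

RULA grades posture, muscle use and force but not how long a task is
performed over a working day, nor vibration.  For informal work — where
task durations vary wildly between and within days — the per-task RULA
action level (RAL, 1-4) is extended to an exposure value

    EV = D x RAL + V

where D is an ordinal duration band of hours spent on the task over a
working day (1: <1 h, 2: 1-3 h, 3: 3-7 h, 4: 7+ h) and V is a binary
vibration flag.  The EV is then classified as low (1-2), medium (3-7),
high (8-15) or very high (16+) exposure.

The published bin edges leave gaps (7 and 13-15 are attainable but
unlisted); the classifier closes them contiguously, keeping every printed
edge (3, 8, 16), and ``in_printed_gap`` flags values that fell in a gap so
reports can surface them.
"""

from __future__ import annotations

import math

import numpy as np

from .types import DescriptiveStats, DomainError, ExposureClass, TaskExposure

__all__ = [
    "duration_band",
    "exposure_value",
    "exposure_classification",
    "in_printed_gap",
    "classify_task",
    "average_ral",
    "task_stats",
    "GAP_EXPOSURE_VALUES",
]

#: EVs in the gaps of the printed bins: 7 (3x2+1) and 13 (4x3+1) are
#: attainable; 14-15 lie in the same 13-15 gap and are kept for totality.
GAP_EXPOSURE_VALUES = frozenset({7, 13, 14, 15})


def duration_band(hours: float) -> int:
    """Ordinal duration band for hours spent on a task over a working day.

    [0,1) -> 1, [1,3) -> 2, [3,7) -> 3, [7,inf) -> 4 (half-open,
    lower-inclusive: exactly 3 h ranks in the 3-7 h band).
    """
    if not (isinstance(hours, (int, float)) and math.isfinite(hours)) or hours <= 0:
        raise DomainError(f"task hours must be a finite number > 0, got {hours!r}")
    if hours < 1:
        return 1
    if hours < 3:
        return 2
    if hours < 7:
        return 3
    return 4


def exposure_value(ral: int, duration_band: int, vibration: int) -> int:
    """Exposure value EV = D x RAL + V."""
    for name, value, hi in (
        ("ral", ral, 4),
        ("duration_band", duration_band, 4),
        ("vibration", vibration, 1),
    ):
        lo = 0 if name == "vibration" else 1
        if not isinstance(value, int) or isinstance(value, bool) or not lo <= value <= hi:
            raise DomainError(f"{name}={value!r} outside [{lo}, {hi}]")
    return duration_band * ral + vibration


def exposure_classification(ev: int) -> ExposureClass:
    """Classify an exposure value: <=2 low, 3-7 medium, 8-15 high, 16+ very high."""
    if not isinstance(ev, int) or isinstance(ev, bool) or ev < 1:
        raise DomainError(f"exposure value must be an integer >= 1, got {ev!r}")
    if ev <= 2:
        return ExposureClass.LOW
    if ev <= 7:
        return ExposureClass.MEDIUM
    if ev <= 15:
        return ExposureClass.HIGH
    return ExposureClass.VERY_HIGH


def in_printed_gap(ev: int) -> bool:
    """True when the EV falls in a gap of the published bin edges."""
    return ev in GAP_EXPOSURE_VALUES


def classify_task(task_id: str, ral: int, band: int, vibration: int) -> TaskExposure:
    """Build the full per-task exposure record from (RAL, D, V)."""
    ev = exposure_value(ral, band, vibration)
    return TaskExposure(
        task_id=task_id,
        ral=ral,
        duration_band=band,
        vibration=vibration,
        exposure_value=ev,
        classification=exposure_classification(ev),
        in_gap_bin=in_printed_gap(ev),
    )


def average_ral(action_levels: list[int]) -> int:
    """Average the per-worker action levels of one task to an integer RAL.

    The arithmetic mean is rounded half-up (3.5 -> 4), which keeps the
    summary conservative at the midpoint.
    """
    if not action_levels:
        raise DomainError("average_ral: empty list")
    for level in action_levels:
        if not isinstance(level, int) or isinstance(level, bool) or not 1 <= level <= 4:
            raise DomainError(f"action level {level!r} outside [1, 4]")
    return int(math.floor(sum(action_levels) / len(action_levels) + 0.5))


def task_stats(action_levels: list[int]) -> DescriptiveStats:
    """Descriptive statistics of a task's action levels across workers.

    SD is the sample standard deviation (n-1 denominator); with a single
    observation it is reported as 0 with ``single_observation`` set.
    """
    if not action_levels:
        raise DomainError("task_stats: empty list")
    arr = np.asarray(action_levels, dtype=float)
    n = arr.size
    sd = float(arr.std(ddof=1)) if n >= 2 else 0.0
    return DescriptiveStats(
        mean=float(arr.mean()),
        sd=sd,
        median=float(np.median(arr)),
        minimum=int(arr.min()),
        maximum=int(arr.max()),
        n=int(n),
        single_observation=n == 1,
    )
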