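"""The action priority matrix: worker-level aggregation of task exposures.

A worker's task exposure classifications place them in Group A (any task
high or very high) or Group B (all tasks low/medium).  Crossing the group
with whether the worker spends more than 3 hours per working day on their
tasks yields one of four actions:

    (A, >3 h)  eliminate immediately
    (A, <=3 h) eliminate soon
    (B, >3 h)  further investigation required
    (B, <=3 h) acceptable

The ">3 h" threshold is strict: exactly 3 hours falls in the lower band.
By default the hours criterion is the worker's total daily hours summed
over tasks; ``hours_rule="any-task"`` instead asks whether any single task
exceeds 3 hours.
"""

from __future__ import annotations

from .types import (
    DomainError,
    ECGroup,
    ExposureClass,
    PriorityAction,
    WorkerPriority,
    WorkerProfile,
)

__all__ = ["ec_group", "total_daily_hours", "priority_action", "assess_worker"]

HOURS_THRESHOLD = 3.0


def ec_group(classifications: list[ExposureClass]) -> ECGroup:
    """Group A if any classification is high/very high, else Group B."""
    if not classifications:
        raise DomainError("ec_group: empty list of classifications")
    high = {ExposureClass.HIGH, ExposureClass.VERY_HIGH}
    return ECGroup.A if any(c in high for c in classifications) else ECGroup.B


def total_daily_hours(profile: WorkerProfile) -> float:
    """Total hours the worker spends on all tasks over one working day."""
    if not profile.task_hours:
        raise DomainError(f"worker {profile.worker_id}: no task hours recorded")
    return float(sum(profile.task_hours.values()))


def priority_action(group: ECGroup, total_hours: float) -> PriorityAction:
    """The matrix cell for an exposure group and daily task hours."""
    if not isinstance(group, ECGroup):
        raise DomainError(f"invalid exposure group {group!r}")
    if total_hours <= 0:
        raise DomainError(f"total hours must be > 0, got {total_hours!r}")
    long_day = total_hours > HOURS_THRESHOLD
    if group is ECGroup.A:
        return (
            PriorityAction.ELIMINATE_IMMEDIATELY
            if long_day
            else PriorityAction.ELIMINATE_SOON
        )
    return PriorityAction.INVESTIGATE_FURTHER if long_day else PriorityAction.ACCEPTABLE


def assess_worker(profile: WorkerProfile, hours_rule: str = "total") -> WorkerPriority:
    """Place a worker in the priority matrix.

    ``hours_rule="total"`` compares the worker's summed daily hours with
    the 3 h threshold; ``"any-task"`` compares the longest single task.
    The reported ``total_daily_hours`` is always the sum.
    """
    if hours_rule not in ("total", "any-task"):
        raise DomainError(f"unknown hours_rule {hours_rule!r}")
    group = ec_group([t.classification for t in profile.task_exposures])
    total = total_daily_hours(profile)
    decisive = total if hours_rule == "total" else max(profile.task_hours.values())
    return WorkerPriority(
        worker_id=profile.worker_id,
        ec_group=group,
        total_daily_hours=total,
        action=priority_action(group, decisive),
    )
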