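"""Seeded synthetic observation generator.

Emulates walkthrough posture records of small-scale manual work: per-task
templates give uniform ranges for segment angles, Bernoulli probabilities
for posture flags, and uniform ranges for load, repetition rate and daily
task hours.  The default templates mirror the hand-made cookware study
conditions: loads from light (under 5 kg) to very heavy (over 20 kg),
highly repetitive actions (around 12 per minute), task durations from half
an hour to about ten hours, and vibration confined to the defect-removal
task.

Randomness comes from numpy's PCG64 generator; each worker draws from a
substream derived deterministically from (seed, worker index), so output
is reproducible row-for-row under a fixed seed and stable under parallel
per-worker generation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .io import ObservationTable, Provenance
from .types import PostureObservation

__all__ = ["TaskTemplate", "SimulationConfig", "default_templates", "simulate_observations"]

_FLAG_NAMES = (
    "shoulder_raised",
    "upper_arm_abducted",
    "arm_supported_or_leaning",
    "arm_across_midline_or_out",
    "wrist_deviated",
    "wrist_twist_end_range",
    "neck_in_extension",
    "neck_twisted",
    "neck_side_bent",
    "trunk_twisted",
    "trunk_side_bent",
    "legs_unsupported",
    "posture_static_over_1min",
    "load_static_or_repeated",
    "shock_or_rapid_force",
    "vibration_present",
)


class TaskTemplate(BaseModel):
    """Sampling recipe for one task's posture observations."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    task_id: str = Field(min_length=1)
    upper_arm_range: tuple[float, float] = (0.0, 45.0)
    lower_arm_range: tuple[float, float] = (60.0, 100.0)
    wrist_range: tuple[float, float] = (0.0, 15.0)
    neck_range: tuple[float, float] = (0.0, 20.0)
    trunk_range: tuple[float, float] = (0.0, 20.0)
    load_range_kg: tuple[float, float] = (0.0, 2.0)
    reps_range_per_min: tuple[float, float] = (0.0, 4.0)
    hours_range: tuple[float, float] = (0.5, 2.0)
    flag_probabilities: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _validate(self) -> "TaskTemplate":
        for name in (
            "upper_arm_range",
            "lower_arm_range",
            "wrist_range",
            "neck_range",
            "trunk_range",
            "load_range_kg",
            "reps_range_per_min",
            "hours_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{self.task_id}: {name} is not well-ordered")
        if self.load_range_kg[0] < 0 or self.reps_range_per_min[0] < 0:
            raise ValueError(f"{self.task_id}: load and repetition ranges must be >= 0")
        if self.hours_range[0] <= 0:
            raise ValueError(f"{self.task_id}: hours must be > 0")
        unknown = set(self.flag_probabilities) - set(_FLAG_NAMES)
        if unknown:
            raise ValueError(f"{self.task_id}: unknown flags {sorted(unknown)}")
        for flag, p in self.flag_probabilities.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{self.task_id}: probability {flag}={p} outside [0, 1]")
        return self


class SimulationConfig(BaseModel):
    """Number of workers, task templates and the master seed."""

    model_config = ConfigDict(frozen=True)

    n_workers: int = Field(gt=0)
    tasks: tuple[TaskTemplate, ...] = Field(min_length=1)
    seed: int = 0


def default_templates() -> list[TaskTemplate]:
    """Nine task templates patterned on the cookware operation."""
    rep = {"load_static_or_repeated": 1.0}
    return [
        TaskTemplate(
            task_id="preparing_sand",
            upper_arm_range=(60, 120),
            wrist_range=(10, 30),
            trunk_range=(20, 60),
            load_range_kg=(1, 3),
            reps_range_per_min=(10, 16),
            hours_range=(0.4, 0.9),
            flag_probabilities={"shoulder_raised": 0.6, **rep},
        ),
        TaskTemplate(
            task_id="preparing_flat_sand_surface",
            upper_arm_range=(30, 70),
            wrist_range=(0, 15),
            trunk_range=(55, 80),
            load_range_kg=(1, 3),
            reps_range_per_min=(10, 16),
            hours_range=(1.2, 2.8),
            flag_probabilities=rep,
        ),
        TaskTemplate(
            task_id="loading_sand",
            upper_arm_range=(20, 45),
            trunk_range=(20, 60),
            neck_range=(5, 20),
            load_range_kg=(3, 5),
            reps_range_per_min=(10, 16),
            hours_range=(0.4, 0.9),
            flag_probabilities={"trunk_twisted": 0.5, **rep},
        ),
        TaskTemplate(
            task_id="creating_mould_cavity",
            upper_arm_range=(80, 120),
            trunk_range=(20, 60),
            load_range_kg=(5, 8),
            reps_range_per_min=(10, 16),
            hours_range=(3.5, 6.5),
            flag_probabilities={"trunk_twisted": 0.5, "legs_unsupported": 1.0, **rep},
        ),
        TaskTemplate(
            task_id="dismantling_and_sprinkling_ash",
            upper_arm_range=(20, 45),
            lower_arm_range=(40, 60),
            wrist_range=(5, 15),
            trunk_range=(20, 45),
            load_range_kg=(1, 5),
            hours_range=(0.4, 0.9),
            flag_probabilities={
                "arm_across_midline_or_out": 0.8,
                "wrist_deviated": 0.8,
                "legs_unsupported": 0.7,
            },
        ),
        TaskTemplate(
            task_id="liquifying_metal",
            upper_arm_range=(20, 45),
            trunk_range=(20, 35),
            load_range_kg=(8, 10),
            reps_range_per_min=(10, 16),
            hours_range=(1.2, 2.8),
        ),
        TaskTemplate(
            task_id="transporting_pouring_molten_metal",
            upper_arm_range=(0, 18),
            wrist_range=(0, 0),
            trunk_range=(0, 0),
            load_range_kg=(11, 20),
            hours_range=(0.4, 0.9),
            flag_probabilities={"posture_static_over_1min": 1.0, **rep},
        ),
        TaskTemplate(
            task_id="breaking_the_mould",
            upper_arm_range=(0, 18),
            wrist_range=(0, 0),
            trunk_range=(20, 60),
            load_range_kg=(3, 5),
            reps_range_per_min=(10, 16),
            hours_range=(0.4, 0.9),
            flag_probabilities=rep,
        ),
        TaskTemplate(
            task_id="removing_defects",
            upper_arm_range=(45, 90),
            wrist_range=(16, 35),
            neck_range=(15, 30),
            trunk_range=(20, 60),
            load_range_kg=(20, 25),
            reps_range_per_min=(10, 16),
            hours_range=(7.5, 10.5),
            flag_probabilities={
                "wrist_deviated": 0.8,
                "wrist_twist_end_range": 0.6,
                "neck_twisted": 0.5,
                "trunk_twisted": 0.6,
                "legs_unsupported": 0.7,
                "vibration_present": 1.0,
                **rep,
            },
        ),
    ]


def _sample_observation(
    rng: np.random.Generator, worker_id: str, template: TaskTemplate
) -> PostureObservation:
    def uniform(lo: float, hi: float) -> float:
        return float(round(rng.uniform(lo, hi), 1)) if hi > lo else float(lo)

    flags = {
        name: bool(rng.random() < template.flag_probabilities.get(name, 0.0))
        for name in _FLAG_NAMES
    }
    legs_unsupported = flags.pop("legs_unsupported")
    return PostureObservation(
        worker_id=worker_id,
        task_id=template.task_id,
        upper_arm_flexion=uniform(*template.upper_arm_range),
        lower_arm_flexion=uniform(*template.lower_arm_range),
        wrist_flexion=uniform(*template.wrist_range),
        neck_flexion=uniform(*template.neck_range),
        trunk_flexion=uniform(*template.trunk_range),
        legs_and_feet_supported=not legs_unsupported,
        repetitions_per_min=uniform(*template.reps_range_per_min),
        load_kg=uniform(*template.load_range_kg),
        task_hours=max(0.1, uniform(*template.hours_range)),
        **flags,
    )


def simulate_observations(config: SimulationConfig) -> ObservationTable:
    """Generate ``n_workers x len(tasks)`` schema-valid observation rows."""
    rows: list[PostureObservation] = []
    for index in range(config.n_workers):
        rng = np.random.default_rng([config.seed, index])
        worker_id = f"w{index + 1:02d}"
        for template in config.tasks:
            rows.append(_sample_observation(rng, worker_id, template))
    return ObservationTable(
        rows=rows,
        provenance=Provenance(f"simulated(seed={config.seed})", "memory"),
    )
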