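"""The RULA (Rapid Upper Limb Assessment) scoring engine.

RULA is an observational screening tool for work-related upper-limb load:
body-segment postures are banded into ordinal scores, combined through two
published lookup tables (Table A for the arm/wrist side, Table B for the
neck/trunk/legs side), adjusted for muscle use (static or highly repetitive
work) and force/load, and finally combined through Table C into a grand
score of 1-7.  The grand score maps onto four action levels that grade the
urgency of ergonomic intervention.

The three lookup tables are shipped as CSV assets transcribed from the
published RULA worksheet (McAtamney & Corlett, Applied Ergonomics, 1993)
and are verified against recorded SHA-256 checksums at load time.

Band boundaries follow the worksheet's phrasing: shared boundaries between
two printed bands are lower-inclusive for the upper band (trunk flexed
exactly 20 deg scores the 20-60 band), while strictly-phrased thresholds
(">15 deg", ">60 deg", ">10 kg", "more than 4 times per minute") are strict.
"""

from __future__ import annotations

import csv
import hashlib
import json
from collections import Counter
from functools import lru_cache
from importlib import resources

from .types import (
    ArmWristScores,
    DomainError,
    NeckTrunkLegsScores,
    PostureObservation,
    RulaScoreBreakdown,
)

__all__ = [
    "score_arm_wrist",
    "score_neck_trunk_legs",
    "posture_score_a",
    "posture_score_b",
    "muscle_use_score",
    "force_load_score",
    "grand_score",
    "action_level",
    "score_task",
    "consolidate",
]

_DATA = resources.files("ergorula.data")


class TableIntegrityError(RuntimeError):
    """A shipped lookup-table asset does not match its recorded checksum."""


@lru_cache(maxsize=None)
def _checksums() -> dict[str, str]:
    return json.loads(_DATA.joinpath("checksums.json").read_text(encoding="utf-8"))


@lru_cache(maxsize=None)
def _load_table(name: str, n_keys: int) -> dict[tuple[int, ...], int]:
    """Load a lookup-table CSV asset, verifying its SHA-256 checksum."""
    text = _DATA.joinpath(name).read_text(encoding="utf-8")
    digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
    expected = _checksums().get(name)
    if digest != expected:
        raise TableIntegrityError(
            f"{name}: checksum {digest} does not match recorded {expected}"
        )
    table: dict[tuple[int, ...], int] = {}
    reader = csv.reader(text.splitlines())
    next(reader)  # header
    for row in reader:
        values = [int(v) for v in row]
        table[tuple(values[:n_keys])] = values[n_keys]
    return table


def score_arm_wrist(obs: PostureObservation) -> ArmWristScores:
    """Band the arm/wrist segment angles and flags into ordinal scores.

    Upper arm: 1 for -20..20 deg, 2 for >20 deg extension or 20-45 deg
    flexion, 3 for 45-90 deg, 4 beyond 90 deg; +1 if the shoulder is
    raised, +1 if the arm is abducted, -1 (floored at 1) if the arm is
    supported or the worker leans.  Lower arm: 1 inside 60-100 deg,
    2 outside; +1 working across the midline or out to the side.
    Wrist: 1 in neutral, 2 up to 15 deg, 3 beyond; +1 for ulnar/radial
    deviation.  Wrist twist: 2 at end of twisting range, else 1.
    """
    a = obs.upper_arm_flexion
    if a < -20:
        upper = 2
    elif a < 20:
        upper = 1
    elif a < 45:
        upper = 2
    elif a <= 90:
        upper = 3
    else:
        upper = 4
    upper += int(obs.shoulder_raised) + int(obs.upper_arm_abducted)
    if obs.arm_supported_or_leaning:
        upper = max(1, upper - 1)

    lower = 1 if 60 <= obs.lower_arm_flexion <= 100 else 2
    lower += int(obs.arm_across_midline_or_out)

    w = abs(obs.wrist_flexion)
    if w == 0:
        wrist = 1
    elif w <= 15:
        wrist = 2
    else:
        wrist = 3
    wrist += int(obs.wrist_deviated)

    twist = 2 if obs.wrist_twist_end_range else 1
    return ArmWristScores(upper, lower, wrist, twist)


def score_neck_trunk_legs(obs: PostureObservation) -> NeckTrunkLegsScores:
    """Band the neck/trunk/legs angles and flags into ordinal scores.

    Neck: 1 for 0-10 deg flexion, 2 for 10-20 deg, 3 beyond 20 deg,
    4 in extension; +1 twisted, +1 side-bent.  Trunk: 1 upright and
    supported, 2 up to 20 deg flexion, 3 for 20-60 deg, 4 beyond 60 deg;
    +1 twisted, +1 side-bent.  Legs: 1 if legs and feet are supported and
    balanced, else 2.
    """
    f = obs.neck_flexion
    if obs.neck_in_extension or f < 0:
        neck = 4
    elif f < 10:
        neck = 1
    elif f <= 20:
        neck = 2
    else:
        neck = 3
    neck += int(obs.neck_twisted) + int(obs.neck_side_bent)

    t = obs.trunk_flexion
    if t <= 0:
        trunk = 1
    elif t < 20:
        trunk = 2
    elif t <= 60:
        trunk = 3
    else:
        trunk = 4
    trunk += int(obs.trunk_twisted) + int(obs.trunk_side_bent)

    legs = 1 if obs.legs_and_feet_supported else 2
    return NeckTrunkLegsScores(neck, trunk, legs)


def posture_score_a(s: ArmWristScores) -> int:
    """Table A posture score (1-9) for an arm/wrist score tuple."""
    table = _load_table("table_a.csv", 4)
    return table[(s.upper_arm, s.lower_arm, s.wrist, s.wrist_twist)]


def posture_score_b(s: NeckTrunkLegsScores) -> int:
    """Table B posture score (1-9) for a neck/trunk/legs score tuple."""
    table = _load_table("table_b.csv", 3)
    return table[(s.neck, s.trunk, s.legs)]


def muscle_use_score(obs: PostureObservation) -> int:
    """Muscle-use adjustment: 1 if the posture is held static for over a
    minute or the action repeats more than 4 times per minute, else 0."""
    return int(obs.posture_static_over_1min or obs.repetitions_per_min > 4)


def force_load_score(obs: PostureObservation) -> int:
    """Force/load adjustment (0-3).

    0 for an intermittent load under 2 kg; 1 for 2-10 kg intermittent;
    2 for 2-10 kg static or repeated; 3 for any load over 10 kg or for
    shock / rapid force build-up.
    """
    if obs.shock_or_rapid_force or obs.load_kg > 10:
        return 3
    if obs.load_kg >= 2:
        return 2 if obs.load_static_or_repeated else 1
    return 0


def grand_score(score_c: int, score_d: int) -> int:
    """Table C grand score (1-7) from the two side scores.

    Side scores exceeding the printed table clamp to its last row/column
    (C at 8+, D at 7+).
    """
    if not (isinstance(score_c, int) and isinstance(score_d, int)):
        raise DomainError("grand_score expects integer side scores")
    if score_c < 1 or score_d < 1:
        raise DomainError(f"side scores must be >= 1, got ({score_c}, {score_d})")
    table = _load_table("table_c.csv", 2)
    return table[(min(score_c, 8), min(score_d, 7))]


def action_level(grand: int) -> int:
    """Map the grand score onto the four action levels.

    1-2: posture acceptable if not maintained or repeated for long
    periods; 3-4: further investigation, change may be needed; 5-6:
    investigation and changes required soon; 7: investigation and changes
    required immediately.
    """
    if not isinstance(grand, int) or not 1 <= grand <= 7:
        raise DomainError(f"grand score {grand!r} outside [1, 7]")
    return (1, 1, 2, 2, 3, 3, 4)[grand - 1]


def score_task(obs: PostureObservation) -> RulaScoreBreakdown:
    """Run the full RULA procedure on one observation.

    The muscle-use and force/load adjustments are assessed from the same
    observation fields on both the arm/wrist (A) and neck/trunk/legs (B)
    sides, as on the worksheet.
    """
    aw = score_arm_wrist(obs)
    ntl = score_neck_trunk_legs(obs)
    pa = posture_score_a(aw)
    pb = posture_score_b(ntl)
    muscle = muscle_use_score(obs)
    force = force_load_score(obs)
    score_c = pa + muscle + force
    score_d = pb + muscle + force
    grand = grand_score(score_c, score_d)
    return RulaScoreBreakdown(
        worker_id=obs.worker_id,
        task_id=obs.task_id,
        arm_wrist=aw,
        neck_trunk_legs=ntl,
        posture_a=pa,
        posture_b=pb,
        muscle_a=muscle,
        muscle_b=muscle,
        force_a=force,
        force_b=force,
        score_c=score_c,
        score_d=score_d,
        grand=grand,
        action_level=action_level(grand),
    )


def consolidate(breakdowns: list[RulaScoreBreakdown]) -> RulaScoreBreakdown:
    """Consolidate independent observer sessions of the same worker-task.

    Returns the modal breakdown by grand score; ties between equally
    frequent grand scores are broken toward the higher (more conservative)
    one.  Mirrors the field practice of comparing observers' sheets and
    settling differences by discussion.
    """
    if not breakdowns:
        raise DomainError("consolidate: empty list of breakdowns")
    keys = {(b.worker_id, b.task_id) for b in breakdowns}
    if len(keys) > 1:
        raise DomainError(f"consolidate: mixed worker/task ids {sorted(keys)}")
    counts = Counter(b.grand for b in breakdowns)
    top = max(counts.values())
    chosen_grand = max(g for g, c in counts.items() if c == top)
    return next(b for b in breakdowns if b.grand == chosen_grand)
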