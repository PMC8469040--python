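"""Packaged nine-task hand-made cookware fixture.

The fixture encodes the published per-task assessment of a hand-made
(sand-cast aluminium) cookware operation: nine tasks, each with an average
RULA action level, a duration band, a vibration flag, and the printed
exposure value and classification.  One printed row ("Liquifying metal",
RAL 3, band 2, EV printed as 3) is inconsistent with EV = D x RAL + V,
which gives 6; it is flagged ``eq1_inconsistent`` and the recomputed value
is used wherever arithmetic consistency matters.

The raw 18-worker observation records behind the published tables are not
public.  ``fixture_observations`` therefore returns SYNTHETIC posture
rows, constructed from the qualitative per-task hazard descriptions so
that RULA scoring reproduces each task's printed action level.  They are
illustrative stand-ins, not the study's data: per-task spread across
workers is zero by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd

from .exposure import exposure_classification, exposure_value
from .io import ObservationTable, read_observations
from .types import ExposureClass

__all__ = [
    "PaperTaskFixture",
    "paper_fixture",
    "fixture_observations",
    "expected_paper_results",
]

_DATA = resources.files("ergorula.data")


@dataclass(frozen=True)
class PaperTaskFixture:
    """One task row of the published ergonomic-assessment table."""

    task_id: str
    name: str
    ral: int
    duration_band: int
    vibration: int
    printed_ev: int
    printed_ec: ExposureClass
    eq1_inconsistent: bool
    hazard_note: str


@lru_cache(maxsize=None)
def paper_fixture() -> tuple[PaperTaskFixture, ...]:
    """The nine cookware tasks with their published assessment values."""
    payload = json.loads(_DATA.joinpath("paper_tasks.json").read_text(encoding="utf-8"))
    return tuple(
        PaperTaskFixture(
            task_id=entry["task_id"],
            name=entry["name"],
            ral=entry["ral"],
            duration_band=entry["duration_band"],
            vibration=entry["vibration"],
            printed_ev=entry["printed_ev"],
            printed_ec=ExposureClass(entry["printed_ec"]),
            eq1_inconsistent=entry["eq1_inconsistent"],
            hazard_note=entry["hazard_note"],
        )
        for entry in payload["tasks"]
    )


def fixture_observations() -> ObservationTable:
    """Synthetic 18-worker x 9-task observation table (see module note)."""
    with resources.as_file(_DATA.joinpath("paper_observations.csv")) as path:
        return read_observations(path, fmt="csv")


def expected_paper_results() -> pd.DataFrame:
    """Regression table: printed vs. recomputed exposure value per task.

    For the eight arithmetically consistent tasks the two agree; the
    flagged row carries both so the discrepancy is explicit rather than
    silently reproduced.
    """
    rows = []
    for entry in paper_fixture():
        ev = exposure_value(entry.ral, entry.duration_band, entry.vibration)
        rows.append(
            {
                "task_id": entry.task_id,
                "name": entry.name,
                "ral": entry.ral,
                "duration_band": entry.duration_band,
                "vibration": entry.vibration,
                "printed_ev": entry.printed_ev,
                "expected_ev": ev,
                "printed_ec": entry.printed_ec.value,
                "expected_ec": exposure_classification(ev).value,
                "eq1_inconsistent": entry.eq1_inconsistent,
            }
        )
    return pd.DataFrame(rows)
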