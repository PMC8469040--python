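"""Readers/writers for observation tables and assessment reports, plus the
end-to-end assessment pipeline.

Observation tables use a fixed published column schema (see
``CSV_COLUMNS``); CSV files are comma-separated UTF-8 with a header row,
"." as decimal separator and booleans serialized as 0/1, so that
write -> read -> write round-trips are byte-identical.  JSON files carry
the same records under a ``rows`` key.

``run_assessment`` runs the whole method: read -> consolidate observer
sessions per worker-task -> RULA score -> average action level per task ->
duration band -> exposure value -> exposure classification -> priority
matrix per worker -> report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
import yaml
from pydantic import ValidationError

from . import exposure, priority, rula
from .types import (
    DescriptiveStats,
    DomainError,
    ECGroup,
    ExposureClass,
    PostureObservation,
    PriorityAction,
    SchemaError,
    TaskExposure,
    WorkerProfile,
    WorkerPriority,
)

logger = logging.getLogger("ergorula")

SCHEMA_VERSION = "1"

#: Published observation-table schema: CSV column -> PostureObservation field.
COLUMN_TO_FIELD: dict[str, str] = {
    "worker_id": "worker_id",
    "task_id": "task_id",
    "observer_id": "observer_id",
    "upper_arm_deg": "upper_arm_flexion",
    "shoulder_raised": "shoulder_raised",
    "upper_arm_abducted": "upper_arm_abducted",
    "arm_supported": "arm_supported_or_leaning",
    "lower_arm_deg": "lower_arm_flexion",
    "arm_across_midline": "arm_across_midline_or_out",
    "wrist_deg": "wrist_flexion",
    "wrist_deviated": "wrist_deviated",
    "wrist_twist_endrange": "wrist_twist_end_range",
    "neck_deg": "neck_flexion",
    "neck_extension": "neck_in_extension",
    "neck_twisted": "neck_twisted",
    "neck_side_bent": "neck_side_bent",
    "trunk_deg": "trunk_flexion",
    "trunk_twisted": "trunk_twisted",
    "trunk_side_bent": "trunk_side_bent",
    "legs_supported": "legs_and_feet_supported",
    "static_over_1min": "posture_static_over_1min",
    "reps_per_min": "repetitions_per_min",
    "load_kg": "load_kg",
    "load_static_or_repeated": "load_static_or_repeated",
    "shock_force": "shock_or_rapid_force",
    "task_hours": "task_hours",
    "vibration": "vibration_present",
}

CSV_COLUMNS: list[str] = list(COLUMN_TO_FIELD)
_FIELD_TO_COLUMN = {v: k for k, v in COLUMN_TO_FIELD.items()}

_STRING_COLUMNS = {"worker_id", "task_id", "observer_id"}
_FLOAT_COLUMNS = {
    "upper_arm_deg",
    "lower_arm_deg",
    "wrist_deg",
    "neck_deg",
    "trunk_deg",
    "reps_per_min",
    "load_kg",
    "task_hours",
}
_BOOL_COLUMNS = set(CSV_COLUMNS) - _STRING_COLUMNS - _FLOAT_COLUMNS


@dataclass(frozen=True)
class Provenance:
    """Where an observation table came from."""

    source: str
    format: str
    schema_version: str = SCHEMA_VERSION


@dataclass(frozen=True)
class ObservationTable:
    """A validated list of posture observations plus their provenance."""

    rows: list[PostureObservation]
    provenance: Provenance

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        """The table as a DataFrame in published column order."""
        records = [_row_to_record(obs) for obs in self.rows]
        return pd.DataFrame.from_records(records, columns=CSV_COLUMNS)


def _row_to_record(obs: PostureObservation) -> dict[str, Any]:
    record: dict[str, Any] = {}
    for column, fname in COLUMN_TO_FIELD.items():
        value = getattr(obs, fname)
        if column in _BOOL_COLUMNS:
            record[column] = int(value)
        else:
            record[column] = value
    return record


def _fmt(value: Any) -> str:
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def _parse_bool(raw: str) -> bool:
    if raw in ("0", "1"):
        return raw == "1"
    raise ValueError(f"expected 0 or 1, got {raw!r}")


def _record_to_observation(record: dict[str, Any], index: int) -> PostureObservation:
    kwargs: dict[str, Any] = {}
    for column, fname in COLUMN_TO_FIELD.items():
        raw = record[column]
        try:
            if column in _STRING_COLUMNS:
                kwargs[fname] = str(raw)
            elif column in _FLOAT_COLUMNS:
                kwargs[fname] = float(raw)
            else:
                kwargs[fname] = _parse_bool(str(raw)) if isinstance(raw, str) else bool(raw)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"row {index}: column {column!r}: {exc}") from exc
    try:
        return PostureObservation(**kwargs)
    except ValidationError as exc:
        raise SchemaError(f"row {index}: {exc}") from exc


def _check_columns(found: Iterable[str]) -> None:
    found_set = set(found)
    missing = [c for c in CSV_COLUMNS if c not in found_set]
    unknown = sorted(found_set - set(CSV_COLUMNS))
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if unknown:
        raise SchemaError(f"unknown column(s): {', '.join(unknown)}")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "csv"
    if fmt not in ("csv", "json"):
        raise SchemaError(f"unrecognized observation format {fmt!r}")
    return fmt


def read_observations(path: str | Path, fmt: str | None = None) -> ObservationTable:
    """Read and validate an observation table from CSV or JSON.

    Every row must parse against the published schema; a failing row
    raises a :class:`SchemaError` naming its (0-based) index and is also
    logged, so no row is ever silently coerced or dropped.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        _check_columns(frame.columns)
        records = frame.to_dict(orient="records")
    else:
        payload = json.loads(path.read_text(encoding="utf-8"))
        records = payload["rows"] if isinstance(payload, dict) else payload
        for record in records:
            _check_columns(record.keys())
    rows: list[PostureObservation] = []
    errors: list[str] = []
    for index, record in enumerate(records):
        try:
            rows.append(_record_to_observation(record, index))
        except SchemaError as exc:
            logger.error("rejected %s: %s", path, exc)
            errors.append(str(exc))
    if errors:
        raise SchemaError("; ".join(errors))
    return ObservationTable(rows=rows, provenance=Provenance(str(path), fmt))


def write_observations(
    table: ObservationTable, path: str | Path, fmt: str | None = None
) -> Path:
    """Write an observation table to CSV or JSON in the published schema."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        lines = [",".join(CSV_COLUMNS)]
        for obs in table.rows:
            record = _row_to_record(obs)
            lines.append(",".join(_fmt(record[c]) for c in CSV_COLUMNS))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "rows": [_row_to_record(obs) for obs in table.rows],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# Assessment report
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AssessmentReport:
    """Per-task exposures, per-task action-level statistics, per-worker
    priorities and any warnings raised along the way."""

    per_task: list[TaskExposure]
    per_task_stats: dict[str, DescriptiveStats]
    per_worker: list[WorkerPriority]
    warnings: list[str] = field(default_factory=list)


_REPORT_COLUMNS = [
    "section",
    "task_id",
    "worker_id",
    "average_ral",
    "duration_band",
    "vibration",
    "exposure_value",
    "exposure_classification",
    "in_gap_bin",
    "mean",
    "sd",
    "median",
    "minimum",
    "maximum",
    "n",
    "ec_group",
    "total_daily_hours",
    "action",
    "message",
]

#: Markdown headers mirror the published assessment-table layout.
_MD_TASK_HEADERS = [
    "Task",
    "Average RULA Action Level",
    "Duration Per Task",
    "Vibration",
    "Exposure Value",
    "Exposure Classification",
]


def _report_rows(report: AssessmentReport) -> list[dict[str, str]]:
    rows: list[dict[str, str]] = []
    for t in report.per_task:
        rows.append(
            {
                "section": "task",
                "task_id": t.task_id,
                "average_ral": str(t.ral),
                "duration_band": str(t.duration_band),
                "vibration": str(t.vibration),
                "exposure_value": str(t.exposure_value),
                "exposure_classification": t.classification.value,
                "in_gap_bin": str(int(t.in_gap_bin)),
            }
        )
    for task_id, s in report.per_task_stats.items():
        rows.append(
            {
                "section": "stats",
                "task_id": task_id,
                "mean": _fmt(s.mean),
                "sd": _fmt(s.sd),
                "median": _fmt(s.median),
                "minimum": str(s.minimum),
                "maximum": str(s.maximum),
                "n": str(s.n),
            }
        )
    for w in report.per_worker:
        rows.append(
            {
                "section": "worker",
                "worker_id": w.worker_id,
                "ec_group": w.ec_group.value,
                "total_daily_hours": _fmt(w.total_daily_hours),
                "action": w.action.value,
            }
        )
    for message in report.warnings:
        rows.append({"section": "warning", "message": message})
    return [{c: row.get(c, "") for c in _REPORT_COLUMNS} for row in rows]


def write_report(
    report: AssessmentReport, path: str | Path, fmt: str = "csv"
) -> Path:
    """Write an assessment report as CSV, JSON or a markdown table set.

    Column order is fixed and numbers are rendered locale-independently,
    so repeated writes of equal reports are byte-identical.
    """
    path = Path(path)
    if fmt == "csv":
        lines = [",".join(_REPORT_COLUMNS)]
        for row in _report_rows(report):
            lines.append(",".join(row[c] for c in _REPORT_COLUMNS))
        text = "\n".join(lines) + "\n"
    elif fmt == "json":
        payload = {
            "per_task": [
                {
                    "task_id": t.task_id,
                    "average_ral": t.ral,
                    "duration_band": t.duration_band,
                    "vibration": t.vibration,
                    "exposure_value": t.exposure_value,
                    "exposure_classification": t.classification.value,
                    "in_gap_bin": t.in_gap_bin,
                }
                for t in report.per_task
            ],
            "per_task_stats": {
                task_id: {
                    "mean": s.mean,
                    "sd": s.sd,
                    "median": s.median,
                    "minimum": s.minimum,
                    "maximum": s.maximum,
                    "n": s.n,
                    "single_observation": s.single_observation,
                }
                for task_id, s in report.per_task_stats.items()
            },
            "per_worker": [
                {
                    "worker_id": w.worker_id,
                    "ec_group": w.ec_group.value,
                    "total_daily_hours": w.total_daily_hours,
                    "action": w.action.value,
                }
                for w in report.per_worker
            ],
            "warnings": list(report.warnings),
        }
        text = json.dumps(payload, indent=1) + "\n"
    elif fmt == "markdown":
        text = render_markdown(report)
    else:
        raise DomainError(f"unrecognized report format {fmt!r}")
    try:
        path.write_text(text, encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    return path


def read_report(path: str | Path, fmt: str | None = None) -> AssessmentReport:
    """Read back a CSV or JSON assessment report written by ``write_report``."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        per_task, stats, workers, warnings = [], {}, [], []
        for _, row in frame.iterrows():
            if row["section"] == "task":
                per_task.append(
                    TaskExposure(
                        task_id=row["task_id"],
                        ral=int(row["average_ral"]),
                        duration_band=int(row["duration_band"]),
                        vibration=int(row["vibration"]),
                        exposure_value=int(row["exposure_value"]),
                        classification=ExposureClass(row["exposure_classification"]),
                        in_gap_bin=row["in_gap_bin"] == "1",
                    )
                )
            elif row["section"] == "stats":
                stats[row["task_id"]] = DescriptiveStats(
                    mean=float(row["mean"]),
                    sd=float(row["sd"]),
                    median=float(row["median"]),
                    minimum=int(row["minimum"]),
                    maximum=int(row["maximum"]),
                    n=int(row["n"]),
                    single_observation=int(row["n"]) == 1,
                )
            elif row["section"] == "worker":
                workers.append(
                    WorkerPriority(
                        worker_id=row["worker_id"],
                        ec_group=ECGroup(row["ec_group"]),
                        total_daily_hours=float(row["total_daily_hours"]),
                        action=PriorityAction(row["action"]),
                    )
                )
            else:
                warnings.append(row["message"])
        return AssessmentReport(per_task, stats, workers, warnings)
    payload = json.loads(path.read_text(encoding="utf-8"))
    per_task = [
        TaskExposure(
            task_id=t["task_id"],
            ral=t["average_ral"],
            duration_band=t["duration_band"],
            vibration=t["vibration"],
            exposure_value=t["exposure_value"],
            classification=ExposureClass(t["exposure_classification"]),
            in_gap_bin=t["in_gap_bin"],
        )
        for t in payload["per_task"]
    ]
    stats = {
        task_id: DescriptiveStats(**s) for task_id, s in payload["per_task_stats"].items()
    }
    workers = [
        WorkerPriority(
            worker_id=w["worker_id"],
            ec_group=ECGroup(w["ec_group"]),
            total_daily_hours=w["total_daily_hours"],
            action=PriorityAction(w["action"]),
        )
        for w in payload["per_worker"]
    ]
    return AssessmentReport(per_task, stats, workers, list(payload["warnings"]))


def render_markdown(report: AssessmentReport) -> str:
    """Render the report as markdown tables in the published layout."""
    lines = ["## Ergonomic assessment", ""]
    lines.append("| " + " | ".join(_MD_TASK_HEADERS) + " |")
    lines.append("|" + "---|" * len(_MD_TASK_HEADERS))
    for t in report.per_task:
        label = t.classification.value.replace("_", " ").capitalize()
        flag = " *" if t.in_gap_bin else ""
        lines.append(
            f"| {t.task_id} | {t.ral} | {t.duration_band} | {t.vibration} "
            f"| {t.exposure_value} | {label}{flag} |"
        )
    lines += ["", "## RULA action levels for each task", ""]
    lines.append("| Task | Mean (SD) | Median | Minimum | Maximum |")
    lines.append("|---|---|---|---|---|")
    for task_id, s in report.per_task_stats.items():
        mean_sd = f"{s.mean:.1f} ({s.sd:.1f})"
        lines.append(
            f"| {task_id} | {mean_sd} | {_fmt(s.median)} | {s.minimum} | {s.maximum} |"
        )
    lines += ["", "## Worker priorities", ""]
    lines.append("| Worker | Exposure group | Total daily hours | Action |")
    lines.append("|---|---|---|---|")
    for w in report.per_worker:
        lines.append(
            f"| {w.worker_id} | {w.ec_group.value} | {_fmt(w.total_daily_hours)} "
            f"| {w.action.value.replace('_', ' ')} |"
        )
    if report.warnings:
        lines += ["", "## Warnings", ""]
        lines += [f"- {message}" for message in report.warnings]
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AssessmentConfig:
    """Configuration for one end-to-end assessment run.

    ``input=None`` uses the packaged nine-task cookware fixture.  ``seed``
    is threaded to any simulation input for reproducibility; the pipeline
    itself is deterministic.
    """

    input: str | Path | None = None
    output: str | Path | None = None
    report_format: str = "csv"
    hours_rule: str = "total"
    seed: int | None = None


def load_config(path: str | Path) -> AssessmentConfig:
    """Load an :class:`AssessmentConfig` from a YAML or JSON file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise SchemaError(f"config {path}: expected a mapping")
    known = {f for f in AssessmentConfig.__dataclass_fields__}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise SchemaError(f"config {path}: unknown key(s): {', '.join(unknown)}")
    return AssessmentConfig(**raw)


def run_assessment(
    config: AssessmentConfig | None = None, table: ObservationTable | None = None
) -> AssessmentReport:
    """Run the full extended-RULA assessment.

    Observer sessions of the same worker-task are consolidated, each
    worker-task gets a RULA breakdown, per-task action levels are averaged
    into a RAL, task duration (mean hours across workers) is banded,
    vibration is coded at task level (1 if any observation of the task
    reports it), the exposure value and classification are derived, and
    every worker is placed in the action priority matrix.
    """
    config = config or AssessmentConfig()
    if table is None:
        if config.input is None:
            from .fixtures import fixture_observations

            table = fixture_observations()
        else:
            table = read_observations(config.input)
    if not table.rows:
        raise SchemaError("no observations")

    warnings: list[str] = []

    # consolidate observer sessions per worker-task (input order preserved)
    by_worker_task: dict[tuple[str, str], list] = {}
    task_order: list[str] = []
    for obs in table.rows:
        key = (obs.worker_id, obs.task_id)
        by_worker_task.setdefault(key, []).append(obs)
        if obs.task_id not in task_order:
            task_order.append(obs.task_id)
    breakdowns = {
        key: rula.consolidate([rula.score_task(o) for o in group])
        for key, group in by_worker_task.items()
    }
    hours = {
        key: group[0].task_hours for key, group in by_worker_task.items()
    }

    per_task: list[TaskExposure] = []
    per_task_stats: dict[str, DescriptiveStats] = {}
    for task_id in task_order:
        keys = [k for k in breakdowns if k[1] == task_id]
        levels = [breakdowns[k].action_level for k in keys]
        ral = exposure.average_ral(levels)
        stats = exposure.task_stats(levels)
        mean_hours = float(sum(hours[k] for k in keys) / len(keys))
        band = exposure.duration_band(mean_hours)
        vibration = int(
            any(o.vibration_present for k in keys for o in by_worker_task[k])
        )
        task_exposure = exposure.classify_task(task_id, ral, band, vibration)
        if task_exposure.in_gap_bin:
            warnings.append(
                f"task {task_id}: exposure value {task_exposure.exposure_value} "
                "falls in a gap of the printed classification bins"
            )
        if stats.single_observation:
            warnings.append(f"task {task_id}: single observation; SD undefined")
        per_task.append(task_exposure)
        per_task_stats[task_id] = stats

    exposures_by_task = {t.task_id: t for t in per_task}
    per_worker: list[WorkerPriority] = []
    worker_order: list[str] = []
    for worker_id, task_id in breakdowns:
        if worker_id not in worker_order:
            worker_order.append(worker_id)
    for worker_id in worker_order:
        worker_tasks = [t for (w, t) in breakdowns if w == worker_id]
        profile = WorkerProfile(
            worker_id=worker_id,
            task_exposures=[exposures_by_task[t] for t in worker_tasks],
            task_hours={t: hours[(worker_id, t)] for t in worker_tasks},
        )
        per_worker.append(priority.assess_worker(profile, config.hours_rule))
    if not per_worker:
        warnings.append("no workers assessed")

    report = AssessmentReport(per_task, per_task_stats, per_worker, warnings)
    if config.output is not None:
        write_report(report, config.output, config.report_format)
    return report
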