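"""Reading, writing and screening of CPX cohorts.

A cohort is a list of :class:`CPXRecord`, one per graded exercise test
(cardiopulmonary exercise test, CPX).  On disk a cohort is a long-format
UTF-8 CSV: one row per stage, participant metadata repeated on every row,
missing values as empty fields (never 0).  Columns::

    participant_id, test_date, age, sex, ergometry, height_cm, weight_kg,
    vo2max, resting_bla, stage_index, load, bla, rpe

``load`` is watts on the bicycle and km/h on the treadmill; ``bla`` is
capillary blood lactate in mmol/l; ``rpe`` is the Borg 6-20 rating.

Screening applies six exclusion criteria in a fixed first-match order:
(A) re-tests — only the earliest test per participant is analysed,
(B) missing blood lactate, (C) missing RPE, (D) fewer than three stages,
(E) ergometry other than bicycle/treadmill, (F) implausible data.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace

from .errors import DomainError, SchemaError

__all__ = [
    "StageMeasurement",
    "CPXRecord",
    "ExclusionReport",
    "ImplausibilityRules",
    "read_cohort",
    "write_cohort",
    "apply_exclusions",
    "bmi_class",
    "COHORT_COLUMNS",
    "EXCLUSION_CRITERIA",
]

COHORT_COLUMNS = (
    "participant_id",
    "test_date",
    "age",
    "sex",
    "ergometry",
    "height_cm",
    "weight_kg",
    "vo2max",
    "resting_bla",
    "stage_index",
    "load",
    "bla",
    "rpe",
)

EXCLUSION_CRITERIA = (
    "A_retest",
    "B_missing_bla",
    "C_missing_rpe",
    "D_lt3_stages",
    "E_other_ergometry",
    "F_implausible",
)


@dataclass(frozen=True)
class StageMeasurement:
    """One completed stage: load, end-of-stage lactate and RPE."""

    stage_index: int
    load: float
    duration_min: float = 3.0
    bla: float | None = None
    rpe: int | None = None


@dataclass
class CPXRecord:
    """One participant's graded exercise test with metadata and stages."""

    participant_id: str
    test_date: dt.date
    age: float
    sex: str
    ergometry: str
    height_cm: float
    weight_kg: float
    vo2max: float
    resting_bla: float | None
    stages: list[StageMeasurement] = field(default_factory=list)

    @property
    def n_stages(self) -> int:
        return len(self.stages)


@dataclass
class ExclusionReport:
    """Accounting of the screening step; conserves records by construction."""

    n_input: int
    n_kept: int
    counts: dict[str, int]

    def check(self) -> None:
        if self.n_input != self.n_kept + sum(self.counts.values()):
            raise AssertionError(
                "exclusion accounting does not conserve records: "
                f"{self.n_input} != {self.n_kept} + {self.counts}"
            )


@dataclass(frozen=True)
class ImplausibilityRules:
    """Concrete, configurable reading of criterion F ("implausible data").

    Defaults reject only physiologically impossible values: lactate above
    25 mmol/l or non-positive, RPE outside the Borg 6-20 range, a load
    sequence that does not strictly increase, and non-positive
    anthropometrics.
    """

    max_bla: float = 25.0
    min_rpe: int = 6
    max_rpe: int = 20
    require_increasing_load: bool = True

    def violated(self, rec: CPXRecord) -> str | None:
        if rec.age <= 0 or rec.height_cm <= 0 or rec.weight_kg <= 0:
            return "non-positive age/height/weight"
        prev_load = None
        for st in rec.stages:
            if st.bla is not None and not (0.0 < st.bla <= self.max_bla):
                return f"bla {st.bla} outside (0, {self.max_bla}]"
            if st.rpe is not None and not (self.min_rpe <= st.rpe <= self.max_rpe):
                return f"rpe {st.rpe} outside [{self.min_rpe}, {self.max_rpe}]"
            if self.require_increasing_load and prev_load is not None and st.load <= prev_load:
                return "load not strictly increasing"
            prev_load = st.load
        return None


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest round-tripping decimal
    return str(value)


def write_cohort(cohort: list[CPXRecord], path) -> None:
    """Write a cohort to the long-format CSV; inverse of :func:`read_cohort`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for rec in cohort:
            for st in rec.stages:
                writer.writerow(
                    [
                        rec.participant_id,
                        rec.test_date.isoformat(),
                        _fmt(rec.age),
                        rec.sex,
                        rec.ergometry,
                        _fmt(rec.height_cm),
                        _fmt(rec.weight_kg),
                        _fmt(rec.vo2max),
                        _fmt(rec.resting_bla),
                        st.stage_index,
                        _fmt(st.load),
                        _fmt(st.bla),
                        _fmt(st.rpe),
                    ]
                )


def _parse_float(raw: str, column: str, line: int, errors: list[str], *, optional=False):
    if raw == "":
        if optional:
            return None
        errors.append(f"line {line}: missing value for '{column}'")
        return None
    try:
        return float(raw)
    except ValueError:
        errors.append(f"line {line}: unparseable number '{raw}' in '{column}'")
        return None


def _parse_int(raw: str, column: str, line: int, errors: list[str], *, optional=False):
    if raw == "":
        if optional:
            return None
        errors.append(f"line {line}: missing value for '{column}'")
        return None
    try:
        return int(raw)
    except ValueError:
        try:
            f = float(raw)
        except ValueError:
            errors.append(f"line {line}: unparseable integer '{raw}' in '{column}'")
            return None
        if f != int(f):
            errors.append(f"line {line}: non-integer '{raw}' in '{column}'")
            return None
        return int(f)


def read_cohort(path) -> list[CPXRecord]:
    """Read a long-format cohort CSV into records.

    Rows are grouped by (participant_id, test_date) in order of first
    appearance and stages are sorted by stage_index.  All malformed rows
    are collected and reported together in a :class:`SchemaError` with
    line numbers.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration as exc:
            raise SchemaError(f"{path}: empty file, header row required") from exc
        missing = [c for c in COHORT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
        idx = {c: header.index(c) for c in COHORT_COLUMNS}

        errors: list[str] = []
        groups: dict[tuple[str, dt.date], CPXRecord] = {}
        for line, row in enumerate(reader, start=2):
            if not row or all(cell == "" for cell in row):
                continue
            if len(row) < len(header):
                errors.append(f"line {line}: expected {len(header)} fields, got {len(row)}")
                continue
            pid = row[idx["participant_id"]]
            try:
                date = dt.date.fromisoformat(row[idx["test_date"]])
            except ValueError:
                errors.append(f"line {line}: unparseable date '{row[idx['test_date']]}'")
                continue
            age = _parse_float(row[idx["age"]], "age", line, errors)
            height = _parse_float(row[idx["height_cm"]], "height_cm", line, errors)
            weight = _parse_float(row[idx["weight_kg"]], "weight_kg", line, errors)
            vo2max = _parse_float(row[idx["vo2max"]], "vo2max", line, errors)
            resting = _parse_float(row[idx["resting_bla"]], "resting_bla", line, errors, optional=True)
            stage_index = _parse_int(row[idx["stage_index"]], "stage_index", line, errors)
            load = _parse_float(row[idx["load"]], "load", line, errors)
            bla = _parse_float(row[idx["bla"]], "bla", line, errors, optional=True)
            rpe = _parse_int(row[idx["rpe"]], "rpe", line, errors, optional=True)
            if None in (age, height, weight, vo2max, stage_index, load):
                continue
            key = (pid, date)
            if key not in groups:
                groups[key] = CPXRecord(
                    participant_id=pid,
                    test_date=date,
                    age=age,
                    sex=row[idx["sex"]],
                    ergometry=row[idx["ergometry"]],
                    height_cm=height,
                    weight_kg=weight,
                    vo2max=vo2max,
                    resting_bla=resting,
                    stages=[],
                )
            groups[key].stages.append(
                StageMeasurement(stage_index=stage_index, load=load, bla=bla, rpe=rpe)
            )
        if errors:
            raise SchemaError(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))

    records = list(groups.values())
    for rec in records:
        rec.stages.sort(key=lambda st: st.stage_index)
    return records


def apply_exclusions(
    cohort: list[CPXRecord], rules: ImplausibilityRules | None = None
) -> tuple[list[CPXRecord], ExclusionReport]:
    """Screen a cohort with criteria A-F in fixed first-match order.

    Returns the kept records (input order preserved) and an
    :class:`ExclusionReport` whose per-criterion counts add up to the
    input size.  Idempotent: re-screening the kept records excludes
    nothing.
    """
    rules = rules or ImplausibilityRules()
    counts = dict.fromkeys(EXCLUSION_CRITERIA, 0)

    # criterion A: keep only the earliest test per participant (ties: first seen)
    earliest: dict[str, int] = {}
    for i, rec in enumerate(cohort):
        j = earliest.get(rec.participant_id)
        if j is None or rec.test_date < cohort[j].test_date:
            earliest[rec.participant_id] = i

    kept: list[CPXRecord] = []
    for i, rec in enumerate(cohort):
        if earliest[rec.participant_id] != i:
            counts["A_retest"] += 1
        elif any(st.bla is None for st in rec.stages):
            counts["B_missing_bla"] += 1
        elif any(st.rpe is None for st in rec.stages):
            counts["C_missing_rpe"] += 1
        elif len(rec.stages) < 3:
            counts["D_lt3_stages"] += 1
        elif rec.ergometry not in ("bicycle", "treadmill"):
            counts["E_other_ergometry"] += 1
        elif rules.violated(rec) is not None:
            counts["F_implausible"] += 1
        else:
            kept.append(rec)

    report = ExclusionReport(n_input=len(cohort), n_kept=len(kept), counts=counts)
    report.check()
    return kept, report


# WHO bands, half-open at the lower edge: [18.5, 25) is "normal" etc.
_BMI_BANDS = (
    (18.5, "underweight"),
    (25.0, "normal"),
    (30.0, "pre-obese"),
    (35.0, "obesity class I"),
    (40.0, "obesity class II"),
)


def bmi_class(weight_kg: float, height_cm: float) -> str:
    """WHO BMI class for a weight (kg) and height (cm)."""
    if weight_kg <= 0 or height_cm <= 0:
        raise DomainError("weight_kg and height_cm must be positive")
    bmi = weight_kg / (height_cm / 100.0) ** 2
    for upper, label in _BMI_BANDS:
        if bmi < upper:
            return label
    return "obesity class III"


def clone_record(rec: CPXRecord, **changes) -> CPXRecord:
    """Copy a record with field overrides (stages list is shallow-copied)."""
    out = replace(rec, **changes)
    if "stages" not in changes:
        out.stages = list(rec.stages)
    return out
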