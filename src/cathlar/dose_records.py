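"""Per-procedure dose-log data model, CSV/XLSX I/O, descriptive statistics,
and annual-dose estimation.

A dose log holds one record per catheterization procedure.  Each record
carries the machine technique factors (fluoroscopy and cine-acquisition
tube settings and durations), the dose-area product (DAP, Gy·cm²), and the
electronic-personal-dosimeter (EPD) reading of every staff member present,
measured as the personal dose equivalent Hp(10) at the thyroid collar in
μSv.  μSv is the canonical internal dose unit throughout the package;
conversion to mSv happens only at module boundaries (annualization and the
risk engine).

On disk a log is a ``doselog-v1`` CSV: one row per (procedure × operator),
procedure-level fields repeated on each row.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ProcedureType",
    "Role",
    "Sex",
    "OperatorDose",
    "ProcedureRecord",
    "DoseSummary",
    "DoseLogError",
    "SchemaError",
    "ValidationError",
    "DOSELOG_V1_COLUMNS",
    "read_dose_log",
    "read_dose_log_xlsx",
    "write_dose_log",
    "summarize",
    "annualize",
]


class ProcedureType(str, enum.Enum):
    """Catheterization procedure categories."""

    CA_PCI = "CA_PCI"  # coronary angiography with percutaneous intervention
    CA = "CA"  # diagnostic coronary angiography only
    OTHERS = "OTHERS"  # ablation, pacemaker / defibrillator implantation


class Role(str, enum.Enum):
    PRIMARY = "PRIMARY"
    ASSISTANT = "ASSISTANT"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class DoseLogError(Exception):
    """Base error for dose-log parsing and validation."""


class SchemaError(DoseLogError):
    """The file header does not match the documented schema."""


class ValidationError(DoseLogError):
    """A field value violates a record invariant."""


# doselog-v1 mandatory columns, in canonical order.  `beam_directions` is an
# optional trailing column (semicolon-joined ``label:mode`` tokens) written by
# this package so that write/read round-trips preserve every field; strict
# doselog-v1 readers may ignore it.
DOSELOG_V1_COLUMNS = [
    "procedure_id",
    "procedure_type",
    "fluoro_time_min",
    "fluoro_kv",
    "fluoro_ma",
    "acq_kv",
    "acq_ma",
    "acq_time_s",
    "dap_gycm2",
    "operator_id",
    "role",
    "age",
    "sex",
    "epd_dose_usv",
]

_BEAM_COLUMN = "beam_directions"
_BEAM_MODES = ("fluoroscopy", "acquisition")


@dataclass
class OperatorDose:
    """One staff member's EPD reading for one procedure.

    ``epd_dose_usv`` is Hp(10) in μSv measured over the thyroid collar.
    """

    operator_id: str
    role: Role
    age: float
    sex: Sex
    epd_dose_usv: float

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        self.sex = Sex(self.sex)
        if not (18 <= self.age <= 80):
            raise ValidationError(
                f"operator {self.operator_id!r}: age {self.age} outside [18, 80]"
            )
        if self.epd_dose_usv < 0:
            raise ValidationError(
                f"operator {self.operator_id!r}: negative EPD dose {self.epd_dose_usv}"
            )


@dataclass
class ProcedureRecord:
    """One catheterization procedure with technique factors and staff doses."""

    procedure_id: str
    procedure_type: ProcedureType
    fluoro_time_min: float
    fluoro_kv: float
    fluoro_ma: float
    acq_kv: float
    acq_ma: float
    acq_time_s: float
    dap_gycm2: float
    beam_directions: list[tuple[str, str]] = field(default_factory=list)
    operator_doses: list[OperatorDose] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.procedure_type = ProcedureType(self.procedure_type)
        pid = self.procedure_id
        if self.fluoro_time_min < 0 or self.acq_time_s < 0:
            raise ValidationError(f"procedure {pid!r}: negative exposure time")
        for name in ("fluoro_kv", "fluoro_ma", "acq_kv", "acq_ma"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"procedure {pid!r}: {name} must be > 0")
        if self.dap_gycm2 < 0:
            raise ValidationError(f"procedure {pid!r}: negative DAP {self.dap_gycm2}")
        if self.dap_gycm2 == 0 and not (
            self.procedure_type is ProcedureType.OTHERS and self.acq_time_s == 0
        ):
            raise ValidationError(
                f"procedure {pid!r}: zero DAP is only valid for OTHERS "
                "procedures without cine runs"
            )
        for label, mode in self.beam_directions:
            if mode not in _BEAM_MODES:
                raise ValidationError(
                    f"procedure {pid!r}: beam mode {mode!r} not in {_BEAM_MODES}"
                )

    def doses_for(self, role: Role) -> list[OperatorDose]:
        role = Role(role)
        return [od for od in self.operator_doses if od.role is role]


@dataclass
class DoseSummary:
    """Descriptive statistics of a dose log.

    ``dose_stats`` — per (procedure_type × role): n, mean and sample SD
    (n−1 denominator) of the EPD dose in μSv; SD is NaN (reported absent)
    when n = 1.
    ``procedure_stats`` — per procedure_type: n plus mean/SD of each
    technique factor and of DAP.
    """

    dose_stats: pd.DataFrame
    procedure_stats: pd.DataFrame

    @property
    def n_procedures(self) -> int:
        return int(self.procedure_stats["n"].sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FLOAT_FIELDS = {
    "fluoro_time_min",
    "fluoro_kv",
    "fluoro_ma",
    "acq_kv",
    "acq_ma",
    "acq_time_s",
    "dap_gycm2",
    "age",
    "epd_dose_usv",
}


def _encode_beams(beams: Sequence[tuple[str, str]]) -> str:
    return ";".join(f"{label}:{mode}" for label, mode in beams)


def _decode_beams(text: str) -> list[tuple[str, str]]:
    if not text:
        return []
    out = []
    for token in text.split(";"):
        label, _, mode = token.partition(":")
        out.append((label, mode))
    return out


def _parse_row(row: dict, rownum: int) -> dict:
    parsed = {}
    for key, raw in row.items():
        if key in _FLOAT_FIELDS:
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"row {rownum}: field {key!r} is not numeric: {raw!r}"
                ) from None
            if not math.isfinite(value):
                raise ValidationError(f"row {rownum}: field {key!r} is not finite")
            parsed[key] = value
        else:
            parsed[key] = raw
    if parsed.get("epd_dose_usv", 0) < 0:
        raise ValidationError(
            f"row {rownum}: negative EPD dose {parsed['epd_dose_usv']}"
        )
    if parsed.get("dap_gycm2", 0) < 0:
        raise ValidationError(f"row {rownum}: negative DAP {parsed['dap_gycm2']}")
    return parsed


def _rows_to_records(
    rows: Iterable[tuple[int, dict]], skip_bad_rows: bool
) -> list[ProcedureRecord]:
    """Assemble (rownum, raw dict) pairs into records, grouping on procedure_id."""
    groups: dict[str, list[tuple[int, dict]]] = {}
    order: list[str] = []
    errors: list[str] = []
    for rownum, raw in rows:
        try:
            parsed = _parse_row(raw, rownum)
        except DoseLogError as exc:
            if skip_bad_rows:
                continue
            errors.append(str(exc))
            continue
        pid = parsed["procedure_id"]
        if pid not in groups:
            groups[pid] = []
            order.append(pid)
        groups[pid].append((rownum, parsed))
    if errors:
        raise ValidationError("; ".join(errors))

    records: list[ProcedureRecord] = []
    for pid in order:
        members = groups[pid]
        rownum0, first = members[0]
        try:
            operators = [
                OperatorDose(
                    operator_id=p["operator_id"],
                    role=Role(p["role"]),
                    age=p["age"],
                    sex=Sex(p["sex"]),
                    epd_dose_usv=p["epd_dose_usv"],
                )
                for _, p in members
            ]
            record = ProcedureRecord(
                procedure_id=pid,
                procedure_type=ProcedureType(first["procedure_type"]),
                fluoro_time_min=first["fluoro_time_min"],
                fluoro_kv=first["fluoro_kv"],
                fluoro_ma=first["fluoro_ma"],
                acq_kv=first["acq_kv"],
                acq_ma=first["acq_ma"],
                acq_time_s=first["acq_time_s"],
                dap_gycm2=first["dap_gycm2"],
                beam_directions=_decode_beams(first.get(_BEAM_COLUMN, "") or ""),
                operator_doses=operators,
            )
        except (DoseLogError, ValueError) as exc:
            if skip_bad_rows:
                continue
            raise ValidationError(f"row {rownum0}: {exc}") from exc
        records.append(record)
    return records


def read_dose_log(
    path: str | Path,
    dialect: str = "doselog-v1",
    skip_bad_rows: bool = False,
) -> list[ProcedureRecord]:
    """Read a ``doselog-v1`` CSV into :class:`ProcedureRecord` objects.

    Rows sharing a ``procedure_id`` are merged into one record with several
    operator doses.  By default any unparseable row fails the whole load
    (silent dropping would bias dose sums); pass ``skip_bad_rows=True`` to
    drop offending rows instead.
    """
    if dialect != "doselog-v1":
        raise SchemaError(f"unknown dose-log dialect {dialect!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        missing = [c for c in DOSELOG_V1_COLUMNS if c not in header]
        if missing:
            raise SchemaError(
                f"{path}: missing mandatory column(s): {', '.join(missing)}"
            )
        rows = [(i, row) for i, row in enumerate(reader, start=2)]
    return _rows_to_records(rows, skip_bad_rows)


def read_dose_log_xlsx(
    path: str | Path, skip_bad_rows: bool = False
) -> list[ProcedureRecord]:
    """Read a supplementary-data-shaped XLSX workbook (first sheet, doselog-v1
    columns) into records."""
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    ws = wb.worksheets[0]
    rows_iter = ws.iter_rows(values_only=True)
    header = [str(c) if c is not None else "" for c in next(rows_iter)]
    missing = [c for c in DOSELOG_V1_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    rows = []
    for i, values in enumerate(rows_iter, start=2):
        if all(v is None for v in values):
            continue
        rows.append((i, dict(zip(header, values))))
    wb.close()
    return _rows_to_records(rows, skip_bad_rows)


def write_dose_log(records: Sequence[ProcedureRecord], path: str | Path) -> None:
    """Write records as a doselog-v1 CSV (one row per procedure × operator)."""
    path = Path(path)
    columns = DOSELOG_V1_COLUMNS + [_BEAM_COLUMN]
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.DictWriter(handle, fieldnames=columns)
        writer.writeheader()
        for rec in records:
            base = {
                "procedure_id": rec.procedure_id,
                "procedure_type": rec.procedure_type.value,
                "fluoro_time_min": repr(rec.fluoro_time_min),
                "fluoro_kv": repr(rec.fluoro_kv),
                "fluoro_ma": repr(rec.fluoro_ma),
                "acq_kv": repr(rec.acq_kv),
                "acq_ma": repr(rec.acq_ma),
                "acq_time_s": repr(rec.acq_time_s),
                "dap_gycm2": repr(rec.dap_gycm2),
                _BEAM_COLUMN: _encode_beams(rec.beam_directions),
            }
            for od in rec.operator_doses:
                row = dict(base)
                row.update(
                    operator_id=od.operator_id,
                    role=od.role.value,
                    age=repr(od.age),
                    sex=od.sex.value,
                    epd_dose_usv=repr(od.epd_dose_usv),
                )
                writer.writerow(row)


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

_TECH_FIELDS = [
    "fluoro_time_min",
    "fluoro_kv",
    "fluoro_ma",
    "acq_kv",
    "acq_ma",
    "acq_time_s",
    "dap_gycm2",
]


def records_to_frame(records: Sequence[ProcedureRecord]) -> pd.DataFrame:
    """Flatten records to one row per (procedure × operator)."""
    rows = []
    for rec in records:
        base = {
            "procedure_id": rec.procedure_id,
            "procedure_type": rec.procedure_type.value,
            **{f: getattr(rec, f) for f in _TECH_FIELDS},
        }
        for od in rec.operator_doses:
            rows.append(
                {
                    **base,
                    "operator_id": od.operator_id,
                    "role": od.role.value,
                    "age": od.age,
                    "sex": od.sex.value,
                    "epd_dose_usv": od.epd_dose_usv,
                }
            )
    return pd.DataFrame(rows)


def summarize(records: Sequence[ProcedureRecord]) -> DoseSummary:
    """Means and sample standard deviations (n−1 denominator) of EPD doses per
    (procedure type × role), and of technique factors / DAP per type.

    Groups with a single observation report mean only (SD absent/NaN).
    """
    if not records:
        raise ValueError("summarize: empty record list")
    frame = records_to_frame(records)

    dose = (
        frame.groupby(["procedure_type", "role"])["epd_dose_usv"]
        .agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )

    proc = frame.drop_duplicates("procedure_id")
    agg = {"n": ("procedure_id", "count")}
    for f in _TECH_FIELDS:
        agg[f"{f}_mean"] = (f, "mean")
        agg[f"{f}_sd"] = (f, lambda x: x.std(ddof=1))
    proc_stats = proc.groupby("procedure_type").agg(**agg).reset_index()
    return DoseSummary(dose_stats=dose, procedure_stats=proc_stats)


def annualize(
    records: Sequence[ProcedureRecord],
    role: Role,
    window_months: float = 12.0,
) -> float:
    """Annual occupational dose in mSv/yr for one role.

    Sums the role's EPD doses over the observation window and rescales the
    window to 12 months: ``(Σ dose μSv) × (12 / window) / 1000``.  This is
    the annual dose fed to the risk engine.
    """
    if window_months <= 0:
        raise ValueError(f"window_months must be > 0, got {window_months}")
    role = Role(role)
    doses = [od.epd_dose_usv for rec in records for od in rec.doses_for(role)]
    if not doses:
        raise ValueError(f"no dose records for role {role.value}")
    total_usv = sum(doses)
    return total_usv * (12.0 / window_months) / 1000.0
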