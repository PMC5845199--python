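"""Patient data model, validation, and cohort CSV I/O.

A :class:`PatientRecord` carries one child's demographics, the seven
classic clinical signs of Kawasaki disease as tri-state flags
(present / absent / unknown), an admission laboratory panel in
canonical units (see :mod:`kdscore.units`), and an optional IVIG
response label (``True`` = resistant, ``False`` = responsive,
``None`` = unknown).

Missing data are first class throughout: any lab may be absent, any
sign may be unknown, and downstream scoring decides per model whether
a patient is classifiable.  This mirrors clinical reality, where
ratio-based scores routinely lose patients to incomplete differential
counts.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, TextIO, Union

import yaml

from .errors import ParseError, SchemaError, ValidationError
from .units import to_canonical

# Tri-state truth value: True / False / None (unknown)
TriState = Optional[bool]

#: Order of lab fields in the canonical CSV layout.
LAB_FIELDS = (
    "crp", "alt", "ast", "na", "alb", "plt",
    "neut_pct", "neut_count", "lymph_count", "tb",
)

#: Clinical sign fields, canonical CSV order.
SIGN_FIELDS = (
    "rash", "edema_extremities", "oral_mucosal_changes", "strawberry_tongue",
    "desquamation_fingertips", "cervical_lymphadenopathy", "conjunctival_injection",
)

#: Canonical unit of each lab field, for documentation and schema defaults.
LAB_UNITS = {
    "crp": "mg/L", "alt": "IU/L", "ast": "IU/L", "na": "mmol/L", "alb": "g/L",
    "plt": "10^9/L", "neut_pct": "%", "neut_count": "10^9/L",
    "lymph_count": "10^9/L", "tb": "umol/L",
}

_MISSING_SENTINELS = {"", "NA", "na", "NaN", "nan", "None"}


@dataclass
class LabPanel:
    """Admission laboratory values in canonical units; all optional.

    crp mg/L; alt/ast IU/L; na mmol/L; alb g/L; plt 10^9/L;
    neut_pct percent of the differential (0–100); neut_count and
    lymph_count 10^9/L; tb µmol/L.
    """

    crp: Optional[float] = None
    alt: Optional[float] = None
    ast: Optional[float] = None
    na: Optional[float] = None
    alb: Optional[float] = None
    plt: Optional[float] = None
    neut_pct: Optional[float] = None
    neut_count: Optional[float] = None
    lymph_count: Optional[float] = None
    tb: Optional[float] = None


@dataclass
class ClinicalSigns:
    """Tri-state clinical signs (True present, False absent, None unknown)."""

    rash: TriState = None
    edema_extremities: TriState = None
    oral_mucosal_changes: TriState = None
    strawberry_tongue: TriState = None
    desquamation_fingertips: TriState = None
    cervical_lymphadenopathy: TriState = None
    conjunctival_injection: TriState = None


@dataclass
class PatientRecord:
    """One patient: demographics, signs, labs, optional response label."""

    id: str
    age_months: Optional[float] = None
    sex: str = "unknown"  # male / female / unknown
    illness_day_at_treatment: Optional[int] = None
    kd_type: str = "unknown"  # complete / incomplete / unknown
    signs: ClinicalSigns = field(default_factory=ClinicalSigns)
    labs: LabPanel = field(default_factory=LabPanel)
    ivig_resistant: TriState = None


@dataclass
class Cohort:
    """Ordered collection of patients plus a provenance note."""

    patients: list[PatientRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def __getitem__(self, i):
        return self.patients[i]


@dataclass(frozen=True)
class Violation:
    """One invariant violation: which field, which rule, human message."""

    field: str
    rule: str
    message: str


def derive_ratios(labs: LabPanel) -> tuple[Optional[float], Optional[float]]:
    """Neutrophil-to-lymphocyte and platelet-to-lymphocyte ratios.

    Returns ``(nlr, plr)``; each is ``None`` whenever a needed input is
    missing or the lymphocyte count is zero.  Never raises.
    """
    lymph = labs.lymph_count
    if lymph is None or lymph <= 0:
        return None, None
    nlr = labs.neut_count / lymph if labs.neut_count is not None else None
    plr = labs.plt / lymph if labs.plt is not None else None
    return nlr, plr


def validate_patient(record: PatientRecord) -> list[Violation]:
    """Check a record against the data-model invariants.

    Returns an empty list iff all invariants hold; reports, never raises.
    """
    out: list[Violation] = []
    if record.age_months is not None and record.age_months < 0:
        out.append(Violation("age_months", "non_negative",
                             f"age_months={record.age_months} must be >= 0"))
    if record.sex not in ("male", "female", "unknown"):
        out.append(Violation("sex", "domain", f"sex={record.sex!r} not in male/female/unknown"))
    if record.kd_type not in ("complete", "incomplete", "unknown"):
        out.append(Violation("kd_type", "domain",
                             f"kd_type={record.kd_type!r} not in complete/incomplete/unknown"))
    day = record.illness_day_at_treatment
    if day is not None:
        if day < 1 or float(day) != int(day):
            out.append(Violation("illness_day_at_treatment", "positive_integer_day",
                                 f"illness day {day} must be a positive integer day count"))
    for name in LAB_FIELDS:
        v = getattr(record.labs, name)
        if v is None:
            continue
        if not math.isfinite(v) or v < 0:
            out.append(Violation(name, "non_negative",
                                 f"{name}={v} must be finite and >= 0"))
        if name == "neut_pct" and v > 100:
            out.append(Violation("neut_pct", "percent_upper_bound",
                                 f"neut_pct={v} exceeds 100"))
    return out


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Cohort-level invariants: unique ids plus per-patient checks."""
    out: list[Violation] = []
    seen: set[str] = set()
    for rec in cohort:
        if rec.id in seen:
            out.append(Violation("id", "unique", f"duplicate patient id {rec.id!r}"))
        seen.add(rec.id)
        out.extend(validate_patient(rec))
    return out


@dataclass
class CohortSchema:
    """Column mapping and unit declarations for reading cohort CSVs.

    ``column_map`` maps canonical field names to column headers in the
    file (defaults to identity for any omitted field).  ``units``
    declares the unit of each lab column; omitted labs are assumed to
    already be canonical.  Units are declared explicitly rather than
    inferred because printed tables sometimes label a column with one
    unit while the magnitudes belong to another.
    """

    column_map: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def column_for(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)

    @classmethod
    def from_yaml(cls, source: Union[str, TextIO]) -> "CohortSchema":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
        doc = doc or {}
        return cls(column_map=dict(doc.get("column_map", {})),
                   units=dict(doc.get("units", {})))


def _parse_tristate(cell: str, row_id: str, col: str) -> TriState:
    s = cell.strip()
    if s in _MISSING_SENTINELS:
        return None
    if s.lower() in ("1", "true", "yes", "present"):
        return True
    if s.lower() in ("0", "false", "no", "absent"):
        return False
    raise ParseError(f"row {row_id!r}: cannot parse tri-state cell {cell!r} in column {col!r}",
                     row_ids=[row_id])


def _parse_float(cell: str, row_id: str, col: str) -> Optional[float]:
    s = cell.strip()
    if s in _MISSING_SENTINELS:
        return None
    try:
        return float(s)
    except ValueError:
        raise ParseError(f"row {row_id!r}: non-numeric value {cell!r} in column {col!r}",
                         row_ids=[row_id]) from None


def read_cohort(source: Union[str, TextIO], schema: Optional[CohortSchema] = None) -> Cohort:
    """Read a cohort from a delimited text file or stream.

    The file must have a header row and at least the ``id``,
    ``age_months`` and ``ivig_resistant`` columns (under the names the
    schema maps them to).  Lab values are converted to canonical units
    according to the schema's unit declarations; blank and ``NA`` cells
    become missing.  The output has exactly one record per data row.

    Raises
    ------
    SchemaError
        A mapped required column is absent from the header.
    ParseError
        A cell that should be numeric is not; the error lists the row id.
    ValidationError
        Duplicate patient ids.
    """
    schema = schema or CohortSchema()
    if hasattr(source, "read"):
        provenance = "<stream>"
        reader = csv.DictReader(source)
        header = reader.fieldnames  # reads the header even with no data rows
        rows = list(reader)
    else:
        provenance = str(source)
        with open(source, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames
            rows = list(reader)
    if header is None:
        raise SchemaError("cohort file has no header row")

    required = ("id", "age_months", "ivig_resistant")
    for canonical in required:
        col = schema.column_for(canonical)
        if col not in header:
            raise SchemaError(f"required column {col!r} (for field {canonical!r}) "
                              f"missing from header")

    patients: list[PatientRecord] = []
    seen: set[str] = set()
    for row in rows:
        rid = (row.get(schema.column_for("id")) or "").strip()
        if rid in seen:
            raise ValidationError(f"duplicate patient id {rid!r}")
        seen.add(rid)

        def cell(canonical: str) -> Optional[str]:
            return row.get(schema.column_for(canonical))

        labs = LabPanel()
        for name in LAB_FIELDS:
            raw = cell(name)
            if raw is None:
                continue
            v = _parse_float(raw, rid, schema.column_for(name))
            if v is not None:
                unit = schema.units.get(name, LAB_UNITS[name])
                v = to_canonical(v, name, unit)
            setattr(labs, name, v)

        signs = ClinicalSigns()
        for name in SIGN_FIELDS:
            raw = cell(name)
            if raw is not None:
                setattr(signs, name, _parse_tristate(raw, rid, schema.column_for(name)))

        age_raw = cell("age_months")
        age = _parse_float(age_raw, rid, "age_months") if age_raw is not None else None
        day_raw = cell("illness_day_at_treatment")
        day_f = _parse_float(day_raw, rid, "illness_day_at_treatment") if day_raw is not None else None
        day = int(day_f) if day_f is not None else None

        sex_raw = (cell("sex") or "").strip().lower()
        sex = sex_raw if sex_raw in ("male", "female") else "unknown"
        kd_raw = (cell("kd_type") or "").strip().lower()
        kd_type = kd_raw if kd_raw in ("complete", "incomplete") else "unknown"

        label_raw = cell("ivig_resistant")
        label = _parse_tristate(label_raw, rid, "ivig_resistant") if label_raw is not None else None

        patients.append(PatientRecord(
            id=rid, age_months=age, sex=sex, illness_day_at_treatment=day,
            kd_type=kd_type, signs=signs, labs=labs, ivig_resistant=label,
        ))
    return Cohort(patients=patients, provenance=provenance)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float) and v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(v) if isinstance(v, float) else str(v)


#: Canonical CSV column order.
CSV_COLUMNS = (
    ("id", "age_months", "sex", "illness_day_at_treatment", "kd_type")
    + SIGN_FIELDS + LAB_FIELDS + ("ivig_resistant",)
)


def write_cohort(cohort: Cohort, target: Union[str, TextIO]) -> None:
    """Write a cohort to CSV in canonical units and column order.

    Missing values are written as empty cells; tri-states as 1/0/empty.
    ``read_cohort(write_cohort(c))`` is the identity on canonical-unit
    cohorts.
    """

    def _write(fh: TextIO) -> None:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for rec in cohort:
            row = [rec.id, _fmt(rec.age_months), rec.sex,
                   _fmt(rec.illness_day_at_treatment), rec.kd_type]
            row += [_fmt(getattr(rec.signs, s)) for s in SIGN_FIELDS]
            row += [_fmt(getattr(rec.labs, f)) for f in LAB_FIELDS]
            row.append(_fmt(rec.ivig_resistant))
            w.writerow(row)

    if hasattr(target, "write"):
        _write(target)
    else:
        with open(target, "w", encoding="utf-8", newline="") as fh:
            _write(fh)


def cohort_to_csv_string(cohort: Cohort) -> str:
    """Serialize a cohort to a CSV string (used for byte-level determinism checks)."""
    buf = io.StringIO()
    write_cohort(cohort, buf)
    return buf.getvalue()
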