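"""Domain types for the six clinical template tables and their CSV I/O.

Dialect: comma-separated, UTF-8, ISO-8601 dates where "YYYY", "YYYY-MM"
and "YYYY-MM-DD" encode reduced precision, empty string for missing.
Units are fixed per column; readers reject other units instead of
converting.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Optional

from hfscores.errors import ConfigurationError, FormatError, RowParseError

SITES = ("B", "G", "H", "HD", "WU")

SEXES = ("female", "male")
STATUSES = ("inpatient", "outpatient")
NYHA_CLASSES = ("I", "II", "III", "IV")
DRUG_GROUPS = ("beta_blocker", "acei_arb", "statin", "loop_diuretic")
SUBSTANCES = ("furosemide", "torasemide", "other")

#: LOINC code -> laboratory analyte
LOINC_ANALYTE = {
    "14682-9": "creatinine",
    "2160-0": "creatinine",
    "2951-2": "sodium",
    "718-7": "hemoglobin",
    "30350-3": "hemoglobin",
    "62238-1": "egfr",
}
ANALYTES = ("creatinine", "sodium", "hemoglobin", "egfr")

#: canonical unit per analyte; readers reject anything else
LAB_UNITS = {
    "creatinine": "µmol/L",
    "sodium": "mmol/L",
    "hemoglobin": "g/dL",
    "egfr": "mL/min/1.73",
}

_PSEUDONYM_RE = re.compile(r"^([A-Z]+)([1-9][0-9]*)$")


# ---------------------------------------------------------------------------
# value types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class DateValue:
    """Calendar date with explicit reduced precision (day, month or year)."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day given without month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # raises ValueError for impossible calendar dates
            dt.date(self.year, self.month, self.day)

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    @classmethod
    def from_date(cls, d: dt.date) -> "DateValue":
        return cls(d.year, d.month, d.day)

    @classmethod
    def parse(cls, text: str) -> "DateValue":
        """Parse "YYYY", "YYYY-MM" or "YYYY-MM-DD" keeping the precision."""
        m = re.fullmatch(r"(\d{4})(?:-(\d{2})(?:-(\d{2}))?)?", text)
        if not m:
            raise ValueError(f"not an ISO-8601 (partial) date: {text!r}")
        y, mo, d = m.groups()
        return cls(int(y), int(mo) if mo else None, int(d) if d else None)

    def isoformat(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"


@dataclass(frozen=True, order=True)
class PatientKey:
    site: str
    local_id: str
    pseudonym: Optional[str] = None

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site code: {self.site!r}")
        if self.pseudonym is not None and not _PSEUDONYM_RE.fullmatch(self.pseudonym):
            raise ValueError(f"malformed pseudonym: {self.pseudonym!r}")

    @property
    def ref(self) -> tuple[str, str]:
        return (self.site, self.local_id)


# ---------------------------------------------------------------------------
# record types (one per template table)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Enrollment:
    patient: PatientKey
    recruitment_date: dt.date
    status: str  # inpatient | outpatient

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"bad status: {self.status!r}")


@dataclass(frozen=True)
class PersonalData:
    patient: PatientKey
    birth_date: DateValue
    sex: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"bad sex: {self.sex!r}")


@dataclass(frozen=True)
class HistoryRecord:
    patient: PatientKey
    record_date: dt.date
    weight: Optional[float] = None  # kg
    height: Optional[float] = None  # cm
    systolic_bp: Optional[float] = None  # mm Hg
    nyha: Optional[str] = None
    current_smoker: Optional[bool] = None
    hf_first_diagnosis: Optional[DateValue] = None
    diabetes: Optional[bool] = None
    chronic_lung_disease: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.nyha is not None and self.nyha not in NYHA_CLASSES:
            raise ValueError(f"bad NYHA class: {self.nyha!r}")


@dataclass(frozen=True)
class MedicationRecord:
    patient: PatientKey
    record_date: dt.date
    drug_group: str
    substance: Optional[str] = None
    dose: Optional[float] = None  # mg/day

    def __post_init__(self) -> None:
        if self.drug_group not in DRUG_GROUPS:
            raise ValueError(f"bad drug group: {self.drug_group!r}")
        if self.substance is not None and self.substance not in SUBSTANCES:
            raise ValueError(f"bad substance: {self.substance!r}")
        if self.dose is not None and self.dose < 0:
            raise ValueError(f"negative dose: {self.dose}")


@dataclass(frozen=True)
class EchoRecord:
    patient: PatientKey
    record_date: dt.date
    lvef: float  # percent


@dataclass(frozen=True)
class LabRecord:
    patient: PatientKey
    record_date: dt.date
    loinc: str
    analyte: str
    value: float
    unit: str

    def __post_init__(self) -> None:
        expected = LOINC_ANALYTE.get(self.loinc)
        if expected is None:
            raise ValueError(f"unknown LOINC code: {self.loinc!r}")
        if self.analyte != expected:
            raise ValueError(
                f"analyte {self.analyte!r} inconsistent with LOINC {self.loinc}"
            )
        if self.unit != LAB_UNITS[self.analyte]:
            raise ValueError(
                f"unit {self.unit!r} not the canonical {LAB_UNITS[self.analyte]!r} "
                f"for {self.analyte}"
            )


@dataclass
class Cohort:
    """All template tables of one (usually single-site) data set."""

    enrollments: list[Enrollment] = field(default_factory=list)
    personal: list[PersonalData] = field(default_factory=list)
    history: list[HistoryRecord] = field(default_factory=list)
    medication: list[MedicationRecord] = field(default_factory=list)
    echo: list[EchoRecord] = field(default_factory=list)
    labs: list[LabRecord] = field(default_factory=list)

    def patients(self) -> list[PatientKey]:
        return [e.patient for e in self.enrollments]


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

TEMPLATES = {
    "enrollment": ("enrollment.csv", ["site", "local_id", "pseudonym",
                                      "recruitment_date", "status"]),
    "personal": ("personal.csv", ["site", "local_id", "pseudonym",
                                  "birth_date", "sex"]),
    "history": ("history.csv", ["site", "local_id", "pseudonym", "record_date",
                                "weight", "height", "systolic_bp", "nyha",
                                "current_smoker", "hf_first_diagnosis",
                                "diabetes", "chronic_lung_disease"]),
    "medication": ("medication.csv", ["site", "local_id", "pseudonym",
                                      "record_date", "drug_group", "substance",
                                      "dose"]),
    "echo": ("echo.csv", ["site", "local_id", "pseudonym", "record_date",
                          "lvef"]),
    "labs": ("labs.csv", ["site", "local_id", "pseudonym", "record_date",
                          "loinc", "analyte", "value", "unit"]),
}


def _fmt_num(v: Optional[float]) -> str:
    if v is None:
        return ""
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return repr(float(v))


def _fmt_bool(v: Optional[bool]) -> str:
    if v is None:
        return ""
    return "true" if v else "false"


def _parse_num(cell: str) -> Optional[float]:
    if cell == "":
        return None
    return float(cell)


def _parse_bool(cell: str) -> Optional[bool]:
    if cell == "":
        return None
    if cell not in ("true", "false"):
        raise ValueError(f"not a boolean: {cell!r}")
    return cell == "true"


def _parse_date(cell: str) -> dt.date:
    return dt.date.fromisoformat(cell)


def _key_cells(p: PatientKey) -> list[str]:
    return [p.site, p.local_id, p.pseudonym or ""]


def _parse_key(row: dict) -> PatientKey:
    return PatientKey(row["site"], row["local_id"], row["pseudonym"] or None)


def _record_to_row(template: str, r) -> list[str]:
    if template == "enrollment":
        return _key_cells(r.patient) + [r.recruitment_date.isoformat(), r.status]
    if template == "personal":
        return _key_cells(r.patient) + [r.birth_date.isoformat(), r.sex]
    if template == "history":
        return _key_cells(r.patient) + [
            r.record_date.isoformat(), _fmt_num(r.weight), _fmt_num(r.height),
            _fmt_num(r.systolic_bp), r.nyha or "", _fmt_bool(r.current_smoker),
            r.hf_first_diagnosis.isoformat() if r.hf_first_diagnosis else "",
            _fmt_bool(r.diabetes), _fmt_bool(r.chronic_lung_disease)]
    if template == "medication":
        return _key_cells(r.patient) + [r.record_date.isoformat(), r.drug_group,
                                        r.substance or "", _fmt_num(r.dose)]
    if template == "echo":
        return _key_cells(r.patient) + [r.record_date.isoformat(), _fmt_num(r.lvef)]
    if template == "labs":
        return _key_cells(r.patient) + [r.record_date.isoformat(), r.loinc,
                                        r.analyte, _fmt_num(r.value), r.unit]
    raise ConfigurationError(f"unknown template: {template!r}")


def _row_to_record(template: str, row: dict):
    key = _parse_key(row)
    if template == "enrollment":
        return Enrollment(key, _parse_date(row["recruitment_date"]), row["status"])
    if template == "personal":
        return PersonalData(key, DateValue.parse(row["birth_date"]), row["sex"])
    if template == "history":
        hfdx = row["hf_first_diagnosis"]
        return HistoryRecord(
            key, _parse_date(row["record_date"]),
            weight=_parse_num(row["weight"]), height=_parse_num(row["height"]),
            systolic_bp=_parse_num(row["systolic_bp"]),
            nyha=row["nyha"] or None,
            current_smoker=_parse_bool(row["current_smoker"]),
            hf_first_diagnosis=DateValue.parse(hfdx) if hfdx else None,
            diabetes=_parse_bool(row["diabetes"]),
            chronic_lung_disease=_parse_bool(row["chronic_lung_disease"]))
    if template == "medication":
        return MedicationRecord(key, _parse_date(row["record_date"]),
                                row["drug_group"], row["substance"] or None,
                                _parse_num(row["dose"]))
    if template == "echo":
        lvef = _parse_num(row["lvef"])
        if lvef is None:
            raise ValueError("lvef is mandatory in echo rows")
        return EchoRecord(key, _parse_date(row["record_date"]), lvef)
    if template == "labs":
        value = _parse_num(row["value"])
        if value is None:
            raise ValueError("value is mandatory in lab rows")
        analyte = row["analyte"] or LOINC_ANALYTE.get(row["loinc"], "")
        return LabRecord(key, _parse_date(row["record_date"]), row["loinc"],
                         analyte, value, row["unit"])
    raise ConfigurationError(f"unknown template: {template!r}")


def read_template_table(path, template: str) -> list:
    """Read one template CSV into a list of records.

    Raises :class:`FormatError` when the header does not match the
    dialect (missing or unknown columns are both rejected) and
    :class:`RowParseError` with the 1-based data-row index for
    unparseable cells.
    """
    if template not in TEMPLATES:
        raise ConfigurationError(f"unknown template: {template!r}")
    _, columns = TEMPLATES[template]
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        missing = [c for c in columns if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s): "
                              + ", ".join(missing))
        unknown = [c for c in header if c not in columns]
        if unknown:
            raise FormatError(f"{path}: unknown column(s): " + ", ".join(unknown))
        if header != columns:
            raise FormatError(f"{path}: columns out of canonical order")
        records = []
        for i, cells in enumerate(reader, start=1):
            if len(cells) != len(columns):
                raise RowParseError(i, f"expected {len(columns)} cells, "
                                       f"got {len(cells)}")
            row = dict(zip(columns, cells))
            try:
                records.append(_row_to_record(template, row))
            except (ValueError, KeyError) as exc:
                raise RowParseError(i, str(exc)) from exc
    return records


def write_template_table(records, template: str, path) -> None:
    _, columns = TEMPLATES[template]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(columns)
        for r in records:
            writer.writerow(_record_to_row(template, r))


_COHORT_ATTRS = {
    "enrollment": "enrollments", "personal": "personal", "history": "history",
    "medication": "medication", "echo": "echo", "labs": "labs",
}


def write_cohort(cohort: Cohort, directory) -> None:
    """Write all six template CSVs of a cohort into *directory*."""
    directory = Path(directory)
    for template, (filename, _) in TEMPLATES.items():
        write_template_table(getattr(cohort, _COHORT_ATTRS[template]),
                             template, directory / filename)


def read_cohort(directory) -> Cohort:
    """Read the six template CSVs of *directory* into a Cohort."""
    directory = Path(directory)
    kwargs = {}
    for template, (filename, _) in TEMPLATES.items():
        kwargs[_COHORT_ATTRS[template]] = read_template_table(
            directory / filename, template)
    return Cohort(**kwargs)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Report-only outcome of referential-integrity checks."""

    orphans: list[tuple[str, PatientKey]] = field(default_factory=list)
    duplicate_enrollments: list[PatientKey] = field(default_factory=list)
    unit_mismatches: list[tuple[PatientKey, str, str]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.orphans or self.duplicate_enrollments
                    or self.unit_mismatches)

    def entries(self) -> Iterator[dict]:
        for template, key in self.orphans:
            yield {"kind": "orphan", "template": template,
                   "site": key.site, "local_id": key.local_id}
        for key in self.duplicate_enrollments:
            yield {"kind": "duplicate_enrollment",
                   "site": key.site, "local_id": key.local_id}
        for key, analyte, unit in self.unit_mismatches:
            yield {"kind": "unit_mismatch", "site": key.site,
                   "local_id": key.local_id, "analyte": analyte, "unit": unit}

    def to_jsonl(self) -> str:
        return "".join(json.dumps(e, sort_keys=True) + "\n"
                       for e in self.entries())


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """List orphan records, duplicate enrollments and unit mismatches."""
    report = ValidationReport()
    enrolled: set[tuple[str, str]] = set()
    for e in cohort.enrollments:
        if e.patient.ref in enrolled:
            report.duplicate_enrollments.append(e.patient)
        enrolled.add(e.patient.ref)
    for template, attr in _COHORT_ATTRS.items():
        if template == "enrollment":
            continue
        for r in getattr(cohort, attr):
            if r.patient.ref not in enrolled:
                report.orphans.append((template, r.patient))
    for lab in cohort.labs:
        # record-level validation enforces this too; kept for tables built
        # programmatically with object.__new__ or after future relaxations
        if lab.unit != LAB_UNITS.get(lab.analyte):
            report.unit_mismatches.append((lab.patient, lab.analyte, lab.unit))
    return report


# ---------------------------------------------------------------------------
# pseudonymization
# ---------------------------------------------------------------------------


def pseudonymize(cohort: Cohort,
                 site_letter_map: Optional[dict[str, str]] = None,
                 ) -> tuple[Cohort, list[dict]]:
    """Replace local identifiers with site-scoped pseudonyms.

    Patients are enumerated per site in sorted ``local_id`` order
    ("G1", "G2", ...).  Patients that already carry a pseudonym keep it,
    which makes the operation idempotent.  Returns the pseudonymized
    cohort and the key table (one row per newly assigned pseudonym),
    which must never be embedded in shared output.
    """
    if site_letter_map is None:
        site_letter_map = {s: s for s in SITES}
    key_table: list[dict] = []
    mapping: dict[tuple[str, str], PatientKey] = {}
    counters: dict[str, int] = {}

    for e in cohort.enrollments:  # existing pseudonyms reserve their counter
        p = e.patient
        if p.pseudonym is not None:
            m = _PSEUDONYM_RE.fullmatch(p.pseudonym)
            prefix, num = m.group(1), int(m.group(2))
            counters[prefix] = max(counters.get(prefix, 0), num)

    for e in sorted(cohort.enrollments, key=lambda e: (e.patient.site,
                                                       e.patient.local_id)):
        p = e.patient
        if p.site not in site_letter_map:
            raise ConfigurationError(f"site {p.site!r} missing from the "
                                     "site-letter map")
        if p.pseudonym is not None:
            mapping[p.ref] = PatientKey(p.site, p.pseudonym, p.pseudonym)
            continue
        prefix = site_letter_map[p.site]
        counters[prefix] = counters.get(prefix, 0) + 1
        pseudonym = f"{prefix}{counters[prefix]}"
        mapping[p.ref] = PatientKey(p.site, pseudonym, pseudonym)
        key_table.append({"site": p.site, "local_id": p.local_id,
                          "pseudonym": pseudonym})

    def rekey(record):
        new = mapping.get(record.patient.ref)
        if new is None:  # orphan record: leave untouched
            return record
        return replace(record, patient=new)

    out = Cohort(**{attr: [rekey(r) for r in getattr(cohort, attr)]
                    for attr in _COHORT_ATTRS.values()})
    return out, key_table


def write_key_table(key_table: list[dict], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["site", "local_id", "pseudonym"])
        for row in key_table:
            writer.writerow([row["site"], row["local_id"], row["pseudonym"]])
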