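"""Harmonization: from raw template records to one row per patient.

Encodes the preparation rules: mid-period completion of reduced-precision
dates, completed-birthday age, BMI from weight and height, whole-month HF
duration with the >= 18 months flag, closest-record selection anchored at
recruitment, medication-group mapping with absence defaulting to "not
taken", and furosemide-equivalent loop-diuretic dosing.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from hfscores.cohort_model import Cohort, DateValue, MedicationRecord
from hfscores.errors import InvalidInputError

#: clinical fields of the harmonized row (everything except the key columns)
CLINICAL_FIELDS = (
    "age", "sex", "bmi", "systolic_bp", "nyha", "current_smoker", "diabetes",
    "copd_proxy", "hf_duration", "hf_duration_ge_18", "beta_blocker",
    "acei_arb", "statin", "loop_diuretic", "furosemide_equiv_dose", "lvef",
    "creatinine", "sodium", "hemoglobin", "egfr",
)

KEY_COLUMNS = ("site", "local_id", "pseudonym", "status", "recruitment_date")


@dataclass(frozen=True)
class HarmonizationConfig:
    """Tunable mapping constants (kept out of code so they can be audited)."""

    default_furosemide_dose: float = 40.0  # mg/day when dose undocumented
    torasemide_to_furosemide: float = 4.0
    medication_anchor: str = "recruitment"  # anchor date for closeness


@dataclass
class HarmonizedResult:
    table: pd.DataFrame
    provenance: pd.DataFrame  # source record date (ISO) per clinical field
    log: list[dict] = field(default_factory=list)


def complete_date(d: DateValue) -> dt.date:
    """Complete a reduced-precision date to a full calendar date.

    Year precision completes to July 1 (mid-year), month precision to the
    15th (mid-month); day precision is returned unchanged.
    """
    if d.precision == "day":
        return dt.date(d.year, d.month, d.day)
    if d.precision == "month":
        return dt.date(d.year, d.month, 15)
    return dt.date(d.year, 7, 1)


def derive_age(birth: DateValue, reference: dt.date) -> int:
    """Completed whole-year age at *reference* (birthday arithmetic)."""
    completed = complete_date(birth)
    if completed > reference:
        raise InvalidInputError(f"birth date {completed} after reference "
                                f"{reference}")
    years = reference.year - completed.year
    if (reference.month, reference.day) < (completed.month, completed.day):
        years -= 1
    return years


def compute_bmi(weight: float, height: float) -> float:
    """BMI in kg/m² from weight in kg and height in cm."""
    if weight <= 0 or height <= 0:
        raise InvalidInputError("weight and height must be positive")
    return weight / (height / 100.0) ** 2


def hf_duration_months(first_dx: DateValue,
                       recruitment: dt.date) -> tuple[int, bool]:
    """Whole elapsed months between (completed) HF onset and recruitment.

    Returns ``(months, months >= 18)``.  Raises for onset after
    recruitment; callers treat that as missing and log it.
    """
    onset = complete_date(first_dx)
    if onset > recruitment:
        raise InvalidInputError(f"HF onset {onset} after recruitment "
                                f"{recruitment}")
    months = 12 * (recruitment.year - onset.year) \
        + (recruitment.month - onset.month)
    if recruitment.day < onset.day:
        months -= 1
    return months, months >= 18


def select_closest(records: Sequence, recruitment: dt.date,
                   date_of: Callable = lambda r: r.record_date):
    """Record minimizing ``|record_date - recruitment|``, ties to the
    earlier (pre-recruitment) record."""
    if not records:
        raise InvalidInputError("empty record list")
    def sort_key(r):
        d = date_of(r)
        return (abs((d - recruitment).days), d > recruitment)
    return min(records, key=sort_key)


def map_medication(entries: Sequence[MedicationRecord],
                   config: Optional[HarmonizationConfig] = None,
                   ) -> tuple[dict[str, bool], float, list[dict]]:
    """Map one medication list to drug-group booleans and a
    furosemide-equivalent loop-diuretic dose in mg/day.

    Absent groups default to "not taken".  A loop-diuretic entry without a
    dose contributes the configured default lowest furosemide dose;
    torasemide doses are converted with the configured factor.
    """
    config = config or HarmonizationConfig()
    groups = {g: False for g in ("beta_blocker", "acei_arb", "statin",
                                 "loop_diuretic")}
    dose = 0.0
    log: list[dict] = []
    for e in entries:
        groups[e.drug_group] = True
        if e.drug_group != "loop_diuretic":
            continue
        if e.dose is None:
            dose += config.default_furosemide_dose
            log.append({"event": "default_dose", "substance": e.substance,
                        "applied_mg": config.default_furosemide_dose})
        elif e.dose < 0:
            raise InvalidInputError(f"negative dose: {e.dose}")
        elif e.substance == "torasemide":
            dose += e.dose * config.torasemide_to_furosemide
        else:
            dose += e.dose
    return groups, dose, log


def _closest_value(records, recruitment, getter):
    """Closest record among those where *getter* yields a value."""
    eligible = [r for r in records if getter(r) is not None]
    if not eligible:
        return None, None
    rec = select_closest(eligible, recruitment)
    return getter(rec), rec.record_date


def build_harmonized(cohort: Cohort,
                     config: Optional[HarmonizationConfig] = None,
                     ) -> HarmonizedResult:
    """One harmonized row per enrolled patient, with provenance and log."""
    config = config or HarmonizationConfig()
    log: list[dict] = []
    by_patient: dict = {}

    def index(records):
        out: dict = {}
        for r in records:
            out.setdefault(r.patient.ref, []).append(r)
        return out

    personal = {p.patient.ref: p for p in cohort.personal}
    history = index(cohort.history)
    medication = index(cohort.medication)
    echo = index(cohort.echo)
    labs = index(cohort.labs)

    rows: list[dict] = []
    prov_rows: list[dict] = []
    for e in cohort.enrollments:
        key = e.patient
        rec_date = e.recruitment_date
        row: dict = {"site": key.site, "local_id": key.local_id,
                     "pseudonym": key.pseudonym, "status": e.status,
                     "recruitment_date": rec_date.isoformat()}
        prov: dict = {"site": key.site, "local_id": key.local_id}
        row.update({f: None for f in CLINICAL_FIELDS})
        prov.update({f: None for f in CLINICAL_FIELDS})

        def patient_log(event, **kw):
            log.append({"site": key.site, "local_id": key.local_id,
                        "event": event, **kw})

        pd_rec = personal.get(key.ref)
        if pd_rec is None:
            patient_log("empty_template", template="personal")
        else:
            row["sex"] = pd_rec.sex
            prov["sex"] = rec_date.isoformat()
            birth = pd_rec.birth_date
            if birth.precision != "day":
                patient_log("date_completed", field="birth_date",
                            original=birth.isoformat(),
                            completed=complete_date(birth).isoformat())
            try:
                row["age"] = derive_age(birth, rec_date)
                prov["age"] = complete_date(birth).isoformat()
            except InvalidInputError:
                patient_log("birth_after_recruitment",
                            birth=birth.isoformat())

        hrecs = history.get(key.ref, [])
        if not hrecs:
            patient_log("empty_template", template="history")
        weight, w_date = _closest_value(hrecs, rec_date, lambda r: r.weight)
        height, h_date = _closest_value(hrecs, rec_date, lambda r: r.height)
        if weight is not None and height is not None:
            try:
                row["bmi"] = compute_bmi(weight, height)
                prov["bmi"] = max(w_date, h_date).isoformat()
            except InvalidInputError:
                patient_log("bmi_invalid", weight=weight, height=height)
        for fname, getter in (
                ("systolic_bp", lambda r: r.systolic_bp),
                ("nyha", lambda r: r.nyha),
                ("current_smoker", lambda r: r.current_smoker),
                ("diabetes", lambda r: r.diabetes),
                ("copd_proxy", lambda r: r.chronic_lung_disease)):
            value, vdate = _closest_value(hrecs, rec_date, getter)
            if value is not None:
                row[fname] = value
                prov[fname] = vdate.isoformat()
        hf_dx, hf_date = _closest_value(hrecs, rec_date,
                                        lambda r: r.hf_first_diagnosis)
        if hf_dx is not None:
            if hf_dx.precision != "day":
                patient_log("date_completed", field="hf_first_diagnosis",
                            original=hf_dx.isoformat(),
                            completed=complete_date(hf_dx).isoformat())
            try:
                months, ge18 = hf_duration_months(hf_dx, rec_date)
                row["hf_duration"] = months
                row["hf_duration_ge_18"] = ge18
                prov["hf_duration"] = hf_date.isoformat()
                prov["hf_duration_ge_18"] = hf_date.isoformat()
            except InvalidInputError:
                patient_log("onset_after_recruitment",
                            onset=hf_dx.isoformat())

        mrecs = medication.get(key.ref, [])
        if mrecs:
            anchor = rec_date  # configurable anchor; only recruitment shipped
            list_date = select_closest(sorted({r.record_date for r in mrecs}),
                                       anchor, date_of=lambda d: d)
            entries = [r for r in mrecs if r.record_date == list_date]
        else:
            patient_log("empty_template", template="medication")
            list_date, entries = rec_date, []
        groups, dose, med_log = map_medication(entries, config)
        for ev in med_log:
            patient_log(**ev)
        for g, present in groups.items():
            row[g] = present
            prov[g] = list_date.isoformat()
            if not present and mrecs:
                patient_log("medication_absent_default", drug_group=g)
        row["furosemide_equiv_dose"] = dose
        prov["furosemide_equiv_dose"] = list_date.isoformat()

        erecs = echo.get(key.ref, [])
        if erecs:
            rec = select_closest(erecs, rec_date)
            row["lvef"] = rec.lvef
            prov["lvef"] = rec.record_date.isoformat()
        else:
            patient_log("empty_template", template="echo")

        lrecs = labs.get(key.ref, [])
        if not lrecs:
            patient_log("empty_template", template="labs")
        for analyte in ("creatinine", "sodium", "hemoglobin", "egfr"):
            arecs = [r for r in lrecs if r.analyte == analyte]
            if arecs:
                rec = select_closest(arecs, rec_date)
                row[analyte] = rec.value
                prov[analyte] = rec.record_date.isoformat()

        for f in CLINICAL_FIELDS:
            if row[f] is None and f not in ("beta_blocker", "acei_arb",
                                            "statin", "loop_diuretic",
                                            "furosemide_equiv_dose"):
                patient_log("missing_field", field=f)
        rows.append(row)
        prov_rows.append(prov)

    columns = list(KEY_COLUMNS) + list(CLINICAL_FIELDS)
    table = pd.DataFrame(rows, columns=columns)
    provenance = pd.DataFrame(prov_rows,
                              columns=["site", "local_id", *CLINICAL_FIELDS])
    for col in ("age", "bmi", "systolic_bp", "hf_duration",
                "furosemide_equiv_dose", "lvef", "creatinine", "sodium",
                "hemoglobin", "egfr"):
        table[col] = pd.to_numeric(table[col])
    return HarmonizedResult(table=table, provenance=provenance, log=log)


def missing_flags(table: pd.DataFrame) -> pd.DataFrame:
    """Boolean frame: True iff the clinical field is absent."""
    return table[list(CLINICAL_FIELDS)].isna()
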