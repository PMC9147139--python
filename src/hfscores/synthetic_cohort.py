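"""Seeded generator of multi-site synthetic cohorts.

Stands in for clinical data: configurable per-variable distributions,
per-item missingness, reduced date precision (year-only birth and HF
onset) and an adjustable rate of implausible values injected just
outside the plausibility limits.  Deterministic given (profile, seed);
per-site sub-seeds are derived from a stable hash of the site code so
the output is independent of profile ordering.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from hfscores.cohort_model import (
    Cohort,
    DateValue,
    EchoRecord,
    Enrollment,
    HistoryRecord,
    LabRecord,
    LOINC_ANALYTE,
    LAB_UNITS,
    MedicationRecord,
    PatientKey,
    PersonalData,
)
from hfscores.errors import ConfigurationError

# plausibility bounds used when injecting implausible values; transcribed
# to stay just outside the admissible ranges of the checks module
_INJECTION_BOUNDS = {
    "systolic_bp": (70.0, 250.0),
    "lvef": (4.0, 85.0),
    "creatinine": (26.526, 1326.3),
    "sodium": (120.0, 150.0),
    "hemoglobin": (5.0, 20.0),
    "egfr": (5.0, 120.0),
}

MISSABLE_ITEMS = (
    "weight", "height", "systolic_bp", "nyha", "current_smoker",
    "hf_first_diagnosis", "diabetes", "chronic_lung_disease",
    "lvef", "creatinine", "sodium", "hemoglobin", "egfr", "medication",
)


@dataclass(frozen=True)
class ContinuousSpec:
    """Truncated-normal spec with an admissible range."""

    mean: float
    sd: float
    lo: float
    hi: float

    def validate(self, name: str) -> None:
        if not self.lo <= self.hi:
            raise ConfigurationError(f"{name}: lo > hi")
        if self.sd < 0:
            raise ConfigurationError(f"{name}: negative sd")
        if not self.lo <= self.mean <= self.hi:
            raise ConfigurationError(f"{name}: mean outside [lo, hi]")


def _default_missingness() -> dict[str, float]:
    return {item: 0.0 for item in MISSABLE_ITEMS}


@dataclass
class SiteProfile:
    """Generative specification for one synthetic site."""

    site: str
    n_patients: int
    inpatient_fraction: float = 0.5
    p_female: float = 0.4
    recruitment_start: dt.date = dt.date(2018, 1, 1)
    recruitment_end: dt.date = dt.date(2021, 12, 31)
    age: ContinuousSpec = field(default_factory=lambda: ContinuousSpec(68, 12, 19, 100))
    height: ContinuousSpec = field(default_factory=lambda: ContinuousSpec(172, 10, 145, 205))
    bmi: ContinuousSpec = field(default_factory=lambda: ContinuousSpec(27.5, 4.5, 15, 55))
    systolic_bp: ContinuousSpec = field(default_factory=lambda: ContinuousSpec(124, 19, 71, 249))
    lvef: ContinuousSpec = field(default_factory=lambda: ContinuousSpec(38, 12, 5, 80))
    creatinine: ContinuousSpec = field(default_factory=lambda: ContinuousSpec(100, 35, 30, 700))
    sodium: ContinuousSpec = field(default_factory=lambda: ContinuousSpec(139, 3.2, 121, 149))
    hemoglobin: ContinuousSpec = field(default_factory=lambda: ContinuousSpec(13.4, 1.8, 6, 19))
    egfr: ContinuousSpec = field(default_factory=lambda: ContinuousSpec(62, 22, 6, 119))
    hf_years_before: ContinuousSpec = field(default_factory=lambda: ContinuousSpec(2.5, 2.5, 0, 15))
    nyha_probs: tuple[float, float, float, float] = (0.12, 0.43, 0.35, 0.10)
    p_smoker: float = 0.18
    p_diabetes: float = 0.32
    p_lung_disease: float = 0.14
    med_probs: dict[str, float] = field(default_factory=lambda: {
        "beta_blocker": 0.85, "acei_arb": 0.75, "statin": 0.5,
        "loop_diuretic": 0.6})
    p_dose_missing: float = 0.3
    p_torasemide: float = 0.35
    missingness: dict[str, float] = field(default_factory=_default_missingness)
    year_only_birth_fraction: float = 0.5
    year_only_hf_onset_fraction: float = 0.5
    implausible_rate: float = 0.0
    records_per_template: tuple[int, int] = (1, 3)

    _CONTINUOUS = ("age", "height", "bmi", "systolic_bp", "lvef", "creatinine",
                   "sodium", "hemoglobin", "egfr", "hf_years_before")

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        probs = {
            "inpatient_fraction": self.inpatient_fraction,
            "p_female": self.p_female, "p_smoker": self.p_smoker,
            "p_diabetes": self.p_diabetes,
            "p_lung_disease": self.p_lung_disease,
            "p_dose_missing": self.p_dose_missing,
            "p_torasemide": self.p_torasemide,
            "year_only_birth_fraction": self.year_only_birth_fraction,
            "year_only_hf_onset_fraction": self.year_only_hf_onset_fraction,
            "implausible_rate": self.implausible_rate,
        }
        probs.update({f"med_probs[{k}]": v for k, v in self.med_probs.items()})
        probs.update({f"missingness[{k}]": v for k, v in self.missingness.items()})
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} not a probability: {p}")
        if abs(sum(self.nyha_probs) - 1.0) > 1e-9:
            raise ConfigurationError("nyha_probs must sum to 1")
        for name in self._CONTINUOUS:
            getattr(self, name).validate(name)
        if self.age.lo < 18:
            raise ConfigurationError("age.lo below the inclusion bound of 18")
        lo, hi = self.records_per_template
        if not 1 <= lo <= hi:
            raise ConfigurationError("records_per_template must satisfy 1 <= lo <= hi")
        if self.recruitment_start > self.recruitment_end:
            raise ConfigurationError("recruitment window is empty")
        unknown = set(self.missingness) - set(MISSABLE_ITEMS)
        if unknown:
            raise ConfigurationError(f"unknown missingness item(s): {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "SiteProfile":
        d = dict(d)
        for name in cls._CONTINUOUS:
            if name in d and isinstance(d[name], dict):
                d[name] = ContinuousSpec(**d[name])
        for key in ("recruitment_start", "recruitment_end"):
            if key in d and isinstance(d[key], str):
                d[key] = dt.date.fromisoformat(d[key])
        if "nyha_probs" in d:
            d["nyha_probs"] = tuple(d["nyha_probs"])
        if "records_per_template" in d:
            d["records_per_template"] = tuple(d["records_per_template"])
        if "missingness" in d:
            miss = _default_missingness()
            miss.update(d["missingness"])
            d["missingness"] = miss
        return cls(**d)


def load_profiles(path) -> list[SiteProfile]:
    """Load a YAML list of site profiles (top-level key ``sites``)."""
    with Path(path).open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    entries = doc["sites"] if isinstance(doc, dict) else doc
    return [SiteProfile.from_dict(e) for e in entries]


def _site_entropy(site: str) -> int:
    return int.from_bytes(hashlib.sha256(site.encode()).digest()[:8], "big")


def _truncnorm(rng: np.random.Generator, spec: ContinuousSpec) -> float:
    if spec.sd == 0:
        return spec.mean
    for _ in range(1000):  # rejection sampling; ranges are wide in practice
        x = rng.normal(spec.mean, spec.sd)
        if spec.lo <= x <= spec.hi:
            return float(x)
    return float(min(max(spec.mean, spec.lo), spec.hi))


def _implausible(rng: np.random.Generator, item: str) -> float:
    """Draw a value just outside the admissible range (uniform, ±50% band)."""
    lo, hi = _INJECTION_BOUNDS[item]
    if rng.random() < 0.5:
        return float(rng.uniform(hi * 1.0001, hi * 1.5))
    return float(rng.uniform(lo * 0.5, lo * 0.9999))


def _subtract_days(date: dt.date, days: float) -> dt.date:
    return date - dt.timedelta(days=int(round(days)))


def _whole_years(birth: dt.date, ref: dt.date) -> int:
    years = ref.year - birth.year
    if (ref.month, ref.day) < (birth.month, birth.day):
        years -= 1
    return years


def generate_site(profile: SiteProfile, seed: int) -> Cohort:
    """Generate one site's cohort. Fully deterministic given (profile, seed)."""
    profile.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, _site_entropy(profile.site)]))
    cohort = Cohort()
    window = (profile.recruitment_end - profile.recruitment_start).days
    width = len(str(profile.n_patients))

    for i in range(profile.n_patients):
        key = PatientKey(profile.site, f"p{i + 1:0{width}d}")
        recruitment = profile.recruitment_start + dt.timedelta(
            days=int(rng.integers(0, window + 1)))
        status = "inpatient" if rng.random() < profile.inpatient_fraction \
            else "outpatient"
        cohort.enrollments.append(Enrollment(key, recruitment, status))

        sex = "female" if rng.random() < profile.p_female else "male"
        age = _truncnorm(rng, profile.age)
        birth = _subtract_days(recruitment, age * 365.25)
        birth_dv = DateValue.from_date(birth)
        if rng.random() < profile.year_only_birth_fraction:
            # keep day precision if mid-year completion would violate the
            # age >= 18 inclusion bound
            completed = dt.date(birth.year, 7, 1)
            if _whole_years(completed, recruitment) >= 18:
                birth_dv = DateValue(birth.year)
        cohort.personal.append(PersonalData(key, birth_dv, sex))

        miss = profile.missingness
        n_rec = int(rng.integers(profile.records_per_template[0],
                                 profile.records_per_template[1] + 1))
        offsets = [int(rng.integers(-60, 31)) for _ in range(n_rec)]

        # one underlying value per patient and item, shared across records
        values: dict[str, Optional[float]] = {}
        height = _truncnorm(rng, profile.height)
        bmi = _truncnorm(rng, profile.bmi)
        values["height"] = height
        values["weight"] = round(bmi * (height / 100.0) ** 2, 1)
        for item in ("systolic_bp", "lvef", "creatinine", "sodium",
                     "hemoglobin", "egfr"):
            v = _truncnorm(rng, getattr(profile, item))
            if rng.random() < profile.implausible_rate:
                v = _implausible(rng, item)
            values[item] = round(v, 3)
        nyha = str(np.array(["I", "II", "III", "IV"])[
            rng.choice(4, p=np.asarray(profile.nyha_probs))])
        smoker = bool(rng.random() < profile.p_smoker)
        diabetes = bool(rng.random() < profile.p_diabetes)
        lung = bool(rng.random() < profile.p_lung_disease)

        hf_dx: Optional[DateValue] = None
        if rng.random() >= miss.get("hf_first_diagnosis", 0.0):
            onset = _subtract_days(recruitment,
                                   _truncnorm(rng, profile.hf_years_before) * 365.25)
            if rng.random() < profile.year_only_hf_onset_fraction:
                hf_dx = DateValue(onset.year)
            else:
                hf_dx = DateValue.from_date(onset)

        missing = {item: rng.random() < miss.get(item, 0.0)
                   for item in ("weight", "height", "systolic_bp", "nyha",
                                "current_smoker", "diabetes",
                                "chronic_lung_disease", "lvef", "creatinine",
                                "sodium", "hemoglobin", "egfr")}

        for off in offsets:
            record = HistoryRecord(
                key, recruitment + dt.timedelta(days=off),
                weight=None if missing["weight"] else values["weight"],
                height=None if missing["height"] else values["height"],
                systolic_bp=None if missing["systolic_bp"] else values["systolic_bp"],
                nyha=None if missing["nyha"] else nyha,
                current_smoker=None if missing["current_smoker"] else smoker,
                hf_first_diagnosis=hf_dx,
                diabetes=None if missing["diabetes"] else diabetes,
                chronic_lung_disease=None if missing["chronic_lung_disease"] else lung)
            if any(getattr(record, f) is not None for f in
                   ("weight", "height", "systolic_bp", "nyha", "current_smoker",
                    "hf_first_diagnosis", "diabetes", "chronic_lung_disease")):
                cohort.history.append(record)

        if not missing["lvef"]:
            for off in offsets:
                cohort.echo.append(EchoRecord(
                    key, recruitment + dt.timedelta(days=off), values["lvef"]))

        codes = {a: sorted(c for c, an in LOINC_ANALYTE.items() if an == a)
                 for a in ("creatinine", "sodium", "hemoglobin", "egfr")}
        for analyte in ("creatinine", "sodium", "hemoglobin", "egfr"):
            if missing[analyte]:
                continue
            loinc = codes[analyte][int(rng.integers(0, len(codes[analyte])))]
            for off in offsets:
                cohort.labs.append(LabRecord(
                    key, recruitment + dt.timedelta(days=off), loinc, analyte,
                    values[analyte], LAB_UNITS[analyte]))

        if rng.random() >= miss.get("medication", 0.0):
            list_date = recruitment + dt.timedelta(days=int(rng.integers(-30, 15)))
            for group in ("beta_blocker", "acei_arb", "statin", "loop_diuretic"):
                if rng.random() >= profile.med_probs.get(group, 0.0):
                    continue
                substance = None
                dose = None
                if group == "loop_diuretic":
                    if rng.random() < profile.p_torasemide:
                        substance = "torasemide"
                        dose = float(rng.choice([5.0, 10.0, 20.0]))
                    else:
                        substance = "furosemide"
                        dose = float(rng.choice([20.0, 40.0, 80.0]))
                    if rng.random() < profile.p_dose_missing:
                        dose = None
                cohort.medication.append(MedicationRecord(
                    key, list_date, group, substance, dose))

    return cohort


def generate_multisite(profiles: list[SiteProfile], seed: int) -> list[Cohort]:
    """Generate one cohort per profile with order-independent sub-seeds."""
    codes = [p.site for p in profiles]
    if len(set(codes)) != len(codes):
        raise ConfigurationError("duplicate site codes in profile list")
    for p in profiles:
        p.validate()
    return [generate_site(p, seed) for p in profiles]
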