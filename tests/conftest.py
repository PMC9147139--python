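import datetime as dt

import pytest

from hfscores import cohort_model as cm
from hfscores.synthetic_cohort import SiteProfile


def build_patient(cohort: cm.Cohort, site: str, local_id: str,
                  recruitment: dt.date, status: str = "outpatient",
                  birth: cm.DateValue = cm.DateValue(1950),
                  sex: str = "male") -> cm.PatientKey:
    """Add one fully documented patient to *cohort* and return the key."""
    key = cm.PatientKey(site, local_id)
    cohort.enrollments.append(cm.Enrollment(key, recruitment, status))
    cohort.personal.append(cm.PersonalData(key, birth, sex))
    cohort.history.append(cm.HistoryRecord(
        key, recruitment - dt.timedelta(days=3), weight=80.0, height=175.0,
        systolic_bp=125.0, nyha="II", current_smoker=False,
        hf_first_diagnosis=cm.DateValue(recruitment.year - 2, 3, 10),
        diabetes=False, chronic_lung_disease=False))
    cohort.medication.append(cm.MedicationRecord(
        key, recruitment - dt.timedelta(days=2), "beta_blocker"))
    cohort.medication.append(cm.MedicationRecord(
        key, recruitment - dt.timedelta(days=2), "acei_arb"))
    cohort.medication.append(cm.MedicationRecord(
        key, recruitment - dt.timedelta(days=2), "statin"))
    cohort.medication.append(cm.MedicationRecord(
        key, recruitment - dt.timedelta(days=2), "loop_diuretic",
        "furosemide", 40.0))
    cohort.echo.append(cm.EchoRecord(
        key, recruitment - dt.timedelta(days=5), 35.0))
    for loinc, analyte, value in (("14682-9", "creatinine", 95.0),
                                  ("2951-2", "sodium", 139.0),
                                  ("718-7", "hemoglobin", 13.2),
                                  ("62238-1", "egfr", 62.0)):
        cohort.labs.append(cm.LabRecord(
            key, recruitment - dt.timedelta(days=4), loinc, analyte, value,
            cm.LAB_UNITS[analyte]))
    return key


@pytest.fixture
def small_cohort() -> cm.Cohort:
    cohort = cm.Cohort()
    build_patient(cohort, "G", "p01", dt.date(2019, 5, 10))
    build_patient(cohort, "G", "p02", dt.date(2019, 8, 21),
                  status="inpatient", birth=cm.DateValue(1944, 11, 2),
                  sex="female")
    build_patient(cohort, "H", "p01", dt.date(2020, 2, 2),
                  status="inpatient", birth=cm.DateValue(1958, 6))
    return cohort


def make_profile(**overrides) -> SiteProfile:
    defaults = dict(site="G", n_patients=50, implausible_rate=0.0,
                    year_only_birth_fraction=0.3,
                    year_only_hf_onset_fraction=0.3)
    defaults.update(overrides)
    return SiteProfile(**defaults)


@pytest.fixture
def profile() -> SiteProfile:
    return make_profile()
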