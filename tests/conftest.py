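"""Shared fixtures and patient-construction helpers."""

import pytest

from kdscore import (ClinicalSigns, LabPanel, PatientRecord, builtin_models,
                     generate_cohort, SyntheticCohortConfig)


def make_patient(pid="p1", age_months=24.0, illness_day=6, sex="male",
                 ivig_resistant=None, signs=None, **labs) -> PatientRecord:
    """Build a patient with sensible defaults; labs passed by keyword."""
    sign_obj = ClinicalSigns(**(signs or {}))
    return PatientRecord(id=pid, age_months=age_months, sex=sex,
                         illness_day_at_treatment=illness_day,
                         signs=sign_obj, labs=LabPanel(**labs),
                         ivig_resistant=ivig_resistant)


def typical_responder(pid="r1") -> PatientRecord:
    """A plausible IVIG-responsive child: unremarkable labs everywhere."""
    return make_patient(pid, age_months=24, illness_day=6, ivig_resistant=False,
                        signs={"rash": True, "edema_extremities": False,
                               "cervical_lymphadenopathy": True},
                        crp=40.0, alt=25.0, ast=30.0, na=137.0, alb=40.0,
                        plt=380.0, neut_pct=55.0, neut_count=6.0,
                        lymph_count=3.0, tb=5.0)


@pytest.fixture
def models():
    return builtin_models()


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded synthetic cohort, shared across tests that only read it."""
    return generate_cohort(SyntheticCohortConfig(n=600, seed=11))
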