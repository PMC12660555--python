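import numpy as np
import pytest

from ehrfusion.ehr_data import LabelSpace, LabResult, PatientRecord, Visit


@pytest.fixture
def label_space():
    return LabelSpace(("HTN", "DM", "CHF", "ARRHY"))


@pytest.fixture
def small_patient():
    """Three visits with easy hand-checkable timings: (0,48), (100,124), (200,212)."""
    return PatientRecord(
        patient_id="P1",
        visits=[
            Visit(
                admission_time=0.0,
                discharge_time=48.0,
                diagnoses={"DM"},
                note_sections={"ChiefComplaint": "polyuria fatigue"},
                labs=[LabResult("Glucose", "240", "mg/dL", abnormal=True)],
            ),
            Visit(
                admission_time=100.0,
                discharge_time=124.0,
                diagnoses={"DM", "HTN"},
                note_sections={"CurrentIllness": "headache", "MedicalHistory": "diabetes"},
                labs=[LabResult("Glucose", "180", "mg/dL", abnormal=False)],
            ),
            Visit(
                admission_time=200.0,
                discharge_time=212.0,
                diagnoses={"DM", "HTN", "CHF"},
                note_sections={"ChiefComplaint": "dyspnea"},
                labs=[LabResult("BNP", "900", "pg/mL", abnormal=True)],
            ),
        ],
    )


@pytest.fixture
def small_cohort(small_patient):
    second = PatientRecord(
        patient_id="P2",
        visits=[
            Visit(admission_time=10.0, discharge_time=20.0, diagnoses={"ARRHY"}),
            Visit(admission_time=500.0, discharge_time=530.0, diagnoses={"ARRHY", "CHF"}),
        ],
    )
    return [small_patient, second]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
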