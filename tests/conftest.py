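import pytest

from gastropd.cohort import (
    CohortTable,
    EventRecord,
    PatientRecord,
    VisitObservation,
)
from gastropd.response import ResponseParams
from gastropd.simulate import SimulationConfig, simulate_cohort
from gastropd.survival import HazardParams


@pytest.fixture
def table_response_params() -> ResponseParams:
    """Published clinical response estimates (random-effect variance = 1)."""
    return ResponseParams(
        beta=(19.7, -4.62),
        theta_markov={"PR": 18.1, "SD": 19.4, "DP": 18.8},
        omega2=1.0,
    )


@pytest.fixture
def table_os_params() -> HazardParams:
    """Published overall-survival estimates (constant family, per day)."""
    return HazardParams(
        family="constant", lambda0=1e-4, delta_stage=1e-4, delta_linitis=2e-4,
        beta_met=3.43,
    )


def make_patient(pid="P1", **kw) -> PatientRecord:
    defaults = dict(
        patient_id=pid, age_years=62.0, sex="male", ecog=1, tumor_site="gastric",
        location="antrum", linitis=False, lauren="diffuse", grade="poor",
        her2=False, ctnm_stage=3, treatment="CRT", dose_intensity=0.9,
        ct_n_positive=True, ypt=2, ypn=0,
    )
    defaults.update(kw)
    return PatientRecord(**defaults)


@pytest.fixture
def three_patient_cohort() -> CohortTable:
    patients = [make_patient(f"P{i}") for i in (1, 2, 3)]
    visits = [
        VisitObservation(f"P{i}", j, [0.0, 42.0, 84.0][j - 1],
                         [2, 1, 0][j - 1] if i < 3 else [2, 2, 2][j - 1])
        for i in (1, 2, 3)
        for j in (1, 2, 3)
    ]
    events = [
        EventRecord("P1", "metastasis", 300.0, True),
        EventRecord("P1", "death", 400.0, True),
        EventRecord("P2", "death", 900.0, False),
    ]
    return CohortTable.from_records(patients, visits, events)


@pytest.fixture
def small_cohort() -> CohortTable:
    """5-subject simulated fixture used for likelihood cross-checks."""
    return simulate_cohort(SimulationConfig(n_patients=5, seed=7))


@pytest.fixture
def default_cohort() -> CohortTable:
    """Study-sized (115 patient) synthetic cohort."""
    return simulate_cohort(SimulationConfig(n_patients=115, seed=42))
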