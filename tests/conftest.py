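import dataclasses
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from diastolab.cohort import Cohort, EchoMeasurements, PatientRecord
from diastolab.synthetic import GeneratorConfig, MissingnessSpec, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def small_cohort() -> Cohort:
    """Three hand-built patients with assorted missingness."""
    return Cohort(
        [
            PatientRecord(
                "P1",
                EchoMeasurements(
                    mitral_e_vel=80.0, mitral_a_vel=40.0, septal_e_prime=6.0,
                    lateral_e_prime=9.0, tr_peak_vel=3.0, la_volume_index=40.0,
                    las_r=15.0, lv_gls=14.0, lvef=60.0,
                ),
                19.0,
            ),
            PatientRecord(
                "P2",
                EchoMeasurements(
                    mitral_e_vel=45.0, mitral_a_vel=64.0, septal_e_prime=9.0,
                    lateral_e_prime=12.0, la_volume_index=25.0, las_r=30.0,
                    lv_gls=20.0, lvef=65.0,
                ),
                9.0,
            ),
            PatientRecord("P3", EchoMeasurements(mitral_e_vel=70.0), None),
        ],
        provenance="fixture",
    )


@pytest.fixture(scope="session")
def default_cohort_2k() -> Cohort:
    """One default-condition synthetic cohort, reused across tests."""
    return generate_cohort(dataclasses.replace(GeneratorConfig(), n=2000, seed=11))


@pytest.fixture(scope="session")
def complete_cohort_300() -> Cohort:
    """n=300 cohort with no missingness (basis for missingness experiments)."""
    cfg = dataclasses.replace(
        GeneratorConfig(), n=300, seed=5, missingness=MissingnessSpec(()),
    )
    return generate_cohort(cfg)
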