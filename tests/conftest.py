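import numpy as np
import pytest

from appendiscore import PatientPresentation


def make_patient(**overrides) -> PatientPresentation:
    """A fully negative baseline patient; override fields per test."""
    base = dict(
        age_years=30.0,
        sex="female",
        migratory_rif_pain=False,
        anorexia=False,
        nausea=False,
        vomiting=False,
        rif_pain=False,
        rif_tenderness=False,
        rebound_tenderness=False,
        guarding_grade="none",
        rovsing_sign=False,
        temperature_c=36.8,
        wbc_e9_per_L=7.0,
        pmn_percent=60.0,
        crp_mg_per_L=0.0,
        urinalysis_negative=False,
        symptom_duration_h=72.0,
        foreign_national=False,
    )
    base.update(overrides)
    return PatientPresentation(**base)


def random_patient(rng: np.random.Generator) -> PatientPresentation:
    """Uniformly random valid patient, independent of the cohort simulator."""
    return make_patient(
        age_years=float(rng.uniform(5, 90)),
        sex=str(rng.choice(["male", "female"])),
        migratory_rif_pain=bool(rng.integers(2)),
        anorexia=bool(rng.integers(2)),
        nausea=bool(rng.integers(2)),
        vomiting=bool(rng.integers(2)),
        rif_pain=bool(rng.integers(2)),
        rif_tenderness=bool(rng.integers(2)),
        rebound_tenderness=bool(rng.integers(2)),
        guarding_grade=str(rng.choice(["none", "light", "medium", "strong"])),
        rovsing_sign=bool(rng.integers(2)),
        temperature_c=float(rng.uniform(35, 41)),
        wbc_e9_per_L=float(rng.uniform(2, 30)),
        pmn_percent=float(rng.uniform(30, 100)),
        crp_mg_per_L=float(rng.uniform(0, 200)),
        urinalysis_negative=bool(rng.integers(2)),
        symptom_duration_h=float(rng.uniform(1, 150)),
        foreign_national=bool(rng.integers(2)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20220101)


@pytest.fixture
def full_house_patient():
    """Every scoring item present across all three systems."""
    return make_patient(
        age_years=25.0,
        sex="male",
        migratory_rif_pain=True,
        anorexia=True,
        nausea=True,
        vomiting=True,
        rif_pain=True,
        rif_tenderness=True,
        rebound_tenderness=True,
        guarding_grade="strong",
        rovsing_sign=True,
        temperature_c=38.8,
        wbc_e9_per_L=16.0,
        pmn_percent=90.0,
        crp_mg_per_L=60.0,
        urinalysis_negative=True,
        symptom_duration_h=24.0,
        foreign_national=True,
    )
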