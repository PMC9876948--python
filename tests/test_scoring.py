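"""Scoring rules: worked examples, brute-force oracle, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from appendiscore import (
    DEFAULT_CONFIG,
    Guarding,
    air_score,
    alvarado_score,
    ripasa_score,
    score_cohort,
    score_frame,
)
from appendiscore.io import cohort_to_frame
from appendiscore.scoring import air_band, alvarado_band, ripasa_band

from conftest import make_patient, random_patient


# ---------------------------------------------------------------------------
# independent oracle: a literal item-by-item transcription of the three
# weight tables, kept deliberately separate from the implementation

def oracle_alvarado(p):
    return sum([
        1 * p.migratory_rif_pain,
        1 * p.anorexia,
        1 * p.nausea,
        2 * p.rif_tenderness,
        1 * p.rebound_tenderness,
        1 * (p.temperature_c >= 37.3),
        2 * (p.wbc_e9_per_L >= 10),
        1 * (p.pmn_percent >= 75),
    ])


def oracle_air(p):
    if p.guarding_grade == Guarding.light:
        peritonism = 1
    elif p.guarding_grade == Guarding.medium:
        peritonism = 2
    elif p.guarding_grade == Guarding.strong:
        peritonism = 3
    else:
        peritonism = 1 if p.rebound_tenderness else 0
    pmn = 2 if p.pmn_percent >= 85 else (1 if p.pmn_percent >= 70 else 0)
    wbc = 2 if p.wbc_e9_per_L >= 15 else (1 if p.wbc_e9_per_L >= 10 else 0)
    crp = 2 if p.crp_mg_per_L >= 5 else (1 if p.crp_mg_per_L >= 1 else 0)
    return (
        1 * p.vomiting + 1 * p.rif_pain + peritonism
        + 1 * (p.temperature_c > 38.5) + pmn + wbc + crp
    )


def oracle_ripasa(p):
    return sum([
        1.0 if p.sex == "male" else 0.5,
        1.0 if p.age_years < 40 else 0.5,
        0.5 * p.rif_pain,
        0.5 * p.migratory_rif_pain,
        1.0 * p.anorexia,
        1.0 * (p.nausea or p.vomiting),
        1.0 if p.symptom_duration_h < 48 else 0.5,
        1.0 * p.rif_tenderness,
        2.0 * (p.guarding_grade != Guarding.none),
        1.0 * p.rebound_tenderness,
        2.0 * p.rovsing_sign,
        1.0 if 37 < p.temperature_c < 39 else 0.0,
        1.0 * (p.wbc_e9_per_L >= 10),
        1.0 * p.urinalysis_negative,
        1.0 * p.foreign_national,
    ])


# ---------------------------------------------------------------------------
# worked examples

def test_alvarado_examples(full_house_patient):
    r = alvarado_score(full_house_patient)
    assert (r.score, r.band, r.positive) == (10, "likely", True)

    r0 = alvarado_score(make_patient())
    assert (r0.score, r0.band, r0.positive) == (0, "unlikely", False)

    r4 = alvarado_score(make_patient(rif_tenderness=True, wbc_e9_per_L=12.0))
    assert (r4.score, r4.band) == (4, "unlikely")


def test_air_examples(full_house_patient):
    assert air_score(full_house_patient).score == 12

    r0 = air_score(make_patient())
    assert (r0.score, r0.band) == (0, "low")

    # vomiting + isolated rebound (light peritonism) + WBC 12 + CRP 3
    r4 = air_score(
        make_patient(vomiting=True, rebound_tenderness=True, wbc_e9_per_L=12.0, crp_mg_per_L=3.0)
    )
    assert (r4.score, r4.band, r4.positive) == (4, "low", False)


def test_ripasa_examples():
    # young male, full clinical picture, short history, not a foreign national
    r = ripasa_score(
        make_patient(
            age_years=25, sex="male", migratory_rif_pain=True, anorexia=True,
            nausea=True, vomiting=True, rif_pain=True, rif_tenderness=True,
            rebound_tenderness=True, guarding_grade="medium", rovsing_sign=True,
            temperature_c=38.0, wbc_e9_per_L=14.0, urinalysis_negative=True,
            symptom_duration_h=24,
        )
    )
    assert r.score == 15.0
    assert r.positive

    # older female, long history, nothing else: the 1.5 floor
    rmin = ripasa_score(make_patient(age_years=45, sex="female", symptom_duration_h=96))
    assert (rmin.score, rmin.band, rmin.positive) == (1.5, "unlikely", False)


def test_ripasa_boundary_7_5_is_positive_high_probability():
    # 45y female >48h (1.5) + anorexia + nausea/vomiting + tenderness +
    # rebound + guarding = 7.5 exactly
    p = make_patient(
        age_years=45, sex="female", symptom_duration_h=96, anorexia=True,
        nausea=True, rif_tenderness=True, rebound_tenderness=True,
        guarding_grade="light",
    )
    r = ripasa_score(p)
    assert r.score == 7.5
    assert r.positive
    assert r.band == "high_probability"


def test_ripasa_strict_cutoff_switch():
    p = make_patient(
        age_years=45, sex="female", symptom_duration_h=96, anorexia=True,
        nausea=True, rif_tenderness=True, rebound_tenderness=True,
        guarding_grade="light",
    )
    strict = DEFAULT_CONFIG.with_overrides(ripasa_cutoff_inclusive=False)
    assert ripasa_score(p, strict).score == 7.5
    assert not ripasa_score(p, strict).positive


def test_ripasa_fever_band_edges():
    p37 = make_patient(temperature_c=37.0)
    p_just = make_patient(temperature_c=37.01)
    p39 = make_patient(temperature_c=39.0)
    base = ripasa_score(p37).score
    assert ripasa_score(p_just).score == base + 1.0
    assert ripasa_score(p39).score == base


def test_ripasa_heating_febrile_patient_past_39_removes_one_point():
    febrile = make_patient(temperature_c=37.8, rif_tenderness=True)
    hot = make_patient(temperature_c=39.8, rif_tenderness=True)
    assert ripasa_score(febrile).score - ripasa_score(hot).score == 1.0


def test_duration_exactly_48h_takes_lower_weight():
    assert (
        ripasa_score(make_patient(symptom_duration_h=48.0)).score
        == ripasa_score(make_patient(symptom_duration_h=96.0)).score
    )


def test_scores_match_item_sum_oracle(rng):
    for _ in range(1000):
        p = random_patient(rng)
        assert alvarado_score(p).score == oracle_alvarado(p)
        assert air_score(p).score == oracle_air(p)
        assert ripasa_score(p).score == pytest.approx(oracle_ripasa(p))


def test_vectorized_frame_scoring_equals_per_record_path(rng):
    cohort = [random_patient(rng) for _ in range(300)]
    per_record = score_cohort(cohort)
    vectorized = score_frame(cohort_to_frame(cohort))
    pd.testing.assert_frame_equal(
        per_record.astype(float), vectorized.astype(float), check_like=True
    )


# ---------------------------------------------------------------------------
# invariants

def test_score_ranges_and_lattice(rng):
    lattice = set(np.arange(1.5, 16.01, 0.5).round(1))
    for _ in range(500):
        p = random_patient(rng)
        assert alvarado_score(p).score in range(11)
        assert air_score(p).score in range(13)
        assert round(ripasa_score(p).score, 1) in lattice


_FLAGS = [
    "migratory_rif_pain", "anorexia", "nausea", "vomiting", "rif_pain",
    "rif_tenderness", "rebound_tenderness", "rovsing_sign",
    "urinalysis_negative", "foreign_national",
]


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.sampled_from(_FLAGS))
def test_setting_a_flag_never_decreases_any_score(seed, flag):
    p = random_patient(np.random.default_rng(seed))
    if getattr(p, flag):
        return
    update = {flag: True}
    if flag in ("nausea", "vomiting"):
        update["nausea_or_vomiting"] = True
    flipped = p.model_copy(update=update)
    assert alvarado_score(flipped).score >= alvarado_score(p).score
    assert air_score(flipped).score >= air_score(p).score
    assert ripasa_score(flipped).score >= ripasa_score(p).score


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_raising_labs_past_thresholds_never_decreases_alvarado_or_air(seed):
    p = random_patient(np.random.default_rng(seed))
    raised = p.model_copy(
        update=dict(wbc_e9_per_L=p.wbc_e9_per_L + 6, pmn_percent=min(100.0, p.pmn_percent + 12),
                    crp_mg_per_L=p.crp_mg_per_L + 10)
    )
    assert alvarado_score(raised).score >= alvarado_score(p).score
    assert air_score(raised).score >= air_score(p).score


def test_band_assignment_is_total():
    for s in range(11):
        assert alvarado_band(s) in {"unlikely", "suspected", "likely"}
    for s in range(13):
        assert air_band(s) in {"low", "suspected", "high"}
    for s in np.arange(1.5, 16.01, 0.5):
        assert ripasa_band(float(s)) in {
            "unlikely", "low_probability", "high_probability", "diagnosis"
        }


def test_air_band_includes_the_published_gap_at_8():
    assert air_band(8) == "suspected"
    assert air_band(9) == "high"


def test_score_cohort_plumbing(rng):
    patients = [random_patient(rng) for _ in range(3)]
    out = score_cohort(patients)
    assert len(out) == 3
    assert set(out.columns) == {
        f"{s}_{k}" for s in ("alvarado", "air", "ripasa") for k in ("score", "positive")
    }
    single = score_cohort(patients[:1])
    assert len(single) == 1
    with pytest.raises(ValueError, match="empty"):
        score_cohort([])


def test_missing_field_is_an_error_not_imputed():
    from pydantic import ValidationError

    with pytest.raises(ValidationError, match="temperature_c"):
        from appendiscore import PatientPresentation

        kwargs = make_patient().model_dump()
        kwargs.pop("temperature_c")
        PatientPresentation(**kwargs)


def test_alvarado_thresholds_are_configurable():
    p = make_patient(temperature_c=37.0, wbc_e9_per_L=9.0, pmn_percent=70.0)
    assert alvarado_score(p).score == 0
    loose = DEFAULT_CONFIG.with_overrides(
        alvarado_temp_c=36.9, alvarado_wbc=8.0, alvarado_pmn_pct=65.0
    )
    assert alvarado_score(p, loose).score == 4
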