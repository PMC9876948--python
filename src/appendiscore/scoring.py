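"""The Alvarado, AIR and RIPASA clinical decision rules.

Each score is an additive rule over symptoms, signs and laboratory values:

* **Alvarado** (0-10, integers): migratory pain 1, anorexia 1, nausea 1,
  RIF tenderness 2, rebound tenderness 1, elevated temperature 1,
  leukocytosis 2, neutrophil left shift 1.
* **AIR** (0-12, integers): vomiting 1, RIF pain 1, graded peritonism
  (light 1 / medium 2 / strong 3), temperature > 38.5 °C 1, banded
  neutrophil fraction (70-84.9 % -> 1, >= 85 % -> 2), banded WBC
  (10-14.9 -> 1, >= 15 -> 2), banded CRP (1-4.9 mg/L -> 1, >= 5 -> 2).
* **RIPASA** (1.5-16.0 on a 0.5 lattice): adds demographics (sex, age),
  symptom duration, urinalysis, Rovsing's sign and foreign nationality to
  the usual symptom/sign items; fever scores only inside the open band
  (37, 39) °C.

Threshold choices the original publications leave loose (what counts as
"elevated temperature" or "leukocytosis") live in :class:`ScoringConfig`
so alternatives are testable; the defaults are the classical ones.

The study cutoffs are score > 7 (Alvarado), > 5 (AIR) and >= 7.5 (RIPASA);
7.5 itself opens the RIPASA "high probability" band, hence the inclusive
comparison there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .presentation import Guarding, PatientPresentation

__all__ = [
    "ScoringConfig",
    "DEFAULT_CONFIG",
    "ScoreResult",
    "alvarado_score",
    "air_score",
    "ripasa_score",
    "score_cohort",
    "score_frame",
    "SYSTEMS",
    "MAX_SCORE",
]

SYSTEMS = ("alvarado", "air", "ripasa")

#: Reachable score maxima (RIPASA's nominal total is sometimes printed as
#: 17.5, but with the mutually exclusive sex/age/duration categories the
#: reachable maximum is 16.0).
MAX_SCORE = {"alvarado": 10, "air": 12, "ripasa": 16.0}


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds and cutoffs; defaults match the classical definitions."""

    alvarado_temp_c: float = 37.3  # "elevated temperature"
    alvarado_wbc: float = 10.0     # leukocytosis, 1e9/L
    alvarado_pmn_pct: float = 75.0  # left shift, % neutrophils
    air_temp_c: float = 38.5
    ripasa_wbc: float = 10.0
    alvarado_cutoff: float = 7.0   # positive iff score > cutoff
    air_cutoff: float = 5.0        # positive iff score > cutoff
    ripasa_cutoff: float = 7.5
    ripasa_cutoff_inclusive: bool = True  # 7.5 itself is high-probability

    def with_overrides(self, **kw) -> "ScoringConfig":
        return replace(self, **kw)


DEFAULT_CONFIG = ScoringConfig()


@dataclass(frozen=True)
class ScoreResult:
    system: str
    score: float
    band: str
    positive: bool


# ---------------------------------------------------------------------------
# band maps — total functions over each system's reachable scores

def alvarado_band(score: float) -> str:
    if score < 5:
        return "unlikely"
    if score <= 7:
        return "suspected"
    return "likely"


def air_band(score: float) -> str:
    """Low 0-4, suspected 5-8, high 9-12.

    Published band listings for the AIR score often skip 8 ("5-7
    suspected, 9-12 high"); the original AIR definition places 8 in the
    intermediate group, which is what is implemented here.
    """
    if score <= 4:
        return "low"
    if score <= 8:
        return "suspected"
    return "high"


def ripasa_band(score: float) -> str:
    """Unlikely <5, low 5-7, high 7.5-11.5, diagnosis >=12.

    Scores live on a 0.5 lattice, so the bands partition every reachable
    value; the published 11.5-12 gap is closed upward.
    """
    if score < 5:
        return "unlikely"
    if score < 7.5:
        return "low_probability"
    if score < 12:
        return "high_probability"
    return "diagnosis"


# ---------------------------------------------------------------------------
# per-record scoring

def alvarado_score(p: PatientPresentation, config: ScoringConfig = DEFAULT_CONFIG) -> ScoreResult:
    """Alvarado score (0-10) with band and binary call at the > 7 cutoff."""
    score = (
        int(p.migratory_rif_pain)
        + int(p.anorexia)
        + int(p.nausea)
        + 2 * int(p.rif_tenderness)
        + int(p.rebound_tenderness)
        + int(p.temperature_c >= config.alvarado_temp_c)
        + 2 * int(p.wbc_e9_per_L >= config.alvarado_wbc)
        + int(p.pmn_percent >= config.alvarado_pmn_pct)
    )
    return ScoreResult("alvarado", score, alvarado_band(score), score > config.alvarado_cutoff)


_PERITONISM_POINTS = {Guarding.none: 0, Guarding.light: 1, Guarding.medium: 2, Guarding.strong: 3}


def _air_peritonism(p: PatientPresentation) -> int:
    # Graded peritonism: guarding grade dominates; isolated rebound
    # tenderness without guarding counts as the light grade (1 point).
    grade = _PERITONISM_POINTS[p.guarding_grade]
    if grade == 0 and p.rebound_tenderness:
        grade = 1
    return grade


def air_score(p: PatientPresentation, config: ScoringConfig = DEFAULT_CONFIG) -> ScoreResult:
    """AIR score (0-12) with band and binary call at the > 5 cutoff.

    Lab bands are half-open on the right so every value maps to exactly
    one band: PMN [70, 85) -> 1, [85, inf) -> 2; WBC [10, 15) -> 1,
    [15, inf) -> 2; CRP [1, 5) -> 1, [5, inf) -> 2 mg/L.
    """
    score = (
        int(p.vomiting)
        + int(p.rif_pain)
        + _air_peritonism(p)
        + int(p.temperature_c > config.air_temp_c)
        + (2 if p.pmn_percent >= 85 else 1 if p.pmn_percent >= 70 else 0)
        + (2 if p.wbc_e9_per_L >= 15 else 1 if p.wbc_e9_per_L >= 10 else 0)
        + (2 if p.crp_mg_per_L >= 5 else 1 if p.crp_mg_per_L >= 1 else 0)
    )
    return ScoreResult("air", score, air_band(score), score > config.air_cutoff)


def ripasa_score(p: PatientPresentation, config: ScoringConfig = DEFAULT_CONFIG) -> ScoreResult:
    """RIPASA score (1.5-16.0) with band and binary call at 7.5.

    The three mandatory categories (sex, age, duration) always contribute,
    so the floor is 0.5 + 0.5 + 0.5 = 1.5.  Exactly 48 h of symptoms takes
    the longer-duration weight 0.5.  Any guarding grade above none earns
    the single guarding weight 2.0.
    """
    score = (
        (1.0 if p.sex == "male" else 0.5)
        + (1.0 if p.age_years < 40 else 0.5)
        + 0.5 * p.rif_pain
        + 0.5 * p.migratory_rif_pain
        + 1.0 * p.anorexia
        + 1.0 * p.nausea_or_vomiting
        + (1.0 if p.symptom_duration_h < 48 else 0.5)
        + 1.0 * p.rif_tenderness
        + 2.0 * (p.guarding_grade is not Guarding.none)
        + 1.0 * p.rebound_tenderness
        + 2.0 * p.rovsing_sign
        + (1.0 if 37 < p.temperature_c < 39 else 0.0)
        + 1.0 * (p.wbc_e9_per_L >= config.ripasa_wbc)
        + 1.0 * p.urinalysis_negative
        + 1.0 * p.foreign_national
    )
    if config.ripasa_cutoff_inclusive:
        positive = score >= config.ripasa_cutoff
    else:
        positive = score > config.ripasa_cutoff
    return ScoreResult("ripasa", score, ripasa_band(score), positive)


_SCORERS = {"alvarado": alvarado_score, "air": air_score, "ripasa": ripasa_score}


def score_patient(p: PatientPresentation, system: str, config: ScoringConfig = DEFAULT_CONFIG) -> ScoreResult:
    return _SCORERS[system](p, config)


def score_cohort(
    cohort: Sequence[PatientPresentation] | Iterable[PatientPresentation],
    config: ScoringConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Score every patient with all three systems.

    Returns a DataFrame in input order with columns ``<system>_score`` and
    ``<system>_positive`` for each system.  Per-record validation failures
    are re-raised with the offending record index.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    rows = []
    for i, p in enumerate(cohort):
        try:
            row = {}
            for system in SYSTEMS:
                r = _SCORERS[system](p, config)
                row[f"{system}_score"] = r.score
                row[f"{system}_positive"] = r.positive
            rows.append(row)
        except Exception as exc:  # re-raise with position for CSV debugging
            raise type(exc)(f"record {i}: {exc}") from exc
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# vectorized scoring over a cohort DataFrame (same arithmetic as the
# per-record path; equivalence is property-tested)

def score_frame(df: pd.DataFrame, config: ScoringConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Vectorized scoring of a cohort DataFrame.

    `df` must carry the :class:`PatientPresentation` field names as columns
    (flags as booleans or 0/1).  Used by the simulator's calibration loop
    and the pipeline, where per-record object construction would dominate
    the run time.
    """
    b = {c: df[c].to_numpy().astype(bool) for c in (
        "migratory_rif_pain", "anorexia", "nausea", "vomiting", "rif_pain",
        "rif_tenderness", "rebound_tenderness", "rovsing_sign",
        "urinalysis_negative", "foreign_national")}
    temp = df["temperature_c"].to_numpy(float)
    wbc = df["wbc_e9_per_L"].to_numpy(float)
    pmn = df["pmn_percent"].to_numpy(float)
    crp = df["crp_mg_per_L"].to_numpy(float)
    age = df["age_years"].to_numpy(float)
    dur = df["symptom_duration_h"].to_numpy(float)
    male = df["sex"].to_numpy() == "male"
    guard = df["guarding_grade"].map({"none": 0, "light": 1, "medium": 2, "strong": 3}).to_numpy(int)
    if "nausea_or_vomiting" in df.columns and df["nausea_or_vomiting"].notna().all():
        nv = df["nausea_or_vomiting"].to_numpy().astype(bool)
    else:
        nv = b["nausea"] | b["vomiting"]

    alvarado = (
        b["migratory_rif_pain"].astype(int) + b["anorexia"] + b["nausea"]
        + 2 * b["rif_tenderness"] + b["rebound_tenderness"]
        + (temp >= config.alvarado_temp_c)
        + 2 * (wbc >= config.alvarado_wbc)
        + (pmn >= config.alvarado_pmn_pct)
    )

    peritonism = np.where(guard > 0, guard, b["rebound_tenderness"].astype(int))
    air = (
        b["vomiting"].astype(int) + b["rif_pain"] + peritonism
        + (temp > config.air_temp_c)
        + np.select([pmn >= 85, pmn >= 70], [2, 1], 0)
        + np.select([wbc >= 15, wbc >= 10], [2, 1], 0)
        + np.select([crp >= 5, crp >= 1], [2, 1], 0)
    )

    ripasa = (
        np.where(male, 1.0, 0.5)
        + np.where(age < 40, 1.0, 0.5)
        + 0.5 * b["rif_pain"] + 0.5 * b["migratory_rif_pain"]
        + 1.0 * b["anorexia"] + 1.0 * nv
        + np.where(dur < 48, 1.0, 0.5)
        + 1.0 * b["rif_tenderness"] + 2.0 * (guard > 0)
        + 1.0 * b["rebound_tenderness"] + 2.0 * b["rovsing_sign"]
        + ((temp > 37) & (temp < 39))
        + (wbc >= config.ripasa_wbc)
        + 1.0 * b["urinalysis_negative"] + 1.0 * b["foreign_national"]
    )

    if config.ripasa_cutoff_inclusive:
        ripasa_pos = ripasa >= config.ripasa_cutoff - 1e-9
    else:
        ripasa_pos = ripasa > config.ripasa_cutoff + 1e-9
    return pd.DataFrame(
        {
            "alvarado_score": alvarado.astype(int),
            "air_score": air.astype(int),
            "ripasa_score": ripasa,
            "alvarado_positive": alvarado > config.alvarado_cutoff,
            "air_positive": air > config.air_cutoff,
            "ripasa_positive": ripasa_pos,
        },
        index=df.index,
    )
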