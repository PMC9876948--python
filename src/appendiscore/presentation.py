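"""Patient-level clinical record used by all three appendicitis scores.

A :class:`PatientPresentation` carries every symptom, sign and laboratory
value that any of the Alvarado, AIR or RIPASA scores consumes, plus the
histopathology label that serves as the diagnostic gold standard in an
appendectomy cohort.  Validation is strict: scores are clinical decision
rules, so a missing or out-of-range field is an error, never something to
impute silently.
"""

from __future__ import annotations

import enum
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class Guarding(str, enum.Enum):
    """Graded muscular defense on abdominal examination."""

    none = "none"
    light = "light"
    medium = "medium"
    strong = "strong"


class Histopathology(str, enum.Enum):
    """Specimen classification after appendectomy.

    ``negative`` is the "negative appendectomy": a removed appendix with no
    appendicitis on histology — the false-positive outcome of operating on
    the clinical picture alone.
    """

    acute_inflamed = "acute_inflamed"
    gangrenous = "gangrenous"
    perforated = "perforated"
    negative = "negative"

    @property
    def disease_positive(self) -> bool:
        return self is not Histopathology.negative


class PatientPresentation(BaseModel):
    """One patient's feature vector at presentation.

    Units: temperature in degrees Celsius, white-cell count in 1e9 cells/L,
    polymorphonuclear (neutrophil) fraction in percent, CRP in mg/L,
    symptom duration in hours.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    age_years: float = Field(gt=0)
    sex: Literal["male", "female"]
    migratory_rif_pain: bool
    anorexia: bool
    nausea: bool
    vomiting: bool
    nausea_or_vomiting: Optional[bool] = None  # derived from nausea/vomiting if omitted
    rif_pain: bool
    rif_tenderness: bool
    rebound_tenderness: bool
    guarding_grade: Guarding
    rovsing_sign: bool
    temperature_c: float = Field(ge=30, le=45)
    wbc_e9_per_L: float = Field(ge=0)
    pmn_percent: float = Field(ge=0, le=100)
    crp_mg_per_L: float = Field(ge=0)
    urinalysis_negative: bool
    symptom_duration_h: float = Field(gt=0)
    foreign_national: bool
    histopathology: Optional[Histopathology] = None

    @model_validator(mode="after")
    def _derive_nausea_or_vomiting(self) -> "PatientPresentation":
        derived = self.nausea or self.vomiting
        if self.nausea_or_vomiting is None:
            object.__setattr__(self, "nausea_or_vomiting", derived)
        elif self.nausea_or_vomiting != derived:
            raise ValueError(
                "nausea_or_vomiting inconsistent with nausea/vomiting flags"
            )
        return self

    @property
    def disease_positive(self) -> Optional[bool]:
        """Histopathology-confirmed appendicitis, or None when unlabeled."""
        if self.histopathology is None:
            return None
        return self.histopathology.disease_positive


#: Column order for cohort CSVs; header names are exactly the field names.
FIELD_ORDER: tuple[str, ...] = tuple(PatientPresentation.model_fields)

BOOL_FIELDS: tuple[str, ...] = tuple(
    name
    for name, f in PatientPresentation.model_fields.items()
    if f.annotation in (bool, Optional[bool])
)
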