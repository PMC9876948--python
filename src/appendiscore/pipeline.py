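"""End-to-end study pipeline: score a cohort, evaluate, report.

`run_study` reproduces the shape of a score-comparison study on any
labeled cohort: per-system confusion matrix and accuracy metrics at the
study cutoffs, ROC/AUC, pairwise AUC differences (seeded paired
bootstrap), pairwise Pearson correlation of the raw scores, histology
breakdown and negative-appendectomy rate.  All percentages are stored at
full precision with display rounding applied only at render time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd

from . import diagnostics as dx
from .errors import DegenerateInputError
from .io import cohort_to_frame
from .presentation import PatientPresentation
from .rounding import round_half_up
from .scoring import DEFAULT_CONFIG, SYSTEMS, ScoringConfig, score_frame

__all__ = ["RunConfig", "run_study", "report_to_json"]

logger = logging.getLogger("appendiscore")

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration: scoring thresholds/cutoffs plus evaluation
    settings (bootstrap replication count and seed, rounding dialect used
    for display)."""

    scoring: ScoringConfig = field(default_factory=lambda: DEFAULT_CONFIG)
    bootstrap_reps: int = 2000
    seed: int = 0
    rounding_dialect: str = "half_up"

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _as_frame(cohort: Union[pd.DataFrame, Sequence[PatientPresentation]]) -> pd.DataFrame:
    if isinstance(cohort, pd.DataFrame):
        return cohort
    return cohort_to_frame(list(cohort))


def run_study(
    cohort: Union[pd.DataFrame, Sequence[PatientPresentation]],
    config: Optional[RunConfig] = None,
) -> dict:
    """Score and evaluate a labeled cohort; returns the study report dict.

    Requires histopathology labels with both outcome classes present.
    Deterministic given cohort + config (the bootstrap is seeded).
    """
    config = config or RunConfig()
    df = _as_frame(cohort)
    if "histopathology" not in df.columns or df["histopathology"].isna().any():
        raise ValueError("run_study requires histopathology labels for every patient")
    labels = dx.disease_labels(df["histopathology"])
    if labels.all() or not labels.any():
        raise DegenerateInputError("cohort must contain both outcome classes")
    n = len(df)
    logger.info("run_study: n=%d seed=%d config=%s", n, config.seed, config.digest())

    scored = score_frame(df, config.scoring)
    histo_counts = df["histopathology"].value_counts().to_dict()

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "config_digest": config.digest(),
        "seed": config.seed,
        "n": n,
        "n_disease_positive": int(labels.sum()),
        "n_disease_negative": int((~labels).sum()),
        "negative_appendectomy_rate_pct": 100.0 * float((~labels).mean()),
        "histology_breakdown": {k: int(v) for k, v in sorted(histo_counts.items())},
        "systems": {},
        "auc_differences": {},
        "pearson_correlations": {},
    }

    for system in SYSTEMS:
        scores = scored[f"{system}_score"].to_numpy(float)
        calls = scored[f"{system}_positive"].to_numpy(bool)
        cm = dx.confusion_matrix(calls, labels)
        auc = dx.roc_auc(scores, labels)
        summary = dx.diagnostic_metrics(cm, auc=auc)
        report["systems"][system] = {
            "confusion_matrix": cm.as_dict(),
            "n_positive_calls": int(calls.sum()),
            "metrics": summary.as_dict(),
            "metrics_display": summary.rounded(),
            "score_mean": float(scores.mean()),
            "score_sd": float(scores.std(ddof=1)),
        }

    pairs = [("alvarado", "air"), ("alvarado", "ripasa"), ("air", "ripasa")]
    for a, b in pairs:
        sa = scored[f"{a}_score"].to_numpy(float)
        sb = scored[f"{b}_score"].to_numpy(float)
        diff = dx.auc_difference(
            sa, sb, labels, n_boot=config.bootstrap_reps, seed=config.seed
        )
        report["auc_differences"][f"{b}_minus_{a}"] = diff.as_dict()
        report["pearson_correlations"][f"{a}_vs_{b}"] = dx.pearson_r(sa, sb)

    return report


def report_to_json(report: dict, dialect_decimals: int = 6) -> str:
    """Canonical JSON rendering of a study report (sorted keys, fixed
    float precision) so identical inputs yield byte-identical files."""

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, float):
            return round_half_up(obj, dialect_decimals)
        return obj

    return json.dumps(clean(report), indent=2, sort_keys=True)
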