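"""Diagnostic test accuracy: 2x2 tables, summary metrics, ROC/AUC, correlation.

All metrics are computed against the histopathology gold standard
(disease-positive = any specimen other than a negative appendectomy).
Percentages are held at full precision internally; display rounding
(half-up, one decimal for percentages and two for ratios) is applied only
when a summary is rendered, so rounding ambiguity never propagates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError
from .presentation import Histopathology
from .rounding import round_half_up

__all__ = [
    "ConfusionMatrix",
    "DiagnosticSummary",
    "confusion_matrix",
    "diagnostic_metrics",
    "roc_curve",
    "roc_auc",
    "AucDifference",
    "auc_difference",
    "pearson_r",
    "disease_labels",
]


def disease_labels(histopathology: Sequence) -> np.ndarray:
    """Binary disease vector from histopathology labels (negative
    appendectomy -> 0, any appendicitis -> 1)."""
    return np.array(
        [Histopathology(h).disease_positive for h in histopathology], dtype=bool
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        """Disease-positive column total."""
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


def confusion_matrix(calls: Sequence, labels: Sequence) -> ConfusionMatrix:
    """Cross-tabulate binary test calls against binary disease labels."""
    calls = np.asarray(calls).astype(bool)
    labels = np.asarray(labels).astype(bool)
    if calls.shape != labels.shape or calls.ndim != 1:
        raise ValueError(
            f"calls and labels must be equal-length 1-D vectors, got {calls.shape} vs {labels.shape}"
        )
    if calls.size == 0:
        raise ValueError("empty input")
    return ConfusionMatrix(
        tp=int(np.sum(calls & labels)),
        fp=int(np.sum(calls & ~labels)),
        fn=int(np.sum(~calls & labels)),
        tn=int(np.sum(~calls & ~labels)),
    )


@dataclass(frozen=True)
class DiagnosticSummary:
    """The eight accuracy summaries, percentages on the 0-100 scale.

    A metric whose denominator is empty (e.g. PPV with no positive calls,
    PLR at specificity 1) is ``None`` and listed in ``undefined`` — never
    silently infinite.
    """

    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: float
    plr: Optional[float]
    nlr: Optional[float]
    auc: Optional[float] = None
    undefined: tuple[str, ...] = field(default=())

    def rounded(self) -> dict:
        """Display form: half-up, 1 dp for percentages, 2 dp for ratios,
        3 dp for AUC."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, name)
            out[name] = None if v is None else round_half_up(v, 1)
        for name in ("plr", "nlr"):
            v = getattr(self, name)
            out[name] = None if v is None else round_half_up(v, 2)
        out["auc"] = None if self.auc is None else round_half_up(self.auc, 3)
        return out

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "plr": self.plr,
            "nlr": self.nlr,
            "auc": self.auc,
            "undefined": list(self.undefined),
        }


def diagnostic_metrics(cm: ConfusionMatrix, auc: Optional[float] = None) -> DiagnosticSummary:
    """Sensitivity, specificity, PPV, NPV, accuracy (all %), PLR, NLR.

    Requires at least one disease-positive and one disease-negative
    subject; other empty denominators yield ``None`` entries.
    """
    if cm.n_pos < 1 or cm.n_neg < 1:
        raise DegenerateInputError(
            "need at least one disease-positive and one disease-negative subject"
        )
    sens = cm.tp / cm.n_pos
    spec = cm.tn / cm.n_neg
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    ppv = ratio(cm.tp, cm.tp + cm.fp, "ppv")
    npv = ratio(cm.tn, cm.tn + cm.fn, "npv")
    plr = ratio(sens, 1 - spec, "plr")
    nlr = ratio(1 - sens, spec, "nlr")
    return DiagnosticSummary(
        sensitivity=100 * sens,
        specificity=100 * spec,
        ppv=None if ppv is None else 100 * ppv,
        npv=None if npv is None else 100 * npv,
        accuracy=100 * (cm.tp + cm.tn) / cm.n,
        plr=plr,
        nlr=nlr,
        auc=auc,
        undefined=tuple(undefined),
    )


# ---------------------------------------------------------------------------
# ROC / AUC

def _validate_roc_input(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    if labels.all() or not labels.any():
        raise DegenerateInputError("ROC requires both disease classes present")
    return scores, labels


def roc_curve(scores: Sequence[float], labels: Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical ROC over all distinct score thresholds.

    Returns (fpr, tpr, thresholds); the curve starts at (0, 0) and ends at
    (1, 1).  A call is positive when score >= threshold.
    """
    scores, labels = _validate_roc_input(scores, labels)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # last index of each tie group
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tps / y.sum()]
    fpr = np.r_[0.0, fps / (~y).sum()]
    thresholds = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thresholds


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Area under the empirical ROC curve by the trapezoid rule.

    Equals the Mann-Whitney probability that a random diseased patient
    outscores a random non-diseased one, ties counted half.
    """
    fpr, tpr, _ = roc_curve(scores, labels)
    return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class AucDifference:
    delta: float
    auc_a: float
    auc_b: float
    ci: Optional[tuple[float, float]] = None
    n_boot: int = 0

    def as_dict(self) -> dict:
        return {
            "delta": self.delta,
            "auc_a": self.auc_a,
            "auc_b": self.auc_b,
            "ci": None if self.ci is None else list(self.ci),
            "n_boot": self.n_boot,
        }


def auc_difference(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence,
    n_boot: int = 0,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> AucDifference:
    """AUC(B) - AUC(A) on the same patients, optionally with a seeded
    paired-bootstrap percentile interval.

    Resamples patients with replacement, recomputing both AUCs on each
    resample; draws that lose one disease class are redrawn.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("paired comparison needs equal-length vectors")
    auc_a = roc_auc(scores_a, labels)
    auc_b = roc_auc(scores_b, labels)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = labels.size
        deltas = np.empty(n_boot)
        k = 0
        while k < n_boot:
            idx = rng.integers(0, n, size=n)
            yb = labels[idx]
            if yb.all() or not yb.any():
                continue
            deltas[k] = roc_auc(scores_b[idx], yb) - roc_auc(scores_a[idx], yb)
            k += 1
        lo, hi = np.quantile(deltas, [alpha / 2, 1 - alpha / 2])
        ci = (float(lo), float(hi))
    return AucDifference(delta=auc_b - auc_a, auc_a=auc_a, auc_b=auc_b, ci=ci, n_boot=n_boot)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation between two score vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in one of the inputs")
    return float(stats.pearsonr(x, y).statistic)
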