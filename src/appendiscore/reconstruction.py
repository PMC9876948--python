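"""Recover integer confusion matrices behind published rounded metrics.

A diagnostic-accuracy table typically prints sensitivity and specificity
to one decimal together with the cohort's column totals (here 121
histopathology-positive and 11 negative appendectomies).  Because the
underlying cell counts are small integers, an exhaustive search over all
(tp, tn) pairs usually pins down the exact 2x2 table — and once the table
is recovered, every other printed cell (PPV, NPV, likelihood ratios,
accuracy) can be recomputed and checked for internal consistency at its
own printed precision.  This is the same granularity logic as GRIM-style
checks of published means, applied to 2x2 tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .diagnostics import ConfusionMatrix, diagnostic_metrics
from .errors import ImpossibleRowError
from .rounding import ROUNDERS, printed_decimals, round_half_up

__all__ = [
    "ReportedRow",
    "MetricVerdict",
    "AuditReport",
    "reconstruct_matrix",
    "audit_row",
    "reference_rows",
]

#: metrics a row may optionally report, with their value scale
_OPTIONAL_METRICS = ("ppv", "npv", "accuracy", "plr", "nlr")
_DEFAULT_DECIMALS = {"ppv": 1, "npv": 1, "accuracy": 1, "plr": 2, "nlr": 2}


@dataclass(frozen=True)
class _Printed:
    """A printed numeric cell, keeping its display precision ("25" is a
    0-decimal print, "78.03" a 2-decimal one)."""

    text: str

    @property
    def value(self) -> float:
        return float(self.text)

    @property
    def decimals(self) -> int:
        return printed_decimals(self.text)

    @property
    def scaled(self) -> int:
        """Value in integer units of the last printed digit."""
        return round(self.value * 10**self.decimals)


def _printed(value, default_decimals: Optional[int] = None) -> Optional[_Printed]:
    if value is None:
        return None
    if isinstance(value, _Printed):
        return value
    if isinstance(value, str):
        return _Printed(value.strip())
    # numeric input: fall back to the conventional precision for the cell
    nd = 1 if default_decimals is None else default_decimals
    return _Printed(f"{float(value):.{nd}f}")


@dataclass(frozen=True)
class ReportedRow:
    """One published table row: system, cutoff, printed metrics, marginals.

    Printed values are best given as strings so their display precision is
    preserved; floats are accepted and assumed to carry the conventional
    precision (1 decimal for percentages, 2 for ratios).
    """

    system: str
    cutoff: str
    sensitivity: str | float
    specificity: str | float
    n_pos: int
    n_neg: int
    ppv: Optional[str | float] = None
    npv: Optional[str | float] = None
    accuracy: Optional[str | float] = None
    plr: Optional[str | float] = None
    nlr: Optional[str | float] = None

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("marginals n_pos and n_neg must be >= 1")
        object.__setattr__(self, "sensitivity", _printed(self.sensitivity))
        object.__setattr__(self, "specificity", _printed(self.specificity))
        for m in _OPTIONAL_METRICS:
            object.__setattr__(self, m, _printed(getattr(self, m), _DEFAULT_DECIMALS[m]))
        for cell in (self.sensitivity, self.specificity):
            if not 0 <= cell.value <= 100:
                raise ValueError(f"percentage out of range: {cell.text}")


def _matching_counts(printed: _Printed, total: int) -> np.ndarray:
    """All integer numerators k in 0..total whose percentage k/total
    rounds (half-up) to the printed value at its printed precision."""
    k = np.arange(total + 1)
    pct = 100.0 * k / total
    scale = 10**printed.decimals
    rounded = np.floor(pct * scale + 0.5 + 1e-9).astype(np.int64)
    return k[rounded == printed.scaled]


def reconstruct_matrix(row: ReportedRow) -> list[ConfusionMatrix]:
    """Every confusion matrix on the row's marginals whose sensitivity and
    specificity reproduce the printed values; exhaustive by construction.

    Raises :class:`ImpossibleRowError` when no matrix qualifies — the
    printed row is then internally inconsistent with its marginals.
    """
    tps = _matching_counts(row.sensitivity, row.n_pos)
    tns = _matching_counts(row.specificity, row.n_neg)
    out = [
        ConfusionMatrix(tp=int(tp), fp=int(row.n_neg - tn), fn=int(row.n_pos - tp), tn=int(tn))
        for tp in tps
        for tn in tns
    ]
    if not out:
        raise ImpossibleRowError(
            f"no {row.n_pos}x{row.n_neg} matrix yields sensitivity "
            f"{row.sensitivity.text} and specificity {row.specificity.text}"
        )
    return out


@dataclass(frozen=True)
class MetricVerdict:
    """Consistency verdict for one printed cell against the best candidate.

    ``delta`` is reported at the cell's display precision (half-up dialect);
    ``rounded`` maps every rounding dialect to the recomputed display value,
    so a truncated print is distinguishable from a half-up one.
    """

    metric: str
    reported: float
    computed: float          # full precision, best candidate
    rounded: dict            # dialect -> display value
    delta: float             # rounded[half_up] - reported
    verdict: str             # match | near_miss | impossible

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "reported": self.reported,
            "computed": self.computed,
            "rounded": dict(self.rounded),
            "delta": self.delta,
            "verdict": self.verdict,
        }


@dataclass(frozen=True)
class AuditReport:
    row: ReportedRow
    candidates: tuple[ConfusionMatrix, ...]
    unique: bool
    verdicts: tuple[MetricVerdict, ...] = field(default=())

    @property
    def all_match(self) -> bool:
        return all(v.verdict == "match" for v in self.verdicts)

    def as_dict(self) -> dict:
        return {
            "system": self.row.system,
            "cutoff": self.row.cutoff,
            "n_pos": self.row.n_pos,
            "n_neg": self.row.n_neg,
            "candidates": [c.as_dict() for c in self.candidates],
            "unique": self.unique,
            "verdicts": [v.as_dict() for v in self.verdicts],
        }


def _metric_value(summary, name: str) -> Optional[float]:
    return getattr(summary, name)


def audit_row(row: ReportedRow, near_miss_units: int = 2) -> AuditReport:
    """Reconstruct the row's matrix and check every optionally printed cell.

    For each reported metric the verdict is, against the candidate matrix
    that comes closest at the cell's printed precision:

    * ``match``     — recomputed value rounds (half-up) to the printed one;
    * ``near_miss`` — off by at most `near_miss_units` units in the last
      printed digit (a plausible rounding-dialect discrepancy);
    * ``impossible``— further off than that: the printed cell cannot come
      from any matrix consistent with the printed sensitivity/specificity.
    """
    candidates = reconstruct_matrix(row)
    summaries = [diagnostic_metrics(c) for c in candidates]
    verdicts = []
    for name in _OPTIONAL_METRICS:
        cell = getattr(row, name)
        if cell is None:
            continue
        nd = cell.decimals
        unit = 10.0**-nd
        best = None
        for s in summaries:
            value = _metric_value(s, name)
            if value is None:
                continue
            display = round_half_up(value, nd)
            delta = round_half_up(display - cell.value, nd)
            if best is None or abs(delta) < abs(best[1]):
                best = (value, delta)
        if best is None:
            verdicts.append(
                MetricVerdict(name, cell.value, float("nan"), {}, float("nan"), "impossible")
            )
            continue
        value, delta = best
        verdict = (
            "match"
            if delta == 0
            else "near_miss"
            if abs(delta) <= near_miss_units * unit + 1e-12
            else "impossible"
        )
        verdicts.append(
            MetricVerdict(
                metric=name,
                reported=cell.value,
                computed=value,
                rounded={d: f(value, nd) for d, f in ROUNDERS.items()},
                delta=delta,
                verdict=verdict,
            )
        )
    return AuditReport(
        row=row,
        candidates=tuple(candidates),
        unique=len(candidates) == 1,
        verdicts=tuple(verdicts),
    )


def reference_rows() -> tuple[int, int, list[ReportedRow]]:
    """The bundled published comparison rows for the three scores in a
    132-patient appendectomy cohort (121 histopathology-positive, 11
    negative), as printed: (n_pos, n_neg, rows)."""
    raw = json.loads(
        resources.files("appendiscore").joinpath("data/reference_rows.json").read_text()
    )
    rows = [
        ReportedRow(n_pos=raw["n_pos"], n_neg=raw["n_neg"], **r) for r in raw["rows"]
    ]
    return raw["n_pos"], raw["n_neg"], rows
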