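"""Diagnostic-accuracy and agreement statistics for binary screening rules.

Centred on the 2x2 confusion matrix of a rule against a reference diagnosis:
sensitivity, specificity, predictive values, Cohen's kappa and AUC (for a
binary rule, the area under the two-segment ROC equals (Se+Sp)/2).

Because raw respondent-level data behind published validation studies are
often not deposited, :func:`reconstruct_confusion` rebuilds the 2x2 table
from the published cohort size, case count and sensitivity/specificity —
rounding to the nearest whole respondent — so that every downstream metric
(PPV, NPV, kappa, AUC) can be recomputed and checked against printed values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ConfusionMatrix",
    "DiagnosticReport",
    "UndefinedMetricError",
    "confusion_from_labels",
    "reconstruct_confusion",
    "diagnostic_report",
    "agreement_kappa",
    "kappa_from_confusion",
    "roc_and_optimal_cutoff",
    "ROCResult",
    "wald_or_ci",
    "report_frame",
    "format_report",
    "write_reports",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's defining ratio has a zero denominator (degenerate margin)."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a binary rule against a binary reference diagnosis."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn

    @property
    def n_positive(self) -> int:
        """Number of rule-positive respondents."""
        return self.tp + self.fp

    @property
    def n_negative(self) -> int:
        return self.fn + self.tn

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


@dataclass(frozen=True)
class DiagnosticReport:
    """Se/Sp/PPV/NPV as proportions, plus Cohen's kappa and binary-rule AUC.

    Metrics whose defining margin is degenerate (e.g. PPV with no positive
    calls) are NaN and listed in ``undefined`` — never a silent 0/0.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    kappa: float
    auc: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "kappa": self.kappa,
            "auc": self.auc,
            "undefined": list(self.undefined),
        }


def confusion_from_labels(
    predictions: Sequence[bool], reference: Sequence[bool]
) -> ConfusionMatrix:
    """Tally a rule's predictions against reference diagnoses."""
    pred = np.asarray(predictions, dtype=bool)
    ref = np.asarray(reference, dtype=bool)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError(
            f"predictions and reference must be equal-length 1-d sequences, "
            f"got shapes {pred.shape} and {ref.shape}"
        )
    if pred.size == 0:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    return ConfusionMatrix(
        tp=int(np.sum(pred & ref)),
        fp=int(np.sum(pred & ~ref)),
        fn=int(np.sum(~pred & ref)),
        tn=int(np.sum(~pred & ~ref)),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def reconstruct_confusion(
    n_total: int, n_diseased: int, sensitivity: float, specificity: float
) -> ConfusionMatrix:
    """Rebuild the 2x2 table from published cohort counts and Se/Sp.

    ``tp = round(Se * n_diseased)`` and ``tn = round(Sp * (n_total -
    n_diseased))`` with half-up rounding; fn and fp follow by complement.
    Recomputed Se/Sp agree with the inputs to within half a count.
    """
    if not 0 < n_diseased < n_total:
        raise ValueError(
            f"need 0 < n_diseased < n_total, got {n_diseased} of {n_total}"
        )
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    n_healthy = n_total - n_diseased
    tp = _round_half_up(sensitivity * n_diseased)
    tn = _round_half_up(specificity * n_healthy)
    return ConfusionMatrix(tp=tp, fp=n_healthy - tn, fn=n_diseased - tp, tn=tn)


def kappa_from_confusion(cm: ConfusionMatrix) -> float:
    """Cohen's kappa of rule vs reference from the 2x2 table margins.

    When expected agreement is 1 (both margins fully concentrated on the
    same category, which forces observed agreement 1) kappa is taken as 1.
    """
    n = cm.total
    po = (cm.tp + cm.tn) / n
    pe = (cm.n_positive * cm.n_diseased + cm.n_negative * cm.n_healthy) / n**2
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def diagnostic_report(cm: ConfusionMatrix) -> DiagnosticReport:
    """All identification metrics of one rule from its confusion matrix."""
    undefined: list[str] = []

    def ratio(name: str, num: int, den: int) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    se = ratio("sensitivity", cm.tp, cm.n_diseased)
    sp = ratio("specificity", cm.tn, cm.n_healthy)
    ppv = ratio("ppv", cm.tp, cm.n_positive)
    npv = ratio("npv", cm.tn, cm.n_negative)
    kappa = kappa_from_confusion(cm)
    if math.isnan(se) or math.isnan(sp):
        undefined.append("auc")
        auc = math.nan
    else:
        auc = (se + sp) / 2.0
    return DiagnosticReport(
        sensitivity=se,
        specificity=sp,
        ppv=ppv,
        npv=npv,
        kappa=kappa,
        auc=auc,
        undefined=tuple(undefined),
    )


def agreement_kappa(pred_a: Sequence[bool], pred_b: Sequence[bool]) -> float:
    """Cohen's kappa between two binary classifications (no reference needed).

    Symmetric in its arguments and invariant under relabelling of the
    positive class.
    """
    a = np.asarray(pred_a, dtype=bool)
    b = np.asarray(pred_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("the two prediction vectors must have equal length")
    if a.size == 0:
        raise ValueError("cannot compute agreement on empty inputs")
    # reuse the 2x2 formula with b playing the role of the reference
    cm = confusion_from_labels(a, b)
    return kappa_from_confusion(cm)


@dataclass(frozen=True)
class ROCResult:
    """ROC points (as produced over distinct score thresholds), the
    Youden-optimal cutoff for a strict ``score > cutoff`` test, and AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    cutoff: float
    auc: float
    youden: float


def roc_and_optimal_cutoff(
    scores: Sequence[float], reference: Sequence[bool]
) -> ROCResult:
    """ROC analysis of a continuous score with Youden-index cutoff selection.

    The cutoff is chosen for a strict ``score > cutoff`` classification from
    the midpoints between consecutive distinct scores (plus one candidate
    below the minimum), maximising the Youden index Se+Sp-1; ties are broken
    toward the lowest qualifying cutoff, favouring sensitivity.  AUC is the
    trapezoidal area under the ROC points.
    """
    from sklearn.metrics import auc as _auc
    from sklearn.metrics import roc_curve

    s = np.asarray(scores, dtype=float)
    y = np.asarray(reference, dtype=bool)
    if s.shape != y.shape or s.ndim != 1 or s.size == 0:
        raise ValueError("scores and reference must be equal-length 1-d sequences")
    if y.all() or not y.any():
        raise ValueError("reference must contain both classes for ROC analysis")

    fpr, tpr, thresholds = roc_curve(y, s)
    auc_value = float(_auc(fpr, tpr))

    uniq = np.unique(s)
    candidates = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0])
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    best_cutoff = candidates[0]
    best_j = -np.inf
    for c in candidates:
        called = s > c
        se = np.sum(called & y) / n_pos
        sp = np.sum(~called & ~y) / n_neg
        j = se + sp - 1.0
        if j > best_j:  # strict: ties keep the lowest qualifying cutoff
            best_j = j
            best_cutoff = c
    return ROCResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        cutoff=float(best_cutoff),
        auc=auc_value,
        youden=float(best_j),
    )


def wald_or_ci(
    beta: float, se: float, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Odds ratio exp(beta) with its Wald confidence interval.

    Returns ``(OR, lower, upper)`` where the bounds are
    ``exp(beta ± z·se)`` for the two-sided normal quantile z.
    """
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    z = norm.ppf((1.0 + confidence) / 2.0)
    return (math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se))


# ---------------------------------------------------------------------------
# Report writing (one row per rule, published column order)
# ---------------------------------------------------------------------------


def format_report(report: DiagnosticReport) -> dict:
    """Report at the customary printed precision: percentages to 1 decimal,
    kappa and AUC to 2 decimals.  Undefined metrics render as None."""

    def pct(x: float):
        return None if math.isnan(x) else round(100.0 * x, 1)

    def two(x: float):
        return None if math.isnan(x) else round(x, 2)

    return {
        "sensitivity_pct": pct(report.sensitivity),
        "specificity_pct": pct(report.specificity),
        "ppv_pct": pct(report.ppv),
        "npv_pct": pct(report.npv),
        "kappa": two(report.kappa),
        "auc": two(report.auc),
    }


def report_frame(reports: Mapping[str, DiagnosticReport]) -> pd.DataFrame:
    """One formatted row per rule, in the standard column order."""
    rows = [{"rule": name, **format_report(rep)} for name, rep in reports.items()]
    return pd.DataFrame(
        rows,
        columns=[
            "rule",
            "sensitivity_pct",
            "specificity_pct",
            "ppv_pct",
            "npv_pct",
            "kappa",
            "auc",
        ],
    )


def write_reports(
    reports: Mapping[str, DiagnosticReport],
    csv_path=None,
    json_path=None,
) -> pd.DataFrame:
    """Write per-rule report rows as CSV and/or JSON; returns the frame."""
    import json as _json

    frame = report_frame(reports)
    if csv_path is not None:
        frame.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            _json.dump(frame.to_dict(orient="records"), fh, indent=2)
    return frame
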