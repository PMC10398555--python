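"""Sample-size planning for diagnostic-accuracy and prevalence surveys.

Two standard designs are covered:

* **Accuracy validation** — how many subjects are needed to estimate a
  screening test's sensitivity (or specificity) to within a tolerance ``d``
  at a given confidence, when the disease prevalence in the recruited
  population is ``p``:

      n_Se = z² · Se·(1−Se) / (d² · p)
      n_Sp = z² · Sp·(1−Sp) / (d² · (1−p))

  The prevalence denominator inflates the overall n so that the diseased
  (respectively non-diseased) subgroup alone reaches the precision target.

* **Prevalence survey** — the single-proportion formula with a variance
  design effect D for non-ideal (e.g. convenience) sampling:

      n = D · z² · p·(1−p) / d²

All results are rounded up (a fractional subject is always an extra
subject).  :func:`recruitment_target` additionally inflates a required
analysed sample for anticipated data loss: a fraction of unqualified
(unreliable/excluded) questionnaires and a nonresponse rate, applied
multiplicatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "AccuracyDesign",
    "PrevalenceDesign",
    "n_for_sensitivity",
    "n_for_specificity",
    "n_for_prevalence",
    "recruitment_target",
    "accuracy_plan",
    "prevalence_plan",
]


def _check_open_unit(name: str, value: float) -> None:
    if not 0.0 < value < 1.0:
        raise ValueError(f"{name} must lie strictly in (0, 1), got {value}")


@dataclass(frozen=True)
class AccuracyDesign:
    """Planning inputs for a sensitivity/specificity validation study."""

    expected_sensitivity: float
    expected_specificity: float
    expected_prevalence: float
    tolerance_d: float = 0.10
    confidence: float = 0.95

    def __post_init__(self) -> None:
        for name in (
            "expected_sensitivity",
            "expected_specificity",
            "expected_prevalence",
            "tolerance_d",
            "confidence",
        ):
            _check_open_unit(name, getattr(self, name))


@dataclass(frozen=True)
class PrevalenceDesign:
    """Planning inputs for a prevalence survey with design effect and
    anticipated data loss."""

    expected_prevalence: float
    tolerance_d: float = 0.05
    confidence: float = 0.95
    design_effect: float = 1.0
    unqualified_ratio: float = 0.0
    nonresponse_rate: float = 0.0

    def __post_init__(self) -> None:
        _check_open_unit("expected_prevalence", self.expected_prevalence)
        _check_open_unit("tolerance_d", self.tolerance_d)
        _check_open_unit("confidence", self.confidence)
        if self.design_effect < 1.0:
            raise ValueError(
                f"design_effect must be >= 1, got {self.design_effect}"
            )
        for name in ("unqualified_ratio", "nonresponse_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {v}")


def _z(confidence: float) -> float:
    return float(norm.ppf((1.0 + confidence) / 2.0))


def _ceil(x: float) -> int:
    # guard against float noise pushing an exact integer over the edge
    return int(math.ceil(round(x, 9)))


def n_for_sensitivity(design: AccuracyDesign) -> int:
    """Minimum analysed sample size driven by the sensitivity target."""
    z = _z(design.confidence)
    se = design.expected_sensitivity
    return _ceil(
        z**2 * se * (1.0 - se)
        / (design.tolerance_d**2 * design.expected_prevalence)
    )


def n_for_specificity(design: AccuracyDesign) -> int:
    """Minimum analysed sample size driven by the specificity target."""
    z = _z(design.confidence)
    sp = design.expected_specificity
    return _ceil(
        z**2 * sp * (1.0 - sp)
        / (design.tolerance_d**2 * (1.0 - design.expected_prevalence))
    )


def n_for_prevalence(design: PrevalenceDesign) -> int:
    """Minimum analysed sample size for the prevalence survey."""
    z = _z(design.confidence)
    p = design.expected_prevalence
    return _ceil(
        design.design_effect * z**2 * p * (1.0 - p) / design.tolerance_d**2
    )


def recruitment_target(
    n_required: int, unqualified_ratio: float, nonresponse_rate: float
) -> int:
    """Recruitment count needed so that, after nonresponse and unqualified
    questionnaires, the analysed sample still reaches ``n_required``.

    The two loss factors apply multiplicatively:
    ``ceil(n / ((1−unqualified)·(1−nonresponse)))``; never below
    ``n_required``.
    """
    if n_required < 0:
        raise ValueError("n_required must be non-negative")
    for name, v in (
        ("unqualified_ratio", unqualified_ratio),
        ("nonresponse_rate", nonresponse_rate),
    ):
        if not 0.0 <= v < 1.0:
            raise ValueError(f"{name} must lie in [0, 1), got {v}")
    n = _ceil(n_required / ((1.0 - unqualified_ratio) * (1.0 - nonresponse_rate)))
    return max(n, n_required)


def accuracy_plan(design: AccuracyDesign) -> dict:
    """Required n per accuracy criterion plus the binding (maximum) n."""
    n_se = n_for_sensitivity(design)
    n_sp = n_for_specificity(design)
    return {
        "n_sensitivity": n_se,
        "n_specificity": n_sp,
        "n_required": max(n_se, n_sp),
    }


def prevalence_plan(design: PrevalenceDesign) -> dict:
    """Required analysed n and the loss-inflated recruitment target."""
    n = n_for_prevalence(design)
    return {
        "n_prevalence": n,
        "recruitment_target": recruitment_target(
            n, design.unqualified_ratio, design.nonresponse_rate
        ),
    }
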