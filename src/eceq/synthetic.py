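"""Synthetic respondent cohorts with a latent disease state.

Real questionnaire exports from screening surveys are rarely deposited, so
this module generates cohorts whose answer patterns are statistically
calibrated: a latent atopic-dermatitis state is drawn at a configurable
prevalence, and the seven boolean answers follow either

* a **conditional-independence model** — per-question probabilities
  ``P(Q_i = yes | state)``, with the logical implication Q5 → Q6 enforced
  (a site affected within the last week was affected within the last six
  months); or
* an **explicit pattern table** — a probability distribution over all 128
  answer patterns per disease state, which is what :func:`calibrate`
  produces when asked to hit published rule-level sensitivities/
  specificities and answer marginals exactly.

Operating characteristics of any screening rule under a model are available
analytically (pattern probabilities dotted with the rule's truth table), so
calibration never relies on sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .rules import (
    N_QUESTIONS,
    ScreeningRule,
    get_rule,
    truth_table_array,
)

__all__ = [
    "CohortModel",
    "CalibrationError",
    "CalibrationResult",
    "generate",
    "operating_characteristics",
    "analytic_marginals",
    "pattern_probabilities",
    "calibrate",
    "inject_survey_noise",
    "N_PATTERNS",
]

N_PATTERNS = 2 ** N_QUESTIONS

#: question membership per pattern: _HAS_Q[i, j] is true when pattern j
#: answers question i+1 with yes (pattern order matches rules.all_patterns)
_HAS_Q = np.array(
    [
        [(j >> (N_QUESTIONS - 1 - i)) & 1 == 1 for j in range(N_PATTERNS)]
        for i in range(N_QUESTIONS)
    ],
    dtype=bool,
)

#: patterns violating the Q5 → Q6 implication (lesions within a week but
#: not within six months)
_Q5_WITHOUT_Q6 = _HAS_Q[4] & ~_HAS_Q[5]


def pattern_probabilities(conditional_probs: Sequence[float]) -> np.ndarray:
    """Pattern distribution implied by per-question yes-probabilities.

    Questions are independent given the disease state except for the
    Q5 → Q6 implication: Q5 is drawn only when Q6 is yes, with conditional
    probability ``min(1, p5/p6)``, so the Q5 marginal is ``min(p5, p6)``.
    """
    p = np.asarray(conditional_probs, dtype=float)
    if p.shape != (N_QUESTIONS,):
        raise ValueError(f"expected {N_QUESTIONS} probabilities, got shape {p.shape}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    p5_given_q6 = min(1.0, p[4] / p[5]) if p[5] > 0 else 0.0
    out = np.ones(N_PATTERNS)
    for i in range(N_QUESTIONS):
        if i == 4:
            continue
        out *= np.where(_HAS_Q[i], p[i], 1.0 - p[i])
    q5_term = np.where(
        _HAS_Q[5],
        np.where(_HAS_Q[4], p5_given_q6, 1.0 - p5_given_q6),
        np.where(_HAS_Q[4], 0.0, 1.0),
    )
    out *= q5_term
    return out


@dataclass(frozen=True)
class CohortModel:
    """Generative specification for a synthetic cohort.

    Exactly one answer model must be given: per-state conditional
    probabilities (``diseased_probs``/``healthy_probs``, seven values each)
    or per-state pattern tables (``diseased_patterns``/``healthy_patterns``,
    128 values each summing to one).

    ``awareness_given_disease`` drives the optional caregiver-awareness
    flag: a caregiver of a diseased child is aware of possible atopic
    dermatitis with this probability (the flag is independent of the
    answers given the disease state).
    """

    n: int
    prevalence: float
    seed: int = 0
    diseased_probs: Optional[tuple[float, ...]] = None
    healthy_probs: Optional[tuple[float, ...]] = None
    diseased_patterns: Optional[tuple[float, ...]] = None
    healthy_patterns: Optional[tuple[float, ...]] = None
    awareness_given_disease: float = 0.061
    age_range_months: tuple[float, float] = (0.0, 24.0)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"cohort size must be non-negative, got {self.n}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must lie in [0, 1], got {self.prevalence}")
        cond = self.diseased_probs is not None or self.healthy_probs is not None
        patt = self.diseased_patterns is not None or self.healthy_patterns is not None
        if cond == patt:
            raise ValueError(
                "specify exactly one answer model: conditional probabilities "
                "or pattern tables"
            )
        if cond:
            for name in ("diseased_probs", "healthy_probs"):
                v = getattr(self, name)
                if v is None:
                    raise ValueError(f"{name} is required in conditional mode")
                object.__setattr__(self, name, tuple(float(x) for x in v))
                pattern_probabilities(getattr(self, name))  # validates
        else:
            for name in ("diseased_patterns", "healthy_patterns"):
                v = getattr(self, name)
                if v is None:
                    raise ValueError(f"{name} is required in pattern mode")
                arr = np.asarray(v, dtype=float)
                if arr.shape != (N_PATTERNS,):
                    raise ValueError(
                        f"{name} must have {N_PATTERNS} entries, got {arr.shape}"
                    )
                if np.any(arr < -1e-12) or not math.isclose(
                    arr.sum(), 1.0, abs_tol=1e-6
                ):
                    raise ValueError(f"{name} must be a probability distribution")
                object.__setattr__(self, name, tuple(np.clip(arr, 0.0, None)))
        if not 0.0 <= self.awareness_given_disease <= 1.0:
            raise ValueError("awareness_given_disease must lie in [0, 1]")

    def pattern_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-state pattern distributions (diseased, healthy)."""
        if self.diseased_probs is not None:
            return (
                pattern_probabilities(self.diseased_probs),
                pattern_probabilities(self.healthy_probs),
            )
        d = np.asarray(self.diseased_patterns, dtype=float)
        h = np.asarray(self.healthy_patterns, dtype=float)
        return d / d.sum(), h / h.sum()

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "prevalence": self.prevalence,
            "seed": self.seed,
            "diseased_probs": list(self.diseased_probs) if self.diseased_probs else None,
            "healthy_probs": list(self.healthy_probs) if self.healthy_probs else None,
            "diseased_patterns": list(self.diseased_patterns)
            if self.diseased_patterns
            else None,
            "healthy_patterns": list(self.healthy_patterns)
            if self.healthy_patterns
            else None,
            "awareness_given_disease": self.awareness_given_disease,
            "age_range_months": list(self.age_range_months),
        }


def operating_characteristics(
    model: CohortModel, rule: Union[str, ScreeningRule]
) -> tuple[float, float]:
    """Exact (analytic) sensitivity and specificity of a rule under a model."""
    positive = truth_table_array(get_rule(rule))
    table_d, table_h = model.pattern_tables()
    return float(table_d @ positive), float(table_h @ ~positive)


def analytic_marginals(model: CohortModel) -> np.ndarray:
    """Overall per-question yes-probabilities implied by the model."""
    table_d, table_h = model.pattern_tables()
    overall = model.prevalence * table_d + (1.0 - model.prevalence) * table_h
    return _HAS_Q @ overall


def generate(model: CohortModel) -> pd.DataFrame:
    """Draw a cohort of raw survey records from a model.

    Records come back in the pipeline's input layout with clean metadata
    (matching repeat answers, good self-evaluated quality, unique device
    ids); :func:`inject_survey_noise` degrades them realistically.  The
    reference diagnosis column equals the latent disease state.  Same seed,
    same cohort, byte for byte.
    """
    rng = np.random.default_rng(model.seed)
    n = model.n
    diseased = rng.random(n) < model.prevalence

    table_d, table_h = model.pattern_tables()
    patterns = np.empty(n, dtype=np.int64)
    if diseased.any():
        patterns[diseased] = rng.choice(
            N_PATTERNS, size=int(diseased.sum()), p=table_d
        )
    if (~diseased).any():
        patterns[~diseased] = rng.choice(
            N_PATTERNS, size=int((~diseased).sum()), p=table_h
        )

    lo, hi = model.age_range_months
    # rounding to 0.1 months must not push an age onto the exclusive upper
    # bound (the cleaning flow drops children at or above it)
    ages = np.clip(np.round(rng.uniform(lo, hi, size=n), 1), lo, hi - 0.1)
    df = pd.DataFrame(
        {
            "respondent_id": [f"r{i:06d}" for i in range(n)],
            "age_months": ages,
            "sex": rng.choice(["male", "female"], size=n),
        }
    )
    for i in range(N_QUESTIONS):
        df[f"q{i + 1}"] = _HAS_Q[i][patterns]
    df["device_id"] = [f"dev{i:06d}" for i in range(n)]
    df["ip_address"] = [
        f"10.{i // 65536 % 256}.{i // 256 % 256}.{i % 256}" for i in range(n)
    ]
    df["repeat_first"] = "blue"
    df["repeat_last"] = "blue"
    df["self_quality"] = "good"
    df["excluded_condition"] = False
    df["reference_diagnosis"] = diseased
    df["aware_of_ad"] = diseased & (
        rng.random(n) < model.awareness_given_disease
    )
    return df


class CalibrationError(ValueError):
    """Requested targets cannot be met; carries the best-found residuals."""

    def __init__(self, message: str, achieved: dict, residuals: dict):
        super().__init__(message)
        self.achieved = achieved
        self.residuals = residuals


@dataclass(frozen=True)
class CalibrationResult:
    """A calibrated pattern-table model plus its achieved target values."""

    model: CohortModel
    achieved: dict
    max_residual: float


def calibrate(
    targets: Mapping[Union[str, ScreeningRule], tuple[float, float]],
    n: int,
    prevalence: float,
    marginals: Optional[Sequence[float]] = None,
    seed: int = 0,
    tol: float = 0.01,
    enforce_q5_implication: bool = False,
) -> CalibrationResult:
    """Find a pattern-table model matching rule-level Se/Sp targets.

    ``targets`` maps rules (objects or preset names) to ``(sensitivity,
    specificity)`` pairs; ``marginals`` optionally adds per-question overall
    yes-frequencies (length 7).  All targets are linear functionals of the
    two per-state pattern distributions, so the fit is a bounded linear
    least-squares on the product of two simplices; achieved values are
    recomputed analytically and each must sit within ``tol`` of its target,
    otherwise a :class:`CalibrationError` reports the best-found residuals.

    Unlike the independence generator, calibration does *not* enforce the
    Q5 → Q6 implication by default: real survey answers violate it (a
    week-only rule can have more false positives than its six-month
    counterpart, which is impossible under the implication), and published
    joint targets can be unreachable with it switched on.
    """
    resolved = {get_rule(r): (float(se), float(sp)) for r, (se, sp) in targets.items()}
    if not resolved:
        raise ValueError("at least one rule target is required")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly in (0, 1) for calibration")

    rows: list[np.ndarray] = []
    rhs: list[float] = []
    labels: list[str] = []

    for rule, (se, sp) in resolved.items():
        mask = truth_table_array(rule).astype(float)
        rows.append(np.concatenate([mask, np.zeros(N_PATTERNS)]))
        rhs.append(se)
        labels.append(f"{rule.name}:sensitivity")
        rows.append(np.concatenate([np.zeros(N_PATTERNS), 1.0 - mask]))
        rhs.append(sp)
        labels.append(f"{rule.name}:specificity")

    if marginals is not None:
        marg = np.asarray(marginals, dtype=float)
        if marg.shape != (N_QUESTIONS,):
            raise ValueError(f"marginals must have length {N_QUESTIONS}")
        for i in range(N_QUESTIONS):
            has = _HAS_Q[i].astype(float)
            rows.append(np.concatenate([prevalence * has, (1 - prevalence) * has]))
            rhs.append(marg[i])
            labels.append(f"q{i + 1}:marginal")

    # soft simplex constraints, heavily weighted; blocks renormalised after
    weight = 1000.0
    rows.append(weight * np.concatenate([np.ones(N_PATTERNS), np.zeros(N_PATTERNS)]))
    rhs.append(weight)
    labels.append("_sum_diseased")
    rows.append(weight * np.concatenate([np.zeros(N_PATTERNS), np.ones(N_PATTERNS)]))
    rhs.append(weight)
    labels.append("_sum_healthy")

    # implication-violating patterns are excluded from the problem entirely
    active = np.ones(2 * N_PATTERNS, dtype=bool)
    if enforce_q5_implication:
        active[:N_PATTERNS][_Q5_WITHOUT_Q6] = False
        active[N_PATTERNS:][_Q5_WITHOUT_Q6] = False

    matrix = np.vstack(rows)[:, active]
    fit = lsq_linear(matrix, np.array(rhs), bounds=(0.0, 1.0), tol=1e-12)
    x = np.zeros(2 * N_PATTERNS)
    x[active] = fit.x
    table_d = x[:N_PATTERNS]
    table_h = x[N_PATTERNS:]
    table_d = table_d / table_d.sum()
    table_h = table_h / table_h.sum()

    model = CohortModel(
        n=n,
        prevalence=prevalence,
        seed=seed,
        diseased_patterns=tuple(table_d),
        healthy_patterns=tuple(table_h),
    )

    achieved: dict[str, float] = {}
    residuals: dict[str, float] = {}
    for rule, (se, sp) in resolved.items():
        a_se, a_sp = operating_characteristics(model, rule)
        achieved[f"{rule.name}:sensitivity"] = a_se
        achieved[f"{rule.name}:specificity"] = a_sp
        residuals[f"{rule.name}:sensitivity"] = abs(a_se - se)
        residuals[f"{rule.name}:specificity"] = abs(a_sp - sp)
    if marginals is not None:
        model_marg = analytic_marginals(model)
        for i in range(N_QUESTIONS):
            achieved[f"q{i + 1}:marginal"] = float(model_marg[i])
            residuals[f"q{i + 1}:marginal"] = abs(model_marg[i] - marg[i])

    max_residual = max(residuals.values())
    if max_residual > tol:
        worst = max(residuals, key=residuals.get)
        raise CalibrationError(
            f"calibration infeasible: residual {max_residual:.4f} on {worst} "
            f"exceeds tolerance {tol}",
            achieved=achieved,
            residuals=residuals,
        )
    return CalibrationResult(model=model, achieved=achieved, max_residual=max_residual)


def inject_survey_noise(
    records: pd.DataFrame,
    unqualified_ratio: float = 0.0,
    nonresponse_rate: float = 0.0,
    duplicate_ratio: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Degrade a clean cohort the way a real web survey would.

    Drops each record with probability ``nonresponse_rate``; corrupts the
    repeated-question check of a ``unqualified_ratio`` fraction of the
    remainder; and appends near-clones (same device, address and
    demographics, fresh respondent id) for a ``duplicate_ratio`` fraction.
    Deterministic per seed; all ratios zero returns an identical copy.
    """
    for name, v in (
        ("unqualified_ratio", unqualified_ratio),
        ("nonresponse_rate", nonresponse_rate),
        ("duplicate_ratio", duplicate_ratio),
    ):
        if not 0.0 <= v < 1.0:
            raise ValueError(f"{name} must lie in [0, 1), got {v}")
    rng = np.random.default_rng(seed)
    df = records.copy().reset_index(drop=True)

    if nonresponse_rate > 0:
        df = df.loc[rng.random(len(df)) >= nonresponse_rate].reset_index(drop=True)
    if unqualified_ratio > 0 and len(df):
        corrupt = rng.random(len(df)) < unqualified_ratio
        df.loc[corrupt, "repeat_last"] = (
            df.loc[corrupt, "repeat_first"].astype(str) + "_mismatch"
        )
    if duplicate_ratio > 0 and len(df):
        clone = df.loc[rng.random(len(df)) < duplicate_ratio].copy()
        clone["respondent_id"] = clone["respondent_id"].astype(str) + "-dup"
        df = pd.concat([df, clone], ignore_index=True)
    return df
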