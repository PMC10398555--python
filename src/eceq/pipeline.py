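"""Survey-export cleaning, cohort classification and awareness analysis.

The expected input is a CSV export with one row per respondent and the
following columns (boolean fields accept ``1/0``, ``true/false`` or
``yes/no`` in any case):

========================  =====================================================
column                    meaning
========================  =====================================================
respondent_id             unique identifier after cleaning
age_months                age at response, in months
sex                       ``male``/``female`` (free category, used for
                          duplicate detection only)
q1..q7                    the seven questionnaire answers
device_id, ip_address     opaque strings used for duplicate detection
repeat_first,             the reliability check question asked twice; the two
repeat_last               values must agree
self_quality              self-evaluated response quality; ``poor``/``low``/
                          ``bad`` fail the reliability check
excluded_condition        true when an excluding comorbidity is reported
                          (autoimmune disease, immunodeficiency, severe
                          malnutrition, ...)
reference_diagnosis       optional: dermatologist's diagnosis (validation)
aware_of_ad               optional: caregiver aware of possible atopic
                          dermatitis (awareness analysis)
========================  =====================================================

Cleaning removes records in a fixed stage order — exact duplicates,
reliability failures, over-age children, excluded conditions — so every
record lands in exactly one bucket of the :class:`CleaningReport`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .diagnostics import DiagnosticReport, confusion_from_labels, diagnostic_report
from .rules import (
    N_QUESTIONS,
    ScreeningRule,
    get_rule,
    truth_table_array,
)

__all__ = [
    "ANSWER_COLUMNS",
    "REQUIRED_COLUMNS",
    "CleaningReport",
    "AwarenessCascade",
    "read_cohort",
    "write_cohort",
    "clean",
    "classify_cohort",
    "awareness_cascade",
    "validate_against_reference",
]

ANSWER_COLUMNS = [f"q{i}" for i in range(1, N_QUESTIONS + 1)]
REQUIRED_COLUMNS = [
    "respondent_id",
    "age_months",
    "sex",
    *ANSWER_COLUMNS,
    "device_id",
    "ip_address",
    "repeat_first",
    "repeat_last",
    "self_quality",
    "excluded_condition",
]
OPTIONAL_COLUMNS = ["reference_diagnosis", "aware_of_ad"]

#: Columns whose joint equality marks an exact duplicate submission
#: (device, network address, and basic demographics all identical).
DUPLICATE_KEY = ["device_id", "ip_address", "age_months", "sex"]

_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f"}
_LOW_QUALITY = {"poor", "low", "bad"}


def _coerce_bool(value) -> Optional[bool]:
    """Parse a boolean-ish cell; None for missing; ValueError if unparseable."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        if value in (0, 1):
            return bool(value)
        raise ValueError(f"not a boolean value: {value!r}")
    token = str(value).strip().lower()
    if token == "" or token == "nan":
        return None
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ValueError(f"not a boolean value: {value!r}")


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort CSV, checking that all required columns are present."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns: {missing}")
    return df


def write_cohort(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class CleaningReport:
    """Per-stage accounting of the exclusion flow (each record counted once)."""

    received: int
    unparseable: int
    duplicates_removed: int
    reliability_removed: int
    over_age_removed: int
    condition_removed: int
    retained: int
    partial_duplicate_flags: int = 0

    def __post_init__(self) -> None:
        removed = (
            self.unparseable
            + self.duplicates_removed
            + self.reliability_removed
            + self.over_age_removed
            + self.condition_removed
        )
        if self.received != removed + self.retained:
            raise ValueError(
                f"cleaning report does not balance: received {self.received}, "
                f"removed {removed}, retained {self.retained}"
            )
        if min(
            self.received,
            self.unparseable,
            self.duplicates_removed,
            self.reliability_removed,
            self.over_age_removed,
            self.condition_removed,
            self.retained,
        ) < 0:
            raise ValueError("cleaning report counts must be non-negative")

    def as_dict(self) -> dict[str, int]:
        return {
            "received": self.received,
            "unparseable": self.unparseable,
            "duplicates_removed": self.duplicates_removed,
            "reliability_removed": self.reliability_removed,
            "over_age_removed": self.over_age_removed,
            "condition_removed": self.condition_removed,
            "retained": self.retained,
            "partial_duplicate_flags": self.partial_duplicate_flags,
        }


def clean(
    records: pd.DataFrame, max_age_months: float = 24.0
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the exclusion flow and return (retained records, report).

    Stages, in order (a record is counted in the first stage that removes
    it): unparseable fields → exact duplicates (first occurrence kept) →
    reliability failures (repeat-question mismatch, poor self-evaluated
    quality, or any missing answer) → age at or above ``max_age_months`` →
    excluded medical conditions.  Retained records come back with answer and
    flag columns coerced to real booleans.  Partial duplicates (same device
    and address but different demographics) are flagged in the report but
    retained.
    """
    df = records.copy().reset_index(drop=True)
    received = len(df)
    if received == 0:
        empty = df.reindex(columns=list(df.columns))
        return empty, CleaningReport(0, 0, 0, 0, 0, 0, 0)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input is missing required columns: {missing}")

    bool_columns = ANSWER_COLUMNS + ["excluded_condition"] + [
        c for c in OPTIONAL_COLUMNS if c in df.columns
    ]

    # stage 0: structurally malformed records
    parsed: dict[str, list] = {c: [] for c in bool_columns}
    ages: list[float] = []
    unparseable_mask = np.zeros(received, dtype=bool)
    for i, row in df.iterrows():
        row_bad = False
        age = pd.to_numeric(pd.Series([row["age_months"]]), errors="coerce").iloc[0]
        if pd.isna(age) or age < 0:
            row_bad = True
        ages.append(float(age) if not pd.isna(age) else math.nan)
        for c in bool_columns:
            try:
                parsed[c].append(_coerce_bool(row[c]))
            except ValueError:
                parsed[c].append(None)
                row_bad = True
        unparseable_mask[i] = row_bad
    df["age_months"] = ages
    for c in bool_columns:
        df[c] = pd.array(parsed[c], dtype="boolean")

    stage = np.full(received, "", dtype=object)
    stage[unparseable_mask] = "unparseable"
    alive = ~unparseable_mask

    # stage 1: exact duplicates (device + address + demographics all equal)
    dup = df.loc[alive].duplicated(subset=DUPLICATE_KEY, keep="first").reindex(
        df.index, fill_value=False
    )
    stage[alive & dup.to_numpy()] = "duplicate"
    alive &= ~dup.to_numpy()

    # partial duplicates: same device+address, different demographics — flag only
    partial = (
        df.loc[alive].duplicated(subset=["device_id", "ip_address"], keep="first")
        & ~df.loc[alive].duplicated(subset=DUPLICATE_KEY, keep="first")
    )
    partial_flags = int(partial.sum())

    # stage 2: reliability failures
    repeat_mismatch = (
        df["repeat_first"].astype(str).str.strip().str.lower()
        != df["repeat_last"].astype(str).str.strip().str.lower()
    )
    poor_quality = (
        df["self_quality"].astype(str).str.strip().str.lower().isin(_LOW_QUALITY)
    )
    missing_answers = np.zeros(received, dtype=bool)
    for c in ANSWER_COLUMNS:
        missing_answers |= df[c].isna().to_numpy()
    unreliable = repeat_mismatch.to_numpy() | poor_quality.to_numpy() | missing_answers
    stage[alive & unreliable] = "reliability"
    alive &= ~unreliable

    # stage 3: age filter — strictly younger than max_age_months is retained
    over_age = df["age_months"].to_numpy() >= max_age_months
    stage[alive & over_age] = "age"
    alive &= ~over_age

    # stage 4: excluded medical conditions
    condition = df["excluded_condition"].fillna(False).to_numpy(dtype=bool)
    stage[alive & condition] = "condition"
    alive &= ~condition

    retained = df.loc[alive].copy()
    for c in ANSWER_COLUMNS:
        retained[c] = retained[c].astype(bool)
    retained["excluded_condition"] = retained["excluded_condition"].astype(bool)
    retained = retained.reset_index(drop=True)

    report = CleaningReport(
        received=received,
        unparseable=int(np.sum(stage == "unparseable")),
        duplicates_removed=int(np.sum(stage == "duplicate")),
        reliability_removed=int(np.sum(stage == "reliability")),
        over_age_removed=int(np.sum(stage == "age")),
        condition_removed=int(np.sum(stage == "condition")),
        retained=int(alive.sum()),
        partial_duplicate_flags=partial_flags,
    )
    return retained, report


def _pattern_indices(df: pd.DataFrame) -> np.ndarray:
    idx = np.zeros(len(df), dtype=np.int64)
    for i, c in enumerate(ANSWER_COLUMNS):
        col = df[c]
        if col.isna().any():
            bad = df.loc[col.isna(), "respondent_id"].tolist()
            raise ValueError(f"records with missing answer {c}: {bad[:10]}")
        idx |= col.to_numpy(dtype=bool).astype(np.int64) << (N_QUESTIONS - 1 - i)
    return idx


def classify_cohort(
    records: pd.DataFrame, rule: Union[str, ScreeningRule]
) -> tuple[pd.Series, float]:
    """Classify every (cleaned) record with a rule.

    Returns the per-record boolean labels (aligned with the input index) and
    the identified prevalence ``positives/total`` (NaN for an empty cohort).
    Records with any missing answer raise, naming the offending ids.
    """
    rule = get_rule(rule)
    if len(records) == 0:
        return pd.Series([], dtype=bool, name=rule.name), math.nan
    table = truth_table_array(rule)
    labels = pd.Series(
        table[_pattern_indices(records)], index=records.index, name=rule.name
    )
    return labels, float(labels.mean())


@dataclass(frozen=True)
class AwarenessCascade:
    """Breakdown of rule-identified cases by diagnosis and caregiver awareness.

    ``previously_diagnosed + not_diagnosed = identified``;
    ``aware + unaware = not_diagnosed``;
    ``unaware_with_recent_lesions <= unaware``.  When the awareness flag is
    absent the cascade is truncated below the diagnosis split
    (``truncated_at = 'awareness'`` and the lower counts are None).
    """

    identified: int
    previously_diagnosed: int
    not_diagnosed: int
    aware: Optional[int] = None
    unaware: Optional[int] = None
    unaware_with_recent_lesions: Optional[int] = None
    truncated_at: Optional[str] = None

    def __post_init__(self) -> None:
        if self.previously_diagnosed + self.not_diagnosed != self.identified:
            raise ValueError("diagnosed + not diagnosed must equal identified")
        if self.truncated_at is None:
            if self.aware is None or self.unaware is None:
                raise ValueError("untruncated cascade needs awareness counts")
            if self.aware + self.unaware != self.not_diagnosed:
                raise ValueError("aware + unaware must equal not diagnosed")
            if (
                self.unaware_with_recent_lesions is not None
                and self.unaware_with_recent_lesions > self.unaware
            ):
                raise ValueError("recent-lesion count cannot exceed unaware count")

    @staticmethod
    def _pct(num: Optional[int], den: Optional[int]) -> Optional[float]:
        if num is None or den is None or den == 0:
            return None
        return round(100.0 * num / den, 1)

    @property
    def pct_previously_diagnosed(self) -> Optional[float]:
        return self._pct(self.previously_diagnosed, self.identified)

    @property
    def pct_aware(self) -> Optional[float]:
        return self._pct(self.aware, self.not_diagnosed)

    @property
    def pct_recent_lesions(self) -> Optional[float]:
        return self._pct(self.unaware_with_recent_lesions, self.unaware)

    def as_dict(self) -> dict:
        return {
            "identified": self.identified,
            "previously_diagnosed": self.previously_diagnosed,
            "not_diagnosed": self.not_diagnosed,
            "aware": self.aware,
            "unaware": self.unaware,
            "unaware_with_recent_lesions": self.unaware_with_recent_lesions,
            "pct_previously_diagnosed": self.pct_previously_diagnosed,
            "pct_aware": self.pct_aware,
            "pct_recent_lesions": self.pct_recent_lesions,
            "truncated_at": self.truncated_at,
        }


def awareness_cascade(
    records: pd.DataFrame, classifications: Sequence[bool]
) -> AwarenessCascade:
    """Build the awareness cascade from classified records.

    Identified cases split into previously diagnosed (Q7 yes) versus not;
    the undiagnosed split by the caregiver-awareness flag; and the unaware
    stratum is profiled for recent lesions (Q5 yes).
    """
    labels = np.asarray(classifications, dtype=bool)
    if len(labels) != len(records):
        raise ValueError("classifications must align with records")
    identified_df = records.loc[labels]
    identified = len(identified_df)
    previously = int(identified_df["q7"].astype(bool).sum()) if identified else 0
    not_diagnosed_df = identified_df.loc[~identified_df["q7"].astype(bool)] if identified else identified_df
    not_diagnosed = identified - previously

    has_awareness = (
        "aware_of_ad" in records.columns
        and not (not_diagnosed > 0 and not_diagnosed_df["aware_of_ad"].isna().all())
    )
    if not has_awareness:
        return AwarenessCascade(
            identified=identified,
            previously_diagnosed=previously,
            not_diagnosed=not_diagnosed,
            truncated_at="awareness",
        )

    aware_flags = not_diagnosed_df["aware_of_ad"]
    if aware_flags.isna().any():
        bad = not_diagnosed_df.loc[aware_flags.isna(), "respondent_id"].tolist()
        raise ValueError(f"records with missing awareness flag: {bad[:10]}")
    aware = int(aware_flags.astype(bool).sum())
    unaware_df = not_diagnosed_df.loc[~aware_flags.astype(bool)]
    unaware = not_diagnosed - aware
    lesions = int(unaware_df["q5"].astype(bool).sum())
    return AwarenessCascade(
        identified=identified,
        previously_diagnosed=previously,
        not_diagnosed=not_diagnosed,
        aware=aware,
        unaware=unaware,
        unaware_with_recent_lesions=lesions,
    )


def validate_against_reference(
    records: pd.DataFrame, rule: Union[str, ScreeningRule]
) -> DiagnosticReport:
    """Diagnostic-accuracy report of a rule against the reference diagnosis.

    Every record must carry a ``reference_diagnosis``; degenerate margins
    (e.g. an all-positive reference) surface as NaN metrics listed in the
    report's ``undefined`` field.
    """
    if "reference_diagnosis" not in records.columns:
        raise ValueError("records carry no reference_diagnosis column")
    ref = records["reference_diagnosis"]
    if ref.isna().any():
        bad = records.loc[ref.isna(), "respondent_id"].tolist()
        raise ValueError(f"records with missing reference diagnosis: {bad[:10]}")
    labels, _ = classify_cohort(records, rule)
    cm = confusion_from_labels(labels.to_numpy(), ref.to_numpy(dtype=bool))
    return diagnostic_report(cm)
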