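"""Shared fixtures: raw-record builders and the validation-cohort model."""

from __future__ import annotations

import pandas as pd
import pytest

from eceq import synthetic

# Published phase-1 validation-cohort characteristics used across tests:
# 195 analysed questionnaires, 148 dermatologist-diagnosed cases, per-rule
# sensitivity/specificity and per-question yes-frequencies.
PHASE1_N = 195
PHASE1_DISEASED = 148
PHASE1_PREVALENCE = PHASE1_DISEASED / PHASE1_N
PHASE1_RULE_TARGETS = {
    "rule1": (0.804, 0.851),
    "rule2": (0.811, 0.915),
    "rule3": (0.892, 0.915),
    "rule4": (0.905, 0.894),
}
PHASE1_MARGINALS = [0.595, 0.867, 0.574, 0.785, 0.831, 0.831, 0.364]


def make_record(respondent_id: str = "r0", **overrides) -> dict:
    """One complete, clean raw survey record with overridable fields."""
    record = {
        "respondent_id": respondent_id,
        "age_months": 8.0,
        "sex": "female",
        "q1": False,
        "q2": True,
        "q3": False,
        "q4": True,
        "q5": False,
        "q6": True,
        "q7": False,
        "device_id": f"dev-{respondent_id}",
        "ip_address": f"10.0.0.{abs(hash(respondent_id)) % 250}",
        "repeat_first": "blue",
        "repeat_last": "blue",
        "self_quality": "good",
        "excluded_condition": False,
    }
    record.update(overrides)
    return record


def make_cohort(records: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(records)


@pytest.fixture(scope="session")
def phase1_calibration() -> synthetic.CalibrationResult:
    """Pattern-table model calibrated to the validation cohort's boolean-rule
    operating characteristics and answer marginals."""
    return synthetic.calibrate(
        {name: PHASE1_RULE_TARGETS[name] for name in ("rule1", "rule2", "rule3")},
        n=10_000,
        prevalence=PHASE1_PREVALENCE,
        marginals=PHASE1_MARGINALS,
        seed=20_001,
    )
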