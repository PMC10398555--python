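"""End-to-end runs: configuration, orchestration and report bundles.

A :class:`RunConfig` fully determines a run — rule choice, cleaning
thresholds, input source (CSV file or simulation settings) and seed — and
:func:`run_end_to_end` executes clean → classify → validate/cascade and
returns (optionally writes) a machine-readable report bundle stamped with
the seed and a hash of the canonical configuration, so identical configs
provably produce identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import diagnostics, pipeline, rules, synthetic

__all__ = ["RunConfig", "run_end_to_end", "resolve_rule", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; round-trips losslessly through JSON."""

    rule: str = "rule3"
    rule_file: Optional[str] = None
    intercept: str = "equation"  # logistic-score intercept variant
    cutoff: float = rules.RULE4_CUTOFF
    strict: bool = True
    max_age_months: float = 24.0
    input_csv: Optional[str] = None
    simulate: Optional[dict] = None  # CohortModel keyword arguments
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intercept not in ("equation", "table"):
            raise ValueError(
                f"intercept variant must be 'equation' or 'table', got "
                f"{self.intercept!r}"
            )
        if self.rule_file is None:
            rules.get_rule(self.rule)  # unknown names rejected at load time
        if self.input_csv is None and self.simulate is None:
            raise ValueError("config needs an input_csv or simulate settings")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def resolve_rule(config: RunConfig) -> rules.ScreeningRule:
    """Materialise the configured rule, applying logistic-score overrides."""
    if config.rule_file is not None:
        return rules.load_rule(config.rule_file)
    rule = rules.get_rule(config.rule)
    if isinstance(rule, rules.LogisticRule):
        intercept = (
            rules.RULE4_INTERCEPT_TABLE
            if config.intercept == "table"
            else rules.RULE4_INTERCEPT_EQUATION
        )
        rule = dataclasses.replace(
            rule, intercept=intercept, cutoff=config.cutoff, strict=config.strict
        )
    return rule


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _load_records(config: RunConfig) -> pd.DataFrame:
    if config.input_csv is not None:
        return pipeline.read_cohort(config.input_csv)
    settings = dict(config.simulate)
    settings.setdefault("seed", config.seed)
    model = synthetic.CohortModel(**settings)
    return synthetic.generate(model)


def run_end_to_end(config: RunConfig) -> dict:
    """Clean, classify and report on a cohort; returns the report bundle.

    The bundle always carries cleaning counts and the identified
    prevalence; a diagnostic-accuracy report is added when every retained
    record has a reference diagnosis, and an awareness cascade when the
    awareness flag is available.  Warnings (empty cohort, skipped sections)
    are collected rather than fatal.  When ``output_dir`` is set the bundle,
    cleaned cohort and per-record classifications are written there.
    """
    rule = resolve_rule(config)
    warnings: list[str] = []

    records = _load_records(config)
    cleaned, cleaning_report = pipeline.clean(records, config.max_age_months)

    bundle: dict = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "rule": rule.name,
        "rule_description": rule.describe(),
        "cleaning": cleaning_report.as_dict(),
    }

    labels, prevalence = pipeline.classify_cohort(cleaned, rule)
    if len(cleaned) == 0:
        warnings.append("no records retained after cleaning; empty report")
        bundle["classification"] = {"n": 0, "positives": 0, "prevalence_pct": None}
    else:
        bundle["classification"] = {
            "n": int(len(cleaned)),
            "positives": int(labels.sum()),
            "prevalence_pct": round(100.0 * prevalence, 1),
        }

    has_reference = (
        len(cleaned) > 0
        and "reference_diagnosis" in cleaned.columns
        and not cleaned["reference_diagnosis"].isna().any()
    )
    if has_reference:
        report = pipeline.validate_against_reference(cleaned, rule)
        bundle["validation"] = diagnostics.format_report(report)
        if report.undefined:
            warnings.append(
                f"undefined validation metrics: {', '.join(report.undefined)}"
            )
    else:
        warnings.append("no complete reference diagnosis; validation skipped")

    if len(cleaned) > 0:
        cascade = pipeline.awareness_cascade(cleaned, labels.to_numpy())
        bundle["cascade"] = cascade.as_dict()
        if cascade.truncated_at:
            warnings.append(
                f"awareness cascade truncated at {cascade.truncated_at}"
            )

    bundle["warnings"] = warnings

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        pipeline.write_cohort(cleaned, out / "cleaned.csv")
        classified = cleaned.copy()
        classified["identified"] = labels.to_numpy() if len(cleaned) else []
        pipeline.write_cohort(classified, out / "classification.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(bundle, fh, indent=2)
    return bundle
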