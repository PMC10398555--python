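"""Screening rules over the seven-item infantile atopic-dermatitis questionnaire.

The instrument asks seven yes/no questions per child: allergic family history
(Q1), recurrent red rash or eczema (Q2), dry skin (Q3), itching (Q4),
typical sites affected within the last week (Q5), typical sites affected
within the last six months (Q6), and a previous doctor's diagnosis of atopic
dermatitis (Q7).  A *screening rule* maps the seven answers to a binary
identification.  Two kinds of rule are supported:

* :class:`BooleanRule` — an AND/OR expression tree over the question atoms,
  e.g. ``Q2&Q4&Q6``.
* :class:`LogisticRule` — a logistic risk score ``y = b0 + Σ b_i·Q_i`` whose
  predictive probability ``1/(1+exp(-y))`` is compared against a cutoff,
  optionally with a Q7 override (a previous diagnosis forces a positive
  identification regardless of the score).

Rules are plain data: they can be serialised to and rebuilt from JSON-style
dictionaries, so user-defined variants are first-class citizens next to the
four built-in presets ``rule1``..``rule4``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from math import exp
from pathlib import Path
from typing import Iterator, Mapping, Sequence, Union

N_QUESTIONS = 7

__all__ = [
    "AnswerVector",
    "BooleanRule",
    "LogisticRule",
    "ScreeningRule",
    "q",
    "and_",
    "or_",
    "truth_table",
    "truth_table_array",
    "pattern_index",
    "all_patterns",
    "rule_from_config",
    "rule_to_config",
    "load_rule",
    "get_rule",
    "RULE1",
    "RULE2",
    "RULE3",
    "RULE4",
    "RULE4_TABLE_INTERCEPT",
    "PRESETS",
    "RULE4_COEFFICIENTS",
    "RULE4_INTERCEPT_EQUATION",
    "RULE4_INTERCEPT_TABLE",
    "RULE4_CUTOFF",
]


@dataclass(frozen=True)
class AnswerVector:
    """The seven boolean answers for one respondent.

    Answers are strictly ``True``/``False``; incomplete questionnaires are
    rejected upstream (see :mod:`eceq.pipeline`).
    """

    q1: bool
    q2: bool
    q3: bool
    q4: bool
    q5: bool
    q6: bool
    q7: bool

    def __post_init__(self) -> None:
        for i in range(1, N_QUESTIONS + 1):
            v = getattr(self, f"q{i}")
            if not isinstance(v, (bool,)):
                raise TypeError(f"q{i} must be a bool, got {v!r}")

    @classmethod
    def from_iterable(cls, values: Sequence[bool]) -> "AnswerVector":
        values = list(values)
        if len(values) != N_QUESTIONS:
            raise ValueError(f"expected {N_QUESTIONS} answers, got {len(values)}")
        return cls(*(bool(v) for v in values))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, bool]) -> "AnswerVector":
        return cls(**{f"q{i}": bool(mapping[f"q{i}"]) for i in range(1, N_QUESTIONS + 1)})

    def __getitem__(self, index: int) -> bool:
        """1-based access: ``av[3]`` is the answer to Q3."""
        if not 1 <= index <= N_QUESTIONS:
            raise IndexError(f"question index must be in 1..{N_QUESTIONS}, got {index}")
        return getattr(self, f"q{index}")

    def as_tuple(self) -> tuple[bool, ...]:
        return tuple(getattr(self, f"q{i}") for i in range(1, N_QUESTIONS + 1))


def all_patterns() -> Iterator[AnswerVector]:
    """Enumerate all 2^7 = 128 possible answer vectors in a fixed order.

    The order is lexicographic with Q1 as the slowest-varying bit, so the
    position of a pattern equals :func:`pattern_index` of its answers.
    """
    for bits in product((False, True), repeat=N_QUESTIONS):
        yield AnswerVector(*bits)


def pattern_index(answers: AnswerVector) -> int:
    """Map an answer vector to its position in :func:`all_patterns` (0..127)."""
    idx = 0
    for i in range(1, N_QUESTIONS + 1):
        idx = (idx << 1) | int(answers[i])
    return idx


# ---------------------------------------------------------------------------
# Boolean rules: AND/OR expression trees over question atoms
# ---------------------------------------------------------------------------

# Node representation: ("q", n) | ("and", (node, ...)) | ("or", (node, ...))
Node = tuple


def q(n: int) -> Node:
    if not 1 <= n <= N_QUESTIONS:
        raise ValueError(f"question index must be in 1..{N_QUESTIONS}, got {n}")
    return ("q", n)


def and_(*children: Node) -> Node:
    if not children:
        raise ValueError("AND node needs at least one child")
    return ("and", tuple(children))


def or_(*children: Node) -> Node:
    if not children:
        raise ValueError("OR node needs at least one child")
    return ("or", tuple(children))


def _validate_node(node: Node) -> None:
    if not isinstance(node, tuple) or len(node) != 2:
        raise ValueError(f"malformed rule node: {node!r}")
    kind, payload = node
    if kind == "q":
        if not isinstance(payload, int) or not 1 <= payload <= N_QUESTIONS:
            raise ValueError(
                f"question index must be in 1..{N_QUESTIONS}, got {payload!r}"
            )
    elif kind in ("and", "or"):
        if not isinstance(payload, tuple) or not payload:
            raise ValueError(f"{kind.upper()} node needs a non-empty child tuple")
        for child in payload:
            _validate_node(child)
    else:
        raise ValueError(f"unknown rule node kind {kind!r}")


def _eval_node(node: Node, answers: AnswerVector) -> bool:
    kind, payload = node
    if kind == "q":
        return answers[payload]
    if kind == "and":
        return all(_eval_node(child, answers) for child in payload)
    return any(_eval_node(child, answers) for child in payload)


def _render_node(node: Node, parent: str = "") -> str:
    kind, payload = node
    if kind == "q":
        return f"Q{payload}"
    sep = "&" if kind == "and" else "|"
    body = sep.join(_render_node(child, kind) for child in payload)
    # parenthesise OR under AND (and any nested mixed operator) for clarity
    if parent and parent != kind:
        return f"({body})"
    return body


@dataclass(frozen=True)
class BooleanRule:
    """An AND/OR expression over question atoms, e.g. ``Q2&Q4&Q6``.

    Structural validity (every atom in 1..7, no empty nodes) is enforced at
    construction time, so evaluation is total and deterministic.
    """

    name: str
    expression: Node

    def __post_init__(self) -> None:
        _validate_node(self.expression)

    def evaluate(self, answers: AnswerVector) -> bool:
        return _eval_node(self.expression, answers)

    def describe(self) -> str:
        return _render_node(self.expression)


@dataclass(frozen=True)
class LogisticRule:
    """A logistic risk score with probability cutoff and optional Q7 override.

    ``probability = 1/(1+exp(-(intercept + Σ coefficients[i]·Q_i)))`` with
    ``Q_i ∈ {0, 1}``.  Classification is positive when the probability
    exceeds ``cutoff`` (strictly when ``strict``), or — with ``q7_override``
    — when Q7 is answered yes regardless of the score.
    """

    name: str
    coefficients: Mapping[int, float]
    intercept: float
    cutoff: float = 0.849
    strict: bool = True
    q7_override: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError(f"cutoff must be in (0, 1), got {self.cutoff}")
        for idx in self.coefficients:
            if not isinstance(idx, int) or not 1 <= idx <= N_QUESTIONS:
                raise ValueError(
                    f"coefficient index must be in 1..{N_QUESTIONS}, got {idx!r}"
                )
        # freeze the mapping so the rule is safely shareable
        object.__setattr__(self, "coefficients", dict(self.coefficients))

    def linear_score(self, answers: AnswerVector) -> float:
        return self.intercept + sum(
            b for idx, b in self.coefficients.items() if answers[idx]
        )

    def probability(self, answers: AnswerVector) -> float:
        return 1.0 / (1.0 + exp(-self.linear_score(answers)))

    def evaluate(self, answers: AnswerVector) -> bool:
        if self.q7_override and answers[7]:
            return True
        p = self.probability(answers)
        return p > self.cutoff if self.strict else p >= self.cutoff

    def describe(self) -> str:
        terms = " + ".join(
            f"{b:g}Q{idx}" for idx, b in sorted(self.coefficients.items())
        )
        cmp_ = ">" if self.strict else ">="
        base = f"P({terms} {self.intercept:+g}) {cmp_} {self.cutoff:g}"
        return f"({base})|Q7" if self.q7_override else base


ScreeningRule = Union[BooleanRule, LogisticRule]


def truth_table(rule: ScreeningRule) -> dict[tuple[bool, ...], bool]:
    """Exhaustive evaluation of a rule on all 128 answer vectors."""
    return {av.as_tuple(): rule.evaluate(av) for av in all_patterns()}


def truth_table_array(rule: ScreeningRule):
    """Truth table as a length-128 numpy bool array indexed by pattern_index."""
    import numpy as np

    out = np.empty(2 ** N_QUESTIONS, dtype=bool)
    for av in all_patterns():
        out[pattern_index(av)] = rule.evaluate(av)
    return out


# ---------------------------------------------------------------------------
# JSON-style configuration
# ---------------------------------------------------------------------------


def _node_from_config(d) -> Node:
    if isinstance(d, Mapping):
        if "q" in d:
            return q(int(d["q"]))
        if "and" in d:
            return and_(*(_node_from_config(c) for c in d["and"]))
        if "or" in d:
            return or_(*(_node_from_config(c) for c in d["or"]))
    raise ValueError(f"malformed boolean rule node: {d!r}")


def _node_to_config(node: Node):
    kind, payload = node
    if kind == "q":
        return {"q": payload}
    return {kind: [_node_to_config(c) for c in payload]}


def rule_from_config(config: Mapping, name: str = "custom") -> ScreeningRule:
    """Build a rule from its JSON-style configuration dictionary.

    Logistic rules look like ``{"coef": {"q1": 1.484, ...}, "intercept":
    -4.483, "cutoff": 0.849, "strict": true, "q7_override": true}``; boolean
    rules are nested ``{"and": [...]}/{"or": [...]}/{"q": n}`` trees,
    optionally wrapped as ``{"expression": ...}``.  A ``"name"`` key
    overrides the ``name`` argument.
    """
    name = str(config.get("name", name))
    if "coef" in config:
        coefficients = {
            int(str(k).lstrip("qQ")): float(v) for k, v in config["coef"].items()
        }
        return LogisticRule(
            name=name,
            coefficients=coefficients,
            intercept=float(config["intercept"]),
            cutoff=float(config.get("cutoff", 0.849)),
            strict=bool(config.get("strict", True)),
            q7_override=bool(config.get("q7_override", True)),
        )
    expression = config.get("expression", config)
    if isinstance(expression, Mapping) and {"q", "and", "or"} & set(expression):
        return BooleanRule(name=name, expression=_node_from_config(expression))
    raise ValueError(f"cannot interpret rule configuration: {config!r}")


def rule_to_config(rule: ScreeningRule) -> dict:
    """Inverse of :func:`rule_from_config` (behaviour-preserving round trip)."""
    if isinstance(rule, LogisticRule):
        return {
            "name": rule.name,
            "coef": {f"q{i}": b for i, b in sorted(rule.coefficients.items())},
            "intercept": rule.intercept,
            "cutoff": rule.cutoff,
            "strict": rule.strict,
            "q7_override": rule.q7_override,
        }
    return {"name": rule.name, "expression": _node_to_config(rule.expression)}


def load_rule(path: Union[str, Path]) -> ScreeningRule:
    """Load a rule definition from a JSON file."""
    with open(path) as fh:
        return rule_from_config(json.load(fh), name=Path(path).stem)


# ---------------------------------------------------------------------------
# Built-in presets
# ---------------------------------------------------------------------------

#: Fitted log-odds coefficients of the five-question logistic score
#: (Q5 is excluded from the model; Q7 enters only through the override).
RULE4_COEFFICIENTS: dict[int, float] = {1: 1.484, 2: 2.415, 3: 1.367, 4: 2.749, 6: 1.448}

#: Full-precision intercept from the published regression equation.
RULE4_INTERCEPT_EQUATION = -4.483
#: Alternative intercept as printed in the coefficient table (2 decimals).
#: The two variants disagree on a single boundary pattern ({Q2,Q3,Q4} yes).
RULE4_INTERCEPT_TABLE = -4.84
#: ROC-derived optimal predictive-probability cutoff.
RULE4_CUTOFF = 0.849

RULE1 = BooleanRule("rule1", and_(q(2), q(4), q(5)))
RULE2 = BooleanRule("rule2", and_(q(2), q(4), q(6)))
RULE3 = BooleanRule(
    "rule3",
    or_(and_(q(2), or_(q(4), and_(q(1), q(3))), q(6)), q(7)),
)
RULE4 = LogisticRule(
    "rule4",
    coefficients=RULE4_COEFFICIENTS,
    intercept=RULE4_INTERCEPT_EQUATION,
    cutoff=RULE4_CUTOFF,
)
RULE4_TABLE_INTERCEPT = LogisticRule(
    "rule4_table_intercept",
    coefficients=RULE4_COEFFICIENTS,
    intercept=RULE4_INTERCEPT_TABLE,
    cutoff=RULE4_CUTOFF,
)

PRESETS: dict[str, ScreeningRule] = {
    r.name: r for r in (RULE1, RULE2, RULE3, RULE4, RULE4_TABLE_INTERCEPT)
}


def get_rule(rule: Union[str, ScreeningRule]) -> ScreeningRule:
    """Resolve a preset name or pass a rule object through unchanged."""
    if isinstance(rule, (BooleanRule, LogisticRule)):
        return rule
    try:
        return PRESETS[rule]
    except KeyError:
        raise ValueError(
            f"unknown rule {rule!r}; built-in rules are {sorted(PRESETS)}"
        ) from None
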