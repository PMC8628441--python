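"""Conjunctive threshold rules: the unit of discovery, analysis, and reporting.

A rule is a conjunction of threshold conditions on named numeric predictors,
``r(x) = prod_j 1{x_j in s_j}``, mapping a patient vector to {0, 1} where 1
means the patient *endorses* the rule.  The qSOFA high-risk pattern
(``SBP <= 100 & RR >= 22 & GCS < 15``) is the canonical clinical example.

Thresholds are compared with exact IEEE floating-point ``<=``/``<``/``>``/``>=``
— no epsilon — because reported cut-offs are exact printed values.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Rule",
    "InfeasibleRuleError",
    "RuleParseError",
    "evaluate_rule",
    "rule_endorsement",
    "rule_support",
    "canonicalize",
    "parse_rule",
    "format_rule",
]

#: comparison operators a condition may use
OPS = ("<=", "<", ">", ">=")

_OP_FUNCS = {
    "<=": np.less_equal,
    "<": np.less,
    ">": np.greater,
    ">=": np.greater_equal,
}


class InfeasibleRuleError(ValueError):
    """Raised when a rule's conditions admit no satisfying input."""


class RuleParseError(ValueError):
    """Raised on malformed rule text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Condition:
    """One threshold condition, e.g. ``Potassium.serum > 4.1``."""

    variable: str
    op: str
    threshold: float

    def __post_init__(self):
        if not self.variable:
            raise ValueError("condition variable name must be non-empty")
        if self.op not in OPS:
            raise ValueError(f"unknown operator {self.op!r}; expected one of {OPS}")
        if not np.isfinite(self.threshold):
            raise ValueError(f"threshold must be finite, got {self.threshold}")

    def holds(self, value: float) -> bool:
        return bool(_OP_FUNCS[self.op](value, self.threshold))

    @property
    def is_lower_bound(self) -> bool:
        """True for ``>``/``>=`` (condition bounds the variable from below)."""
        return self.op in (">", ">=")


@dataclass(frozen=True)
class Rule:
    """A conjunction of conditions plus fitted metadata.

    ``support`` is the fraction of a cohort endorsing the rule; ``direction``
    says whether endorsement increases or decreases predicted death risk
    (assigned from the sign of the fitted weight, positive = increasing).
    An empty condition list is the always-true rule; it may appear as an
    internal artifact but is never reported.
    """

    rule_id: str = ""
    conditions: tuple[Condition, ...] = ()
    support: float | None = None
    direction: str | None = None
    weight: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.direction not in (None, "increasing", "decreasing"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.support is not None and not 0.0 <= self.support <= 1.0:
            raise ValueError(f"support must be in [0, 1], got {self.support}")

    @property
    def variables(self) -> tuple[str, ...]:
        """Distinct variables referenced, in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.conditions:
            seen.setdefault(c.variable, None)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.conditions)

    def to_dict(self) -> dict:
        return {
            "rule_id": self.rule_id,
            "conditions": [
                {"variable": c.variable, "op": c.op, "threshold": c.threshold}
                for c in self.conditions
            ],
            "support": self.support,
            "direction": self.direction,
            "weight": self.weight,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Rule":
        return cls(
            rule_id=d.get("rule_id", ""),
            conditions=tuple(
                Condition(c["variable"], c["op"], float(c["threshold"]))
                for c in d["conditions"]
            ),
            support=d.get("support"),
            direction=d.get("direction"),
            weight=d.get("weight"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "Rule":
        return cls.from_dict(json.loads(s))


def evaluate_rule(rule: Rule, x: Mapping[str, float] | pd.Series) -> int:
    """Evaluate ``r(x)`` on a single complete patient vector.

    Returns 1 iff every condition holds.  Raises if a referenced variable is
    absent or missing (rules are defined only on complete inputs).
    """
    for cond in rule.conditions:
        try:
            value = x[cond.variable]
        except KeyError:
            raise KeyError(
                f"rule {rule.rule_id!r} references variable {cond.variable!r} "
                "absent from the input"
            ) from None
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(
                f"variable {cond.variable!r} is missing; rules require complete inputs"
            )
        if not cond.holds(value):
            return 0
    return 1


def rule_endorsement(rule: Rule, X: pd.DataFrame) -> np.ndarray:
    """Vectorized endorsement indicator over the rows of ``X`` (0/1 array)."""
    missing = [v for v in rule.variables if v not in X.columns]
    if missing:
        raise KeyError(f"rule {rule.rule_id!r} references absent variables {missing}")
    out = np.ones(len(X), dtype=np.int8)
    for cond in rule.conditions:
        col = X[cond.variable].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(
                f"variable {cond.variable!r} has missing values; "
                "impute before evaluating rules"
            )
        out &= _OP_FUNCS[cond.op](col, cond.threshold)
    return out.astype(np.int8)


def rule_support(rule: Rule, X: pd.DataFrame) -> float:
    """Fraction of rows endorsing the rule (in [0, 1])."""
    if len(X) == 0:
        raise ValueError("cannot compute support on an empty table")
    return float(rule_endorsement(rule, X).mean())


def canonicalize(rule: Rule) -> Rule:
    """Normalize a rule to a unique form preserving its endorsing set exactly.

    Conditions on the same variable and side are merged to the tightest bound;
    conditions are sorted by (variable, side).  Logically equivalent rules map
    to identical canonical forms.  Raises :class:`InfeasibleRuleError` when the
    bounds admit no value (e.g. ``x > 5 & x <= 3``).
    """
    lower: dict[str, Condition] = {}
    upper: dict[str, Condition] = {}
    for cond in rule.conditions:
        side = lower if cond.is_lower_bound else upper
        prev = side.get(cond.variable)
        if prev is None or _tighter(cond, prev):
            side[cond.variable] = cond

    for var in set(lower) & set(upper):
        lo, up = lower[var], upper[var]
        # the only feasible equal-threshold pair is >= t & <= t (x == t)
        if lo.threshold > up.threshold or (
            lo.threshold == up.threshold and (lo.op == ">" or up.op == "<")
        ):
            raise InfeasibleRuleError(
                f"rule {rule.rule_id!r}: contradictory bounds on {var!r} "
                f"({lo.op} {lo.threshold} and {up.op} {up.threshold})"
            )

    ordered = sorted(
        list(lower.values()) + list(upper.values()),
        key=lambda c: (c.variable, c.is_lower_bound),
    )
    return replace(rule, conditions=tuple(ordered))


def _tighter(a: Condition, b: Condition) -> bool:
    """Is same-side condition ``a`` strictly tighter than ``b``?"""
    if a.is_lower_bound:
        return a.threshold > b.threshold or (
            a.threshold == b.threshold and a.op == ">" and b.op == ">="
        )
    return a.threshold < b.threshold or (
        a.threshold == b.threshold and a.op == "<" and b.op == "<="
    )


_COND_RE = re.compile(
    r"\s*(?P<var>[A-Za-z_][A-Za-z0-9_.\-]*)\s*"
    r"(?P<op><=|>=|<|>)\s*"
    r"(?P<thr>[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?)\s*"
)


def parse_rule(text: str, rule_id: str = "") -> Rule:
    """Parse rule text like ``"Potassium.serum > 4.1 & Platelets <= 136.7"``.

    Grammar: ``condition (" & " condition)*`` with
    ``condition = name op number`` and ``op`` in {<=, <, >, >=}.
    """
    if not text.strip():
        raise RuleParseError("empty rule text", 0)
    conditions = []
    pos = 0
    for i, chunk in enumerate(text.split("&")):
        m = _COND_RE.fullmatch(chunk)
        if m is None:
            raise RuleParseError(f"malformed condition {chunk.strip()!r}", pos)
        conditions.append(
            Condition(m.group("var"), m.group("op"), float(m.group("thr")))
        )
        pos += len(chunk) + 1
    return Rule(rule_id=rule_id, conditions=tuple(conditions))


def format_rule(rule: Rule) -> str:
    """Render a rule as text; ``parse_rule(format_rule(r))`` round-trips."""
    return " & ".join(
        f"{c.variable} {c.op} {_fmt_number(c.threshold)}" for c in rule.conditions
    )


def _fmt_number(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() and abs(x) < 1e15 else repr(float(x))


def canonical_key(rule: Rule) -> tuple:
    """Hashable identity of the canonical form (used for deduplication)."""
    canon = canonicalize(rule)
    return tuple((c.variable, c.op, c.threshold) for c in canon.conditions)
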