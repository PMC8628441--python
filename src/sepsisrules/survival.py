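"""Per-rule survival screening: KM curves, log-rank tests, condition-ablation
decomposition, and the filter that refines the discovered rule set.

Each discovered rule splits the cohort into endorsers and non-endorsers.
A rule is *discriminative* when the two groups' survival distributions
differ: the Kaplan-Meier curves quantify the gap and a two-group log-rank
test puts a p-value on it.  Decomposition analysis then asks whether every
condition in a rule earns its place: dropping one condition at a time yields
revised rules, and when the complete rule's p-value beats every revised
rule's, the conditions act synergistically — no single condition carries the
rule.  Filtering retains rules that are significant, non-degenerate in
support, and (optionally) synergistic in this sense.

Time starts at ICU admission; deaths contribute their event day, survivors
are right-censored at hospital discharge.  Estimates and tests are delegated
to lifelines; the 95% bands use Greenwood's variance on the log-survival
scale, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .cohort import CohortTable
from .rules import Rule, format_rule, rule_endorsement, rule_support

__all__ = [
    "KMCurve",
    "LogRankResult",
    "RuleSurvivalResult",
    "DecompositionReport",
    "FilterCriteria",
    "km_estimate",
    "logrank_test",
    "analyze_rule",
    "decompose_rule",
    "filter_rules",
    "write_rule_report",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate with pointwise 95% bands."""

    event_times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.survival, dtype=float)
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any(self.ci_lower - s > 1e-12) or np.any(s - self.ci_upper > 1e-12):
            raise ValueError("confidence bounds must bracket the estimate")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "at_risk": self.at_risk,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    statistic: float  # chi-square, 1 df for two groups
    df: int
    p_value: float

    def __post_init__(self):
        if self.statistic < 0:
            raise ValueError("chi-square statistic must be >= 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must be in [0, 1]")


@dataclass
class RuleSurvivalResult:
    rule: Rule
    km_endorsing: KMCurve
    km_other: KMCurve
    logrank: LogRankResult


@dataclass
class DecompositionReport:
    """Complete-rule p-value plus one ablation row per condition.

    Each ablation drops exactly one condition; ``p_value`` is None when the
    revised rule is not evaluable (its support is 0 or 1)."""

    rule: Rule
    complete_p: float
    ablations: list[tuple]  # (removed Condition, revised Rule, p or None)

    def synergy(self) -> bool:
        """True iff every evaluable ablation p exceeds the complete rule's p."""
        return all(p is None or p > self.complete_p for _, _, p in self.ablations)


@dataclass(frozen=True)
class FilterCriteria:
    """Retention thresholds: log-rank significance of the complete rule,
    non-degenerate support, and (optionally) the synergy pattern."""

    alpha_complete: float = 0.001
    require_synergy: bool = True
    support_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self):
        if not 0.0 < self.alpha_complete < 1.0:
            raise ValueError("alpha_complete must be in (0, 1)")
        lo, hi = self.support_range
        if not lo < hi:
            raise ValueError("support_range must have lo < hi")


def _km_one_group(time: np.ndarray, event: np.ndarray) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    # restrict to observed-event times (plus t=0 anchor handled by the caller)
    at_risk = table["at_risk"].to_numpy(float)
    deaths = table["observed"].to_numpy(float)
    times = table.index.to_numpy(float)
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy(float)
    # Greenwood variance of log S, pointwise bands on the log scale
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            at_risk > deaths, deaths / (at_risk * (at_risk - deaths)), np.inf
        )
        var_log = np.cumsum(terms)
        half = 1.959963984540054 * np.sqrt(var_log)
        lower = np.where(surv > 0, surv * np.exp(-half), 0.0)
        upper = np.where(surv > 0, np.minimum(surv * np.exp(half), 1.0), 0.0)
    return KMCurve(
        event_times=times,
        survival=surv,
        ci_lower=np.clip(np.nan_to_num(lower, nan=0.0), 0.0, 1.0),
        ci_upper=np.clip(np.nan_to_num(upper, nan=1.0), 0.0, 1.0),
        at_risk=at_risk,
    )


def km_estimate(
    time: np.ndarray, event: np.ndarray, group_mask: np.ndarray
) -> tuple[KMCurve, KMCurve]:
    """KM curves for the two groups defined by ``group_mask`` (True = in
    group, e.g. endorsing a rule).  Returns (in-group, out-group)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group_mask = np.asarray(group_mask, dtype=bool)
    if group_mask.all() or not group_mask.any():
        raise ValueError("both groups must be non-empty")
    return (
        _km_one_group(time[group_mask], event[group_mask]),
        _km_one_group(time[~group_mask], event[~group_mask]),
    )


def logrank_test(
    time: np.ndarray, event: np.ndarray, group_mask: np.ndarray
) -> LogRankResult:
    """Two-group log-rank chi-square (1 df) over pooled event times, ties
    handled by the standard hypergeometric variance."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group_mask = np.asarray(group_mask, dtype=bool)
    if group_mask.all() or not group_mask.any():
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(
        time[group_mask], time[~group_mask],
        event_observed_A=event[group_mask], event_observed_B=event[~group_mask],
    )
    return LogRankResult(
        statistic=float(res.test_statistic), df=1, p_value=float(res.p_value)
    )


def analyze_rule(rule: Rule, table: CohortTable) -> RuleSurvivalResult:
    """Survival screen of one rule: KM pair + log-rank p for endorsers vs
    non-endorsers."""
    mask = rule_endorsement(rule, table.X).astype(bool)
    if mask.all() or not mask.any():
        raise ValueError(
            f"rule {rule.rule_id!r} has support {float(mask.mean())}; "
            "both groups must be non-empty"
        )
    km_in, km_out = km_estimate(table.time, table.event, mask)
    return RuleSurvivalResult(rule, km_in, km_out, logrank_test(table.time, table.event, mask))


def decompose_rule(rule: Rule, table: CohortTable) -> DecompositionReport:
    """Ablate each condition in turn and re-test the revised rules.

    Single-condition rules have no ablation: only ``complete_p`` is reported.
    A revised rule with degenerate support is recorded as not evaluable
    (p = None) rather than failing the pipeline.
    """
    complete = analyze_rule(rule, table)
    ablations = []
    if len(rule.conditions) >= 2:
        for i, cond in enumerate(rule.conditions):
            revised = Rule(
                rule_id=f"{rule.rule_id}~{cond.variable}",
                conditions=rule.conditions[:i] + rule.conditions[i + 1:],
            )
            try:
                p = analyze_rule(revised, table).logrank.p_value
            except ValueError:
                p = None
            ablations.append((cond, revised, p))
    return DecompositionReport(rule, complete.logrank.p_value, ablations)


def filter_rules(
    rules: Sequence[Rule],
    table: CohortTable,
    criteria: FilterCriteria | None = None,
) -> tuple[list[DecompositionReport], list[tuple[Rule, str]]]:
    """Refine the discovered rule set: keep a rule iff its complete-rule
    log-rank p is below ``alpha_complete``, its support lies in
    ``support_range``, and (when required) every evaluable ablation p exceeds
    the complete p.  Discarded rules carry the first failed criterion."""
    criteria = criteria or FilterCriteria()
    lo, hi = criteria.support_range
    retained: list[DecompositionReport] = []
    discarded: list[tuple[Rule, str]] = []
    for rule in rules:
        support = rule_support(rule, table.X)
        if support in (0.0, 1.0):
            discarded.append((rule, "support_range"))
            continue
        report = decompose_rule(rule, table)
        if not report.complete_p < criteria.alpha_complete:
            discarded.append((rule, "alpha_complete"))
        elif not lo <= support <= hi:
            discarded.append((rule, "support_range"))
        elif criteria.require_synergy and not report.synergy():
            discarded.append((rule, "synergy"))
        else:
            retained.append(report)
    return retained, discarded


def write_rule_report(
    reports: Sequence[DecompositionReport],
    table: CohortTable,
    path: str | Path,
) -> pd.DataFrame:
    """Tabular rule report: one header row per rule (text, support,
    direction, complete log-rank p) followed by one row per ablation."""
    rows = []
    for rep in reports:
        rule = rep.rule
        rows.append(
            {
                "rule_id": rule.rule_id,
                "row_type": "complete",
                "rule_text": format_rule(rule),
                "removed_condition": "",
                "support": rule.support
                if rule.support is not None
                else rule_support(rule, table.X),
                "direction": rule.direction or "",
                "p_value": rep.complete_p,
            }
        )
        for cond, revised, p in rep.ablations:
            rows.append(
                {
                    "rule_id": rule.rule_id,
                    "row_type": "ablation",
                    "rule_text": format_rule(revised),
                    "removed_condition": f"{cond.variable} {cond.op} {cond.threshold}",
                    "support": rule_support(revised, table.X),
                    "direction": "",
                    "p_value": p if p is not None else np.nan,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
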