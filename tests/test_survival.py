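"""KM estimation, log-rank testing, decomposition, and rule filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sepsisrules import (
    CohortSpec,
    CohortTable,
    FilterCriteria,
    PlantedRule,
    analyze_rule,
    decompose_rule,
    filter_rules,
    generate_cohort,
    km_estimate,
    logrank_test,
    parse_rule,
)
from sepsisrules.rules import rule_endorsement, rule_support
from sepsisrules.survival import write_rule_report


def brute_force_logrank(time, event, mask):
    """Direct O/E/V tabulation over distinct event times."""
    time, event, mask = map(np.asarray, (time, event, mask))
    num = 0.0
    var = 0.0
    for t in np.unique(time[event.astype(bool)]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & mask).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & mask).sum()
        num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = num**2 / var
    return stat, stats.chi2.sf(stat, 1)


class TestKM:
    def test_no_censoring_equals_empirical_fraction(self):
        time = np.array([2.0, 3.0, 5.0, 5.0])
        event = np.array([True, True, True, True])
        curve, _ = km_estimate(time, event, np.array([True] * 3 + [False]))
        # within the masked group (times 2, 3, 5 all events)
        surv = dict(zip(curve.event_times, curve.survival))
        assert surv[2.0] == pytest.approx(2 / 3)
        assert surv[3.0] == pytest.approx(1 / 3)
        assert surv[5.0] == pytest.approx(0.0)

    def test_all_censored_constant_one(self):
        time = np.array([1.0, 2.0, 3.0, 9.0])
        event = np.zeros(4, dtype=bool)
        curve, other = km_estimate(time, event, np.array([True, True, False, False]))
        assert np.all(curve.survival == 1.0)
        assert np.all(other.survival == 1.0)

    def test_mixed_fixture_matches_hand_product_limit(self):
        """8 subjects, hand-computed product over event times."""
        from sepsisrules.survival import _km_one_group

        time = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        event = np.array([True, True, False, True, False, True, False, False])
        curve = _km_one_group(time, event)
        # product limit: t=1 (8 at risk, 1 death), t=2 (7, 1), t=3 (5, 1), t=5 (3, 1)
        expected = {1.0: 7 / 8, 2.0: (7 / 8) * (6 / 7), 3.0: (7 / 8) * (6 / 7) * (4 / 5),
                    5.0: (7 / 8) * (6 / 7) * (4 / 5) * (2 / 3)}
        got = dict(zip(curve.event_times, curve.survival))
        for t, s in expected.items():
            assert got[t] == pytest.approx(s)

    def test_ci_brackets_estimate_and_at_risk_non_increasing(self):
        rng = np.random.default_rng(0)
        time = rng.exponential(5, 60)
        event = rng.random(60) < 0.7
        mask = rng.random(60) < 0.5
        for curve in km_estimate(time, event, mask):
            assert np.all(curve.ci_lower <= curve.survival + 1e-12)
            assert np.all(curve.survival <= curve.ci_upper + 1e-12)
            assert np.all(np.diff(curve.at_risk) <= 0)

    def test_empty_group_fails(self):
        with pytest.raises(ValueError):
            km_estimate(np.array([1.0, 2.0]), np.array([True, False]),
                        np.array([True, True]))


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        time = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        event = np.tile([True, True, False, True], 2)
        mask = np.repeat([True, False], 4)
        res = logrank_test(time, event, mask)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_fixture_matches_hand_tabulation(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([True, True, True, False, True, True])
        mask = np.array([True, True, True, False, False, False])
        res = logrank_test(time, event, mask)
        stat, p = brute_force_logrank(time, event, mask)
        assert res.statistic == pytest.approx(stat, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        time = rng.exponential(3, 40)
        event = rng.random(40) < 0.8
        mask = rng.random(40) < 0.5
        a = logrank_test(time, event, mask)
        b = logrank_test(time, event, ~mask)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-10)

    def test_ties_match_brute_force(self):
        rng = np.random.default_rng(2)
        time = rng.integers(1, 6, 50).astype(float)  # heavy ties
        event = rng.random(50) < 0.7
        mask = rng.random(50) < 0.5
        res = logrank_test(time, event, mask)
        stat, _ = brute_force_logrank(time, event, mask)
        assert res.statistic == pytest.approx(stat, rel=1e-9)

    def test_one_empty_group_fails(self):
        with pytest.raises(ValueError):
            logrank_test(np.ones(5), np.ones(5, bool), np.zeros(5, bool))


class TestAnalyzeRule:
    def test_maximal_separation_tiny_p(self, simple_predictors):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"GCS": np.concatenate([np.full(30, 5.0), np.full(30, 13.0)])})
        y = np.where(X["GCS"] <= 8, 1, -1)
        time = np.where(y == 1, 2.0, 30.0)
        table = CohortTable(X, y, time, y == 1)
        res = analyze_rule(parse_rule("GCS <= 8", "r"), table)
        assert res.logrank.p_value < 1e-10

    def test_composition_identity(self, planted_cohort):
        _, table = planted_cohort
        rule = parse_rule("GCS <= 8", "r")
        mask = rule_endorsement(rule, table.X).astype(bool)
        direct = logrank_test(table.time, table.event, mask)
        via = analyze_rule(rule, table)
        assert via.logrank.statistic == pytest.approx(direct.statistic)

    def test_degenerate_support_fails(self, planted_cohort):
        _, table = planted_cohort
        with pytest.raises(ValueError, match="support"):
            analyze_rule(parse_rule("GCS <= -100", "never"), table)


class TestDecomposition:
    def test_two_condition_rule_two_ablations(self, planted_cohort, planted_rule):
        _, table = planted_cohort
        rep = decompose_rule(planted_rule, table)
        assert len(rep.ablations) == 2
        for cond, revised, p in rep.ablations:
            assert len(revised.conditions) == 1
            assert cond not in revised.conditions

    def test_single_condition_rule_has_no_ablation(self, planted_cohort):
        _, table = planted_cohort
        rep = decompose_rule(parse_rule("GCS <= 8", "r"), table)
        assert rep.ablations == []
        assert 0 <= rep.complete_p <= 1

    def test_ablation_endorsers_superset(self, planted_cohort, planted_rule):
        _, table = planted_cohort
        rep = decompose_rule(planted_rule, table)
        base = rule_endorsement(planted_rule, table.X).astype(bool)
        for _, revised, _ in rep.ablations:
            sup = rule_endorsement(revised, table.X).astype(bool)
            assert np.all(sup[base])  # every endorser still endorses

    def test_interaction_only_risk_shows_synergy(self, simple_predictors, planted_rule):
        """Risk requires both conditions: the complete rule separates better
        than either ablation (smaller log-rank p)."""
        spec = CohortSpec(n=1500, predictors=simple_predictors,
                          planted_rules=(PlantedRule(planted_rule, 2.5),),
                          intercept=-2.0, seed=99)
        table = generate_cohort(spec)
        rep = decompose_rule(planted_rule, table)
        for _, _, p in rep.ablations:
            assert p is not None and rep.complete_p < p


class TestFilter:
    def test_criteria_reasons(self, planted_cohort, planted_rule):
        _, table = planted_cohort
        always = parse_rule("GCS <= 1000", "always")   # support 1.0
        nearly = parse_rule("GCS <= 100", "nearly")    # support ~1, null-ish
        retained, discarded = filter_rules(
            [planted_rule, always, nearly], table,
            FilterCriteria(alpha_complete=0.001, support_range=(0.05, 0.95)),
        )
        reasons = dict((r.rule_id, reason) for r, reason in discarded)
        assert reasons["always"] == "support_range"
        assert reasons["nearly"] in ("alpha_complete", "support_range")
        assert [rep.rule.rule_id for rep in retained] == ["planted"]

    def test_matches_predicate_by_predicate_oracle(self, planted_cohort):
        _, table = planted_cohort
        rules = [
            parse_rule("GCS <= 8 & Bilirubin > 2", "a"),
            parse_rule("GCS <= 8", "b"),
            parse_rule("Bilirubin > 2", "c"),
            parse_rule("Potassium > 4.0", "d"),
            parse_rule("GCS <= 12", "e"),
        ]
        crit = FilterCriteria(alpha_complete=0.01, require_synergy=True,
                              support_range=(0.05, 0.95))
        retained, discarded = filter_rules(rules, table, crit)
        kept_ids = {rep.rule.rule_id for rep in retained}
        for rule in rules:
            support = rule_support(rule, table.X)
            ok = 0.0 < support < 1.0
            if ok:
                rep = decompose_rule(rule, table)
                ok = (rep.complete_p < crit.alpha_complete
                      and crit.support_range[0] <= support <= crit.support_range[1]
                      and all(p is None or p > rep.complete_p
                              for _, _, p in rep.ablations))
            assert (rule.rule_id in kept_ids) == bool(ok)

    def test_report_round_trip(self, tmp_path, planted_cohort, planted_rule):
        _, table = planted_cohort
        retained, _ = filter_rules([planted_rule], table, FilterCriteria())
        df = write_rule_report(retained, table, tmp_path / "report.csv")
        back = pd.read_csv(tmp_path / "report.csv")
        assert len(back) == len(df) == 3  # complete row + 2 ablations
        complete = back[back["row_type"] == "complete"].iloc[0]
        reparsed = parse_rule(complete["rule_text"])
        assert rule_support(reparsed, table.X) == pytest.approx(complete["support"])
        assert analyze_rule(reparsed, table).logrank.p_value == pytest.approx(
            complete["p_value"]
        )
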