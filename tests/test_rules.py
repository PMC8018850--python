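"""Rule metrics, generation, filtering and the brute-force rule oracle."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acumine import (
    AssociationRule,
    AssociationRuleExtractor,
    MiningParams,
    RuleParams,
    TransactionDB,
    brute_force_mine,
    compute_metrics,
    filter_and_sort,
    generate_rules,
    rules_brute_force,
    support_count,
)

F = frozenset


class TestComputeMetrics:
    def test_reported_metric_relationship(self):
        """supports (1/3, 1/3, 5/12) give conf 1, expconf 5/12, lift 2.4."""
        support, conf, expconf, lift = compute_metrics(1 / 3, 1 / 3, 5 / 12)
        assert support == pytest.approx(0.3333333, abs=5e-8)
        assert conf == pytest.approx(1.0)
        assert expconf == pytest.approx(0.4166667, abs=5e-8)
        assert lift == pytest.approx(2.4)

    @pytest.mark.parametrize("s", [0.1, 0.25, 1.0])
    def test_identical_sets(self, s):
        _, conf, _, lift = compute_metrics(s, s, s)
        assert conf == 1.0
        assert lift == pytest.approx(1 / s)

    def test_independence_gives_unit_lift(self):
        *_, lift = compute_metrics(0.3 * 0.4, 0.3, 0.4)
        assert lift == pytest.approx(1.0)

    @pytest.mark.parametrize("lhs, rhs", [(0.0, 0.5), (0.5, 0.0)])
    def test_zero_supports_rejected(self, lhs, rhs):
        with pytest.raises(ValueError):
            compute_metrics(0.0, lhs, rhs)

    def test_union_cannot_exceed_sides(self):
        with pytest.raises(ValueError):
            compute_metrics(0.9, 0.5, 0.5)


class TestAssociationRule:
    def test_sides_must_be_disjoint_and_non_empty(self):
        with pytest.raises(ValueError):
            AssociationRule(F("A"), F("A"), 0.5, 1.0, 0.5, 2.0)
        with pytest.raises(ValueError):
            AssociationRule(F(), F("A"), 0.5, 1.0, 0.5, 2.0)

    def test_text_is_sorted(self):
        rule = AssociationRule(F({"B1", "A1"}), F({"C1"}), 0.5, 1.0, 0.5, 2.0)
        assert rule.text == "{A1,B1} -> {C1}"


class TestGenerateRules:
    def _fixture_rules(self, db, consequents="all"):
        fi = brute_force_mine(db, MiningParams(min_support=0.2, denominator="formulas"))
        params = RuleParams(min_support=0.2, min_confidence=0.6, consequents=consequents)
        return generate_rules(fi, db, params)

    def test_perfect_confidence_rules_on_fixture(self, dgp_db_formulas):
        rules = {(tuple(sorted(r.lhs)), tuple(sorted(r.rhs))): r
                 for r in self._fixture_rules(dgp_db_formulas)}
        assert rules[(("CV12", "PC6"), ("ST36",))].confidence == pytest.approx(1.0)
        assert rules[(("ST21", "ST25"), ("CV12",))].confidence == pytest.approx(1.0)

    def test_equal_supports_give_perfect_confidence(self):
        db = TransactionDB.from_itemsets([{"A1", "B1"}, {"A1", "B1"}, {"B1"}])
        fi = brute_force_mine(db, MiningParams(min_support=0.5))
        rules = generate_rules(fi, db, RuleParams(min_support=0.5, min_confidence=0.6))
        a_to_b = next(r for r in rules if r.lhs == {"A1"})
        assert a_to_b.confidence == 1.0

    def test_stricter_mining_than_requested_is_an_error(self, dgp_db):
        fi = brute_force_mine(dgp_db, MiningParams(min_support=0.5))
        with pytest.raises(ValueError, match="stricter"):
            generate_rules(fi, dgp_db, RuleParams(min_support=0.2))

    def test_singleton_policy_emits_only_single_consequents(self, dgp_db_formulas):
        for rule in self._fixture_rules(dgp_db_formulas, consequents="singleton"):
            assert len(rule.rhs) == 1

    def test_rule_support_matches_independent_recount(self, dgp_db_formulas):
        for rule in self._fixture_rules(dgp_db_formulas):
            _, supp = support_count(dgp_db_formulas, rule.lhs | rule.rhs)
            assert rule.support == pytest.approx(supp)

    def test_confidence_at_least_support_with_transaction_denominator(self, dgp_db):
        fi = brute_force_mine(dgp_db, MiningParams(min_support=0.2))
        for rule in generate_rules(fi, dgp_db, RuleParams(min_support=0.2, consequents="all")):
            assert rule.confidence >= rule.support - 1e-12


class TestFilterAndSort:
    def _rule(self, lhs, rhs, supp, conf):
        return AssociationRule(F(lhs), F(rhs), supp, conf, 0.5, conf / 0.5)

    def test_threshold_filtering(self):
        rules = [self._rule("A", "B", 0.3, 0.9), self._rule("B", "C", 0.1, 0.9)]
        assert filter_and_sort(rules, RuleParams(min_support=0.2)) == rules[:1]

    def test_equal_metric_ties_break_lexicographically(self):
        rules = [self._rule("B", "C", 0.3, 0.9), self._rule("A", "B", 0.3, 0.9)]
        out = filter_and_sort(rules, RuleParams(min_support=0.2))
        assert [r.text for r in out] == ["{A} -> {B}", "{B} -> {C}"]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_filter_then_sort_equals_sort_then_filter(self, seed):
        rnd = random.Random(seed)
        rules = [
            self._rule(
                rnd.choice("ABC"), rnd.choice("XYZ"),
                rnd.choice([0.1, 0.2, 0.3, 0.4]), rnd.choice([0.5, 0.7, 0.9]),
            )
            for _ in range(rnd.randint(0, 15))
        ]
        params = RuleParams(min_support=0.2, min_confidence=0.6)
        sorted_first = [
            r for r in filter_and_sort(rules, RuleParams(min_support=1e-9, min_confidence=0.0))
            if r.support >= params.min_support and r.confidence >= params.min_confidence
        ]
        assert filter_and_sort(rules, params) == sorted_first


class TestBruteForceRules:
    def test_hand_enumerated_example(self):
        db = [{"A1", "B1"}, {"A1", "B1"}, {"A1"}]
        rules = {(tuple(sorted(r.lhs)), tuple(sorted(r.rhs))): r
                 for r in rules_brute_force(db, RuleParams(min_support=0.5, min_confidence=0.6))}
        b_to_a = rules[(("B1",), ("A1",))]
        assert b_to_a.confidence == pytest.approx(1.0)
        a_to_b = rules[(("A1",), ("B1",))]
        assert a_to_b.confidence == pytest.approx(2 / 3)
        # supp(AB) = supp(A)·supp(B) here, so lift is exactly 1 both ways
        assert a_to_b.lift == pytest.approx(1.0)
        assert b_to_a.lift == pytest.approx(a_to_b.lift)

    def test_full_confidence_means_containment(self, dgp_db):
        rules = rules_brute_force(
            dgp_db, RuleParams(min_support=0.2, min_confidence=1.0, consequents="all")
        )
        assert rules  # the fixture does contain perfect-confidence rules
        for rule in rules:
            for p in dgp_db:
                if rule.lhs <= p.items:
                    assert rule.rhs <= p.items

    def test_guard_limit(self):
        db = [{f"X{i}" for i in range(25)}]
        with pytest.raises(ValueError, match="guard limit"):
            rules_brute_force(db)


def _random_db(rnd: random.Random) -> list[set[str]]:
    items = [f"I{i}" for i in range(rnd.randint(2, 8))]
    return [
        {i for i in items if rnd.random() < 0.5} or {rnd.choice(items)}
        for _ in range(rnd.randint(1, 12))
    ]


def _key(rule: AssociationRule):
    return (
        tuple(sorted(rule.lhs)),
        tuple(sorted(rule.rhs)),
        round(rule.support, 9),
        round(rule.confidence, 9),
        round(rule.expected_confidence, 9),
        round(rule.lift, 9),
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), conf_tenths=st.integers(3, 9))
def test_generate_rules_matches_brute_force_oracle(seed, conf_tenths):
    """Rule generation from mined itemsets equals direct enumeration."""
    rnd = random.Random(seed)
    db = TransactionDB.from_itemsets(_random_db(rnd))
    params = RuleParams(
        min_support=rnd.choice([0.1, 0.2, 0.3, 0.5]),
        min_confidence=conf_tenths / 10,
        consequents="all",
    )
    fi = brute_force_mine(db, MiningParams(min_support=params.min_support))
    assert [_key(r) for r in generate_rules(fi, db, params)] == [
        _key(r) for r in rules_brute_force(db, params)
    ]


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_lift_is_symmetric(seed):
    """lift(A→B) == lift(B→A) on any database."""
    rnd = random.Random(seed)
    db = TransactionDB.from_itemsets(_random_db(rnd))
    rules = rules_brute_force(
        db, RuleParams(min_support=0.1, min_confidence=0.0, consequents="all")
    )
    lifts = {(tuple(sorted(r.lhs)), tuple(sorted(r.rhs))): r.lift for r in rules}
    for (lhs, rhs), lift in lifts.items():
        mirror = lifts.get((rhs, lhs))
        if mirror is not None:
            assert lift == pytest.approx(mirror)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_raising_thresholds_never_adds_rules(seed):
    rnd = random.Random(seed)
    db = TransactionDB.from_itemsets(_random_db(rnd))
    loose = rules_brute_force(db, RuleParams(min_support=0.1, min_confidence=0.3, consequents="all"))
    tight = rules_brute_force(db, RuleParams(min_support=0.3, min_confidence=0.7, consequents="all"))
    assert {_key(r) for r in tight} <= {_key(r) for r in loose}


def test_extractor_backends_agree_on_fixture(dgp_db):
    outputs = [
        AssociationRuleExtractor(algorithm=alg, consequents="all").fit(dgp_db).rules_
        for alg in ("apriori", "fpgrowth", "brute")
    ]
    assert [_key(r) for r in outputs[0]] == [_key(r) for r in outputs[1]] == [
        _key(r) for r in outputs[2]
    ]
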