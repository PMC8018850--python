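"""Association rules over frequent itemsets.

A rule ``LHS -> RHS`` splits a frequent itemset into a disjoint
antecedent and consequent and carries four metrics:

* support — support(LHS ∪ RHS), the co-occurrence frequency;
* confidence — support(LHS ∪ RHS) / support(LHS), estimating
  P(RHS | LHS);
* expected confidence — support(RHS), the baseline P(RHS);
* lift — confidence / expected confidence; > 1 means the antecedent
  raises the chance of seeing the consequent, and it is symmetric in
  the two sides.

Two consequent policies are supported: ``singleton`` (one item on the
right-hand side, the classic presentation) and ``all`` (every
partition of the itemset into two non-empty disjoint sides).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from .apriori import BruteForceMiner, FrequentItemsets, MiningParams
from .fpgrowth import FPGrowthMiner
from .transactions import TransactionDB, TransactionsLike, as_transaction_db

__all__ = [
    "AssociationRule",
    "RuleParams",
    "compute_metrics",
    "generate_rules",
    "filter_and_sort",
    "rules_brute_force",
    "AssociationRuleExtractor",
    "rules_to_frame",
    "rules_to_json",
]


@dataclass(frozen=True)
class AssociationRule:
    """An antecedent → consequent rule with its four metrics."""

    lhs: frozenset[str]
    rhs: frozenset[str]
    support: float
    confidence: float
    expected_confidence: float
    lift: float

    def __post_init__(self) -> None:
        if not self.lhs or not self.rhs:
            raise ValueError("both rule sides must be non-empty")
        if self.lhs & self.rhs:
            raise ValueError("rule sides must be disjoint")

    @property
    def text(self) -> str:
        return "{%s} -> {%s}" % (",".join(sorted(self.lhs)), ",".join(sorted(self.rhs)))

    def __str__(self) -> str:
        return (
            f"{self.text}  supp={self.support:.7f} conf={self.confidence:.7f} "
            f"expconf={self.expected_confidence:.7f} lift={self.lift:.6f}"
        )


@dataclass(frozen=True)
class RuleParams:
    """Rule-generation thresholds and policy.

    Defaults are minimum support 20% and minimum confidence 60% with
    singleton consequents; sorting is support descending, confidence
    descending, then lexicographic on the rule text.
    """

    min_support: float = 0.2
    min_confidence: float = 0.6
    consequents: str = "singleton"  # or "all"

    def __post_init__(self) -> None:
        if not 0 < self.min_support <= 1:
            raise ValueError(f"min_support must be in (0, 1], got {self.min_support}")
        if not 0 <= self.min_confidence <= 1:
            raise ValueError(f"min_confidence must be in [0, 1], got {self.min_confidence}")
        if self.consequents not in ("singleton", "all"):
            raise ValueError("consequents must be 'singleton' or 'all'")


def compute_metrics(
    supp_union: float, supp_lhs: float, supp_rhs: float
) -> tuple[float, float, float, float]:
    """The four rule metrics from the three itemset supports.

    Returns (support, confidence, expected confidence, lift) where
    support = supp_union, confidence = supp_union / supp_lhs,
    expected confidence = supp_rhs, lift = confidence / supp_rhs.

    >>> compute_metrics(1 / 3, 1 / 3, 5 / 12)  # doctest: +ELLIPSIS
    (0.333..., 1.0, 0.416..., 2.4...)
    """
    if supp_lhs <= 0 or supp_rhs <= 0:
        raise ValueError("antecedent and consequent supports must be positive")
    if supp_union > min(supp_lhs, supp_rhs) + 1e-12:
        raise ValueError("union support cannot exceed either side's support")
    confidence = supp_union / supp_lhs
    return supp_union, confidence, supp_rhs, confidence / supp_rhs


def _splits(itemset: frozenset[str], policy: str):
    items = sorted(itemset)
    if policy == "singleton":
        for rhs_item in items:
            yield itemset - {rhs_item}, frozenset([rhs_item])
    else:
        for r in range(1, len(items)):
            for rhs in combinations(items, r):
                rhs_set = frozenset(rhs)
                yield itemset - rhs_set, rhs_set


def _rule_sort_key(rule: AssociationRule):
    return (-rule.support, -rule.confidence, rule.text)


def generate_rules(
    fi: FrequentItemsets,
    db: TransactionDB | None = None,
    params: RuleParams | None = None,
) -> list[AssociationRule]:
    """Generate rules from mined frequent itemsets.

    Every frequent itemset of size ≥ 2 is split per the consequent
    policy; splits whose confidence and support meet the (inclusive)
    thresholds are emitted, sorted deterministically.  ``db`` is only
    needed when the mined collection lacks a subset's support (it never
    does when mining satisfied downward closure).

    Raises
    ------
    ValueError
        If ``fi`` was mined at a support threshold stricter than
        ``params.min_support`` — rules would be silently missing.
    """
    params = params or RuleParams()
    # the smallest count a rule at min_support could need; mining must not
    # have cut above it, else rules would be silently missing
    required_count = max(1, math.ceil(params.min_support * fi.denominator - 1e-12))
    if fi.min_count > required_count:
        raise ValueError(
            f"itemsets were mined with min_count {fi.min_count}, stricter than "
            f"the count {required_count} implied by rule min_support "
            f"{params.min_support:.6g}"
        )
    rules = []
    for itemset in fi.counts:
        if len(itemset) < 2:
            continue
        supp_union = fi.support(itemset)
        if supp_union < params.min_support - 1e-12:
            continue
        for lhs, rhs in _splits(itemset, params.consequents):
            supp_lhs = fi.support(lhs) if lhs in fi else _db_support(db, lhs)
            supp_rhs = fi.support(rhs) if rhs in fi else _db_support(db, rhs)
            support, confidence, expconf, lift = compute_metrics(
                supp_union, supp_lhs, supp_rhs
            )
            if confidence >= params.min_confidence - 1e-12:
                rules.append(
                    AssociationRule(lhs, rhs, support, confidence, expconf, lift)
                )
    rules.sort(key=_rule_sort_key)
    return rules


def _db_support(db: TransactionDB | None, itemset: frozenset[str]) -> float:
    if db is None:
        raise ValueError(
            f"support of {sorted(itemset)} unavailable from the mined itemsets "
            "and no database was provided to recount it"
        )
    count = sum(1 for p in db if itemset <= p.items)
    return count / db.support_denominator


def filter_and_sort(
    rules: Iterable[AssociationRule], params: RuleParams | None = None
) -> list[AssociationRule]:
    """Apply the thresholds (inclusively) and sort deterministically."""
    params = params or RuleParams()
    kept = [
        r
        for r in rules
        if r.support >= params.min_support - 1e-12
        and r.confidence >= params.min_confidence - 1e-12
    ]
    kept.sort(key=_rule_sort_key)
    return kept


def rules_brute_force(
    db: TransactionsLike,
    params: RuleParams | None = None,
    denominator: str | int = "n",
    guard_limit: int = 20,
) -> list[AssociationRule]:
    """Reference rule generator: enumerate all disjoint LHS/RHS pairs.

    Metrics are computed directly from transaction counts, independent
    of any mining algorithm; the consequent policy is all-partitions
    restricted per ``params``.
    """
    params = params or RuleParams()
    db = as_transaction_db(db)
    from .transactions import resolve_denominator

    denom = resolve_denominator(denominator, db)
    transactions = db.itemsets()
    # rules need support >= min_support, so only individually frequent items
    # can appear on either side; enumeration is restricted accordingly
    floor = max(1, math.ceil(params.min_support * denom - 1e-12))
    vocab = sorted(
        item
        for item in db.vocabulary
        if sum(1 for t in transactions if item in t) >= floor
    )
    if len(vocab) > guard_limit:
        raise ValueError(
            f"{len(vocab)} individually frequent items exceed the brute-force "
            f"guard limit of {guard_limit}"
        )

    def supp(s: frozenset[str]) -> float:
        return sum(1 for t in transactions if s <= t) / denom

    rules = []
    for k in range(2, len(vocab) + 1):
        for union in combinations(vocab, k):
            union_set = frozenset(union)
            supp_union = supp(union_set)
            if supp_union < params.min_support - 1e-12 or supp_union == 0:
                continue
            for lhs, rhs in _splits(union_set, params.consequents):
                support, confidence, expconf, lift = compute_metrics(
                    supp_union, supp(lhs), supp(rhs)
                )
                if confidence >= params.min_confidence - 1e-12:
                    rules.append(
                        AssociationRule(lhs, rhs, support, confidence, expconf, lift)
                    )
    rules.sort(key=_rule_sort_key)
    return rules


class AssociationRuleExtractor(BaseEstimator):
    """Mine frequent itemsets and extract association rules in one fit.

    Parameters
    ----------
    min_support, min_confidence : float
        Inclusive thresholds (defaults 0.2 and 0.6).
    consequents : {"singleton", "all"}
        Consequent policy.
    algorithm : {"fpgrowth", "apriori", "brute"}
        Mining backend; all three produce identical itemsets.
    denominator : {"n", "formulas"} or int
        Support denominator convention.

    Attributes
    ----------
    itemsets_ : FrequentItemsets
        The mined frequent itemsets.
    rules_ : list of AssociationRule
        Sorted rule list (support desc, confidence desc, rule text).
    """

    def __init__(
        self,
        min_support: float = 0.2,
        min_confidence: float = 0.6,
        consequents: str = "singleton",
        algorithm: str = "fpgrowth",
        denominator: str | int = "n",
        max_itemset_size: int | None = None,
        min_count: int | None = None,
    ) -> None:
        self.min_support = min_support
        self.min_confidence = min_confidence
        self.consequents = consequents
        self.algorithm = algorithm
        self.denominator = denominator
        self.max_itemset_size = max_itemset_size
        self.min_count = min_count

    def _miner(self):
        from .apriori import AprioriMiner

        miners = {
            "apriori": AprioriMiner,
            "fpgrowth": FPGrowthMiner,
            "brute": BruteForceMiner,
        }
        if self.algorithm not in miners:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r} (expected one of {sorted(miners)})"
            )
        return miners[self.algorithm](
            min_support=self.min_support,
            max_itemset_size=self.max_itemset_size,
            denominator=self.denominator,
            min_count=self.min_count,
        )

    def fit(self, X: TransactionsLike, y: None = None) -> "AssociationRuleExtractor":
        db = as_transaction_db(X)
        self.itemsets_ = self._miner().fit_mine(db)
        params = RuleParams(
            min_support=self.min_support,
            min_confidence=self.min_confidence,
            consequents=self.consequents,
        )
        counting_db = db.with_denominator(self.itemsets_.denominator)
        self.rules_ = generate_rules(self.itemsets_, counting_db, params)
        return self

    def fit_rules(self, X: TransactionsLike) -> list[AssociationRule]:
        return self.fit(X).rules_


def rules_to_frame(rules: Sequence[AssociationRule], decimals: int = 7) -> pd.DataFrame:
    """Tabulate rules: lhs, rhs, support, confidence, expected_confidence, lift."""
    rows = [
        (
            ",".join(sorted(r.lhs)),
            ",".join(sorted(r.rhs)),
            round(r.support, decimals),
            round(r.confidence, decimals),
            round(r.expected_confidence, decimals),
            round(r.lift, decimals),
        )
        for r in rules
    ]
    return pd.DataFrame(
        rows,
        columns=["lhs", "rhs", "support", "confidence", "expected_confidence", "lift"],
    )


def rules_to_json(rules: Sequence[AssociationRule], path: str | Path | None = None) -> str:
    """Serialize rules as a JSON list (optionally written to ``path``)."""
    payload = [
        {
            "lhs": sorted(r.lhs),
            "rhs": sorted(r.rhs),
            "support": r.support,
            "confidence": r.confidence,
            "expected_confidence": r.expected_confidence,
            "lift": r.lift,
        }
        for r in rules
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text
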