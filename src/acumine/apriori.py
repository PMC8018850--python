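"""Level-wise Apriori frequent-itemset mining, plus a brute-force oracle.

Apriori exploits downward closure (every subset of a frequent itemset is
frequent): size-k frequent itemsets are joined into size-(k+1)
candidates, candidates with an infrequent subset are pruned, and the
survivors are counted against the database.  ``BruteForceMiner``
enumerates every non-empty subset of the vocabulary instead and serves
as the reference semantics for both tree- and level-based miners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import pandas as pd
from sklearn.base import BaseEstimator

from .transactions import TransactionDB, TransactionsLike, as_transaction_db, resolve_denominator

__all__ = [
    "MiningParams",
    "FrequentItemsets",
    "candidate_join",
    "AprioriMiner",
    "BruteForceMiner",
    "apriori_mine",
    "brute_force_mine",
]


@dataclass(frozen=True)
class MiningParams:
    """Frequent-itemset mining thresholds.

    ``min_support`` is a fraction of the resolved denominator; the
    smallest count that satisfies it is ``ceil(min_support * denominator)``
    (inclusive comparison).  ``min_count`` overrides that conversion with
    an explicit absolute count.  ``max_itemset_size`` limits pattern
    length; ``None`` means unlimited.  ``denominator`` is ``"n"``
    (transaction count), ``"formulas"`` (the bundled DGP database's
    14-formula reporting convention) or an explicit integer.
    """

    min_support: float = 0.2
    max_itemset_size: int | None = None
    denominator: str | int = "n"
    min_count: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.min_support <= 1:
            raise ValueError(f"min_support must be in (0, 1], got {self.min_support}")
        if self.max_itemset_size is not None and self.max_itemset_size < 1:
            raise ValueError("max_itemset_size must be a positive integer")
        if self.min_count is not None and self.min_count < 1:
            raise ValueError("min_count must be >= 1")

    def resolve_min_count(self, db: TransactionDB) -> int:
        if self.min_count is not None:
            return self.min_count
        denom = resolve_denominator(self.denominator, db)
        # smallest integer count c with c / denom >= min_support
        return max(1, math.ceil(self.min_support * denom - 1e-12))


@dataclass
class FrequentItemsets:
    """Mined frequent itemsets with their counts and supports."""

    counts: dict[frozenset[str], int]
    denominator: int
    n_transactions: int
    min_count: int
    params: MiningParams | None = None

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, itemset: Iterable[str]) -> bool:
        return frozenset(itemset) in self.counts

    def count(self, itemset: Iterable[str]) -> int:
        return self.counts[frozenset(itemset)]

    def support(self, itemset: Iterable[str]) -> float:
        return self.counts[frozenset(itemset)] / self.denominator

    def of_size(self, k: int) -> dict[frozenset[str], int]:
        return {s: c for s, c in self.counts.items() if len(s) == k}

    def to_frame(self) -> pd.DataFrame:
        """Export as a table: itemset (sorted, semicolon-joined), size, count, support."""
        rows = [
            (";".join(sorted(s)), len(s), c, c / self.denominator)
            for s, c in self.counts.items()
        ]
        rows.sort(key=lambda r: (r[1], -r[2], r[0]))
        return pd.DataFrame(rows, columns=["itemset", "size", "count", "support"])


def candidate_join(frequent_k: Iterable[frozenset[str]], k: int) -> list[frozenset[str]]:
    """Join size-k frequent itemsets into pruned size-(k+1) candidates.

    Two k-itemsets sharing their first k-1 items (in lexicographic
    order) join into a (k+1)-candidate; candidates with any size-k
    subset missing from ``frequent_k`` are pruned.  Output is
    deduplicated and sorted.
    """
    fk = {frozenset(s) for s in frequent_k}
    if any(len(s) != k for s in fk):
        raise ValueError(f"all input itemsets must have size {k}")
    ordered = sorted(tuple(sorted(s)) for s in fk)
    candidates: set[frozenset[str]] = set()
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if a[: k - 1] != b[: k - 1]:
                break  # sorted order: later b cannot share the prefix either
            cand = frozenset(a) | frozenset(b)
            if all(frozenset(sub) in fk for sub in combinations(sorted(cand), k)):
                candidates.add(cand)
    return sorted(candidates, key=lambda s: tuple(sorted(s)))


class _BaseMiner(BaseEstimator):
    """Shared fit plumbing for the frequent-itemset miners."""

    min_support: float
    max_itemset_size: int | None
    denominator: str | int
    min_count: int | None

    def _params(self) -> MiningParams:
        return MiningParams(
            min_support=self.min_support,
            max_itemset_size=self.max_itemset_size,
            denominator=self.denominator,
            min_count=self.min_count,
        )

    def _prepare(self, X: TransactionsLike) -> tuple[TransactionDB, MiningParams, int, int]:
        db = as_transaction_db(X)
        if len(db) == 0:
            raise ValueError("cannot mine an empty transaction database")
        params = self._params()
        denom = resolve_denominator(params.denominator, db)
        return db, params, denom, params.resolve_min_count(db)

    def _finalize(self, db, params, denom, min_count, counts) -> "_BaseMiner":
        self.itemsets_ = FrequentItemsets(
            counts=counts,
            denominator=denom,
            n_transactions=len(db),
            min_count=min_count,
            params=params,
        )
        self.n_transactions_ = len(db)
        self.denominator_ = denom
        self.min_count_ = min_count
        return self

    def fit_mine(self, X: TransactionsLike) -> FrequentItemsets:
        """Fit and return the mined ``FrequentItemsets``."""
        return self.fit(X).itemsets_


class AprioriMiner(_BaseMiner):
    """Level-wise Apriori frequent-itemset miner.

    Parameters mirror :class:`MiningParams`.  After :meth:`fit`, the
    mined patterns are available as ``itemsets_`` and the resolved
    absolute threshold as ``min_count_``.

    Examples
    --------
    >>> AprioriMiner(min_support=0.6).fit_mine(
    ...     [{"A", "B", "C"}, {"A", "B"}, {"A", "C"}, {"B", "C"}, {"A", "B", "C"}]
    ... ).to_frame()[["itemset", "count"]].values.tolist()
    [['A', 4], ['B', 4], ['C', 4], ['A;B', 3], ['A;C', 3], ['B;C', 3]]
    """

    def __init__(
        self,
        min_support: float = 0.2,
        max_itemset_size: int | None = None,
        denominator: str | int = "n",
        min_count: int | None = None,
    ) -> None:
        self.min_support = min_support
        self.max_itemset_size = max_itemset_size
        self.denominator = denominator
        self.min_count = min_count

    def fit(self, X: TransactionsLike, y: None = None) -> "AprioriMiner":
        db, params, denom, min_count = self._prepare(X)
        transactions = db.itemsets()

        counts: dict[frozenset[str], int] = {}
        item_counts: dict[str, int] = {}
        for t in transactions:
            for item in t:
                item_counts[item] = item_counts.get(item, 0) + 1
        frequent = {
            frozenset([i]): c for i, c in item_counts.items() if c >= min_count
        }
        k = 1
        while frequent:
            counts.update(frequent)
            if params.max_itemset_size is not None and k >= params.max_itemset_size:
                break
            candidates = candidate_join(frequent.keys(), k)
            if not candidates:
                break
            cand_counts = {c: 0 for c in candidates}
            for t in transactions:
                for cand in candidates:
                    if cand <= t:
                        cand_counts[cand] += 1
            frequent = {c: n for c, n in cand_counts.items() if n >= min_count}
            k += 1
        return self._finalize(db, params, denom, min_count, counts)


class BruteForceMiner(_BaseMiner):
    """Exhaustive frequent-itemset miner (reference oracle).

    Enumerates every non-empty subset of the vocabulary, so the
    vocabulary is capped (``guard_limit``, default 20 items) to bound
    the 2^|V| enumeration.
    """

    def __init__(
        self,
        min_support: float = 0.2,
        max_itemset_size: int | None = None,
        denominator: str | int = "n",
        min_count: int | None = None,
        guard_limit: int = 20,
    ) -> None:
        self.min_support = min_support
        self.max_itemset_size = max_itemset_size
        self.denominator = denominator
        self.min_count = min_count
        self.guard_limit = guard_limit

    def fit(self, X: TransactionsLike, y: None = None) -> "BruteForceMiner":
        db, params, denom, min_count = self._prepare(X)
        transactions = db.itemsets()
        # an itemset containing an item below the count floor can never be
        # frequent, so enumeration is restricted to individually frequent items
        vocab = sorted(
            item
            for item in db.vocabulary
            if sum(1 for t in transactions if item in t) >= min_count
        )
        if len(vocab) > self.guard_limit:
            raise ValueError(
                f"{len(vocab)} individually frequent items exceed the "
                f"brute-force guard limit of {self.guard_limit}"
            )
        max_k = len(vocab)
        if params.max_itemset_size is not None:
            max_k = min(max_k, params.max_itemset_size)
        counts: dict[frozenset[str], int] = {}
        for k in range(1, max_k + 1):
            for combo in combinations(vocab, k):
                s = frozenset(combo)
                n = sum(1 for t in transactions if s <= t)
                if n >= min_count:
                    counts[s] = n
        return self._finalize(db, params, denom, min_count, counts)


def apriori_mine(db: TransactionsLike, params: MiningParams | None = None) -> FrequentItemsets:
    """Functional wrapper over :class:`AprioriMiner`."""
    params = params or MiningParams()
    return AprioriMiner(**_kwargs(params)).fit_mine(db)


def brute_force_mine(db: TransactionsLike, params: MiningParams | None = None) -> FrequentItemsets:
    """Functional wrapper over :class:`BruteForceMiner`."""
    params = params or MiningParams()
    return BruteForceMiner(**_kwargs(params)).fit_mine(db)


def _kwargs(params: MiningParams) -> dict:
    return dict(
        min_support=params.min_support,
        max_itemset_size=params.max_itemset_size,
        denominator=params.denominator,
        min_count=params.min_count,
    )
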