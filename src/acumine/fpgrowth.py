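"""FP-growth frequent-pattern mining.

The database is compressed into an FP-tree: a prefix tree whose paths
hold transactions with items arranged in a fixed global order
(descending support count, ties lexicographic), so shared prefixes
share nodes.  Mining recurses over conditional pattern bases — for each
item, the prefix paths that co-occur with it — building conditional
trees until a single path remains, whose item combinations are emitted
directly.  Output is identical to Apriori's; only the traversal
strategy differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import pandas as pd

from .apriori import FrequentItemsets, MiningParams, _BaseMiner, _kwargs
from .transactions import TransactionDB, TransactionsLike

__all__ = ["FPNode", "FPTree", "build_fptree", "FPGrowthMiner", "fpgrowth_mine", "pair_patterns"]


class FPNode:
    """One node of an FP-tree: an item with the count of paths through it."""

    __slots__ = ("item", "count", "parent", "children", "next_node")

    def __init__(self, item: str | None, count: int = 0, parent: "FPNode | None" = None):
        self.item = item  # None marks the root
        self.count = count
        self.parent = parent
        self.children: dict[str, FPNode] = {}
        self.next_node: FPNode | None = None  # header chain link


class FPTree:
    """Prefix tree over item-ordered transactions with per-item header chains."""

    def __init__(self, item_order: list[str]):
        self.root = FPNode(None)
        self.header: dict[str, FPNode] = {}
        self._tails: dict[str, FPNode] = {}
        self.item_order = item_order
        self._rank = {item: i for i, item in enumerate(item_order)}

    def insert(self, items: Iterable[str], count: int = 1) -> None:
        """Insert a transaction's surviving items, ordered by global rank."""
        node = self.root
        for item in sorted(items, key=self._rank.__getitem__):
            child = node.children.get(item)
            if child is None:
                child = FPNode(item, 0, node)
                node.children[item] = child
                if item in self._tails:
                    self._tails[item].next_node = child
                else:
                    self.header[item] = child
                self._tails[item] = child
            child.count += count
            node = child

    def chain(self, item: str) -> list[FPNode]:
        """All nodes holding ``item``, in insertion order."""
        out = []
        node = self.header.get(item)
        while node is not None:
            out.append(node)
            node = node.next_node
        return out

    def chain_count(self, item: str) -> int:
        return sum(n.count for n in self.chain(item))

    def is_single_path(self) -> list[tuple[str, int]] | None:
        """Return the (item, count) path if the tree is a single chain, else None."""
        path = []
        node = self.root
        while node.children:
            if len(node.children) > 1:
                return None
            (node,) = node.children.values()
            path.append((node.item, node.count))
        return path


def _item_order(item_counts: dict[str, int], min_count: int) -> list[str]:
    surviving = [i for i, c in item_counts.items() if c >= min_count]
    return sorted(surviving, key=lambda i: (-item_counts[i], i))


def build_fptree(db: TransactionDB | Iterable[Iterable[str]], min_count: int) -> FPTree:
    """Build the FP-tree of a database, dropping items below ``min_count``."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    transactions = db.itemsets() if isinstance(db, TransactionDB) else [frozenset(t) for t in db]
    item_counts: dict[str, int] = {}
    for t in transactions:
        for item in t:
            item_counts[item] = item_counts.get(item, 0) + 1
    order = _item_order(item_counts, min_count)
    keep = set(order)
    tree = FPTree(order)
    for t in transactions:
        surviving = t & keep if isinstance(t, frozenset) else set(t) & keep
        if surviving:
            tree.insert(surviving)
    return tree


def _mine_tree(
    tree: FPTree,
    suffix: frozenset[str],
    min_count: int,
    out: dict[frozenset[str], int],
    max_size: int | None,
) -> None:
    single = tree.is_single_path()
    if single is not None:
        # every combination of path items, with the minimum count along it
        for k in range(1, len(single) + 1):
            if max_size is not None and len(suffix) + k > max_size:
                break
            for combo in combinations(single, k):
                out[suffix | frozenset(i for i, _ in combo)] = min(c for _, c in combo)
        return
    # least-frequent first: each item closes one conditional subproblem
    for item in reversed(tree.item_order):
        count = tree.chain_count(item)
        pattern = suffix | {item}
        out[pattern] = count
        if max_size is not None and len(pattern) >= max_size:
            continue
        # conditional pattern base: prefix paths above each occurrence of item
        base: list[tuple[list[str], int]] = []
        cond_counts: dict[str, int] = {}
        for node in tree.chain(item):
            path = []
            up = node.parent
            while up is not None and up.item is not None:
                path.append(up.item)
                up = up.parent
            if path:
                base.append((path, node.count))
                for p in path:
                    cond_counts[p] = cond_counts.get(p, 0) + node.count
        order = _item_order(cond_counts, min_count)
        if not order:
            continue
        keep = set(order)
        cond = FPTree(order)
        for path, cnt in base:
            surviving = [p for p in path if p in keep]
            if surviving:
                cond.insert(surviving, cnt)
        _mine_tree(cond, pattern, min_count, out, max_size)


class FPGrowthMiner(_BaseMiner):
    """FP-growth frequent-itemset miner.

    Mines exactly the same itemsets and counts as :class:`AprioriMiner`
    and :class:`BruteForceMiner`; parameters and fitted attributes
    match theirs.
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

    def fit(self, X: TransactionsLike, y: None = None) -> "FPGrowthMiner":
        db, params, denom, min_count = self._prepare(X)
        tree = build_fptree(db, min_count)
        counts: dict[frozenset[str], int] = {}
        _mine_tree(tree, frozenset(), min_count, counts, params.max_itemset_size)
        counts = {s: c for s, c in counts.items() if c >= min_count}
        return self._finalize(db, params, denom, min_count, counts)


def fpgrowth_mine(db: TransactionsLike, params: MiningParams | None = None) -> FrequentItemsets:
    """Functional wrapper over :class:`FPGrowthMiner`."""
    params = params or MiningParams()
    return FPGrowthMiner(**_kwargs(params)).fit_mine(db)


def pair_patterns(fi: FrequentItemsets) -> pd.DataFrame:
    """All size-2 frequent patterns as a table.

    Columns ``item_a``/``item_b`` (lexicographic within the pair),
    ``count`` and ``support`` (six-decimal string, matching the usual
    frequent-pattern report format), sorted by support descending then
    lexicographically.
    """
    rows = []
    for s, c in fi.of_size(2).items():
        a, b = sorted(s)
        rows.append((a, b, c, c / fi.denominator))
    rows.sort(key=lambda r: (-r[3], r[0], r[1]))
    frame = pd.DataFrame(rows, columns=["item_a", "item_b", "count", "support"])
    frame["support"] = frame["support"].map(lambda v: f"{v:.6f}")
    return frame
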