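"""Synthetic prescription databases with planted core combinations.

The generator emulates the structure of the bundled clinical database:
a few dozen meridian-coded acupoints, prescriptions of a handful of
items each, and one or more "core combinations" — itemsets that
co-occur wholesale far more often than chance.  Each transaction draws
every planted core as a block with probability ``p_core`` and every
remaining vocabulary item independently with probability ``p_bg``;
transactions smaller than ``min_items`` are redrawn.  Mining a database
generated this way should recover the planted cores as the top-ranked
rules, which :func:`recovery_check` verifies.

What this does NOT emulate about real prescription data: correlated
background items, trial-specific prescription-size conventions, or any
meridian-level structure — background items are exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .rules import AssociationRule, RuleParams
from .transactions import Prescription, TransactionDB, normalize_item

__all__ = ["SyntheticSpec", "generate_db", "recovery_check", "RecoveryReport"]

_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-core transaction generator.

    Attributes
    ----------
    n_transactions : int
        Number of prescriptions to draw.
    vocabulary : tuple of str
        Item codes (normalized on construction).
    planted_cores : tuple of (frozenset, float)
        Core itemsets with their per-transaction inclusion probability
        ``p_core``.
    p_bg : float
        Independent inclusion probability of each non-core item; must
        be below every ``p_core`` for the cores to be recoverable
        (equality is allowed only to model the structureless null).
    min_items : int
        Minimum prescription size; smaller draws are rejected and
        redrawn from the same stream.
    seed : int
        Seed of the single pseudo-random stream; same seed, same
        database, bit for bit.
    """

    n_transactions: int
    vocabulary: tuple[str, ...]
    planted_cores: tuple[tuple[frozenset[str], float], ...]
    p_bg: float
    min_items: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        vocab = tuple(normalize_item(v) for v in self.vocabulary)
        object.__setattr__(self, "vocabulary", vocab)
        cores = tuple(
            (frozenset(normalize_item(i) for i in core), float(p))
            for core, p in self.planted_cores
        )
        object.__setattr__(self, "planted_cores", cores)
        if self.n_transactions < 1:
            raise ValueError("n_transactions must be positive")
        if not 0.0 <= self.p_bg <= 1.0:
            raise ValueError("p_bg must be in [0, 1]")
        vocab_set = set(vocab)
        for core, p in cores:
            if not core <= vocab_set:
                raise ValueError(f"planted core {sorted(core)} not within the vocabulary")
            if not 0.0 <= p <= 1.0:
                raise ValueError("core inclusion probability must be in [0, 1]")
            if p < self.p_bg:
                raise ValueError("p_core must be at least p_bg")
        if self.min_items < 1:
            raise ValueError("min_items must be >= 1")

    @classmethod
    def from_config(cls, path: str | Path) -> "SyntheticSpec":
        """Load a spec from a YAML/JSON mapping file."""
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        cores = tuple(
            (frozenset(c["items"]), float(c["p_core"])) for c in data.get("planted_cores", [])
        )
        return cls(
            n_transactions=int(data["n_transactions"]),
            vocabulary=tuple(data["vocabulary"]),
            planted_cores=cores,
            p_bg=float(data.get("p_bg", 0.0)),
            min_items=int(data.get("min_items", 1)),
            seed=int(data.get("seed", 0)),
        )

    def core_items(self) -> frozenset[str]:
        out: set[str] = set()
        for core, _ in self.planted_cores:
            out |= core
        return frozenset(out)


def generate_db(spec: SyntheticSpec) -> TransactionDB:
    """Draw a transaction database from a planted-core spec.

    One shared ``numpy`` Generator stream drives all draws: per
    transaction, core inclusions in listed order, then background
    items in sorted vocabulary order.  Undersized transactions consume
    the stream and are redrawn (bounded; an infeasible spec raises).
    """
    rng = np.random.default_rng(spec.seed)
    vocab_sorted = sorted(spec.vocabulary)
    prescriptions: list[Prescription] = []
    for t in range(spec.n_transactions):
        items: frozenset[str] | None = None
        for _ in range(_MAX_RESAMPLE):
            draw: set[str] = set()
            for core, p_core in spec.planted_cores:
                if rng.random() < p_core:
                    draw |= core
            for item in vocab_sorted:
                if item in draw:
                    continue
                if rng.random() < spec.p_bg:
                    draw.add(item)
            if len(draw) >= spec.min_items:
                items = frozenset(draw)
                break
        if items is None:
            raise ValueError(
                f"could not draw a transaction with >= {spec.min_items} items "
                f"after {_MAX_RESAMPLE} attempts; the spec is infeasible"
            )
        prescriptions.append(Prescription(f"s{t + 1:04d}", items))
    return TransactionDB(prescriptions)


@dataclass
class CoreRecovery:
    """Recovery outcome for one planted core."""

    core: frozenset[str]
    pair_rules_pass: bool
    pair_supports: dict[tuple[str, str], float]
    worst_core_pair_rank: int | None  # 1-based rank in the support-sorted pair list
    best_background_pair_rank: int | None
    outranks_background: bool


@dataclass
class RecoveryReport:
    """Per-core recovery outcomes plus the rule list they were judged on."""

    cores: list[CoreRecovery]
    rules: list[AssociationRule]

    @property
    def all_recovered(self) -> bool:
        return all(c.pair_rules_pass and c.outranks_background for c in self.cores)


def recovery_check(
    db: TransactionDB,
    spec: SyntheticSpec,
    params: RuleParams | None = None,
) -> RecoveryReport:
    """Check that mining recovers the planted cores.

    For each core, verifies (a) that every ordered within-core pair
    rule meets the support and confidence thresholds, and (b) that the
    core's pairs outrank every background-only pair (neither item in
    any core) in the support-sorted pair ranking.  Pair supports are
    counted directly from the database, so the check is independent of
    any particular mining backend.
    """
    params = params or RuleParams()
    n = len(db)
    transactions = db.itemsets()

    def pair_support(a: str, b: str) -> float:
        s = frozenset((a, b))
        return sum(1 for t in transactions if s <= t) / n

    def item_support(a: str) -> float:
        return sum(1 for t in transactions if a in t) / n

    # support-sorted ranking of all vocabulary pairs
    all_pairs = sorted(
        (tuple(sorted(p)) for p in combinations(sorted(db.vocabulary), 2)),
        key=lambda p: (-pair_support(*p), p),
    )
    rank = {p: i + 1 for i, p in enumerate(all_pairs)}
    core_items = spec.core_items()
    background_pairs = [p for p in all_pairs if not (set(p) & core_items)]
    best_bg_rank = min((rank[p] for p in background_pairs), default=None)

    cores: list[CoreRecovery] = []
    rules: list[AssociationRule] = []
    for core, _ in spec.planted_cores:
        supports: dict[tuple[str, str], float] = {}
        passes = True
        worst_rank: int | None = None
        for a, b in combinations(sorted(core), 2):
            supp_pair = pair_support(a, b)
            supports[(a, b)] = supp_pair
            r = rank[(a, b)]
            worst_rank = r if worst_rank is None else max(worst_rank, r)
            for lhs, rhs in ((a, b), (b, a)):
                supp_lhs, supp_rhs = item_support(lhs), item_support(rhs)
                if supp_lhs == 0 or supp_rhs == 0:
                    passes = False
                    continue
                conf = supp_pair / supp_lhs
                if supp_pair < params.min_support - 1e-12 or conf < params.min_confidence - 1e-12:
                    passes = False
                else:
                    rules.append(
                        AssociationRule(
                            frozenset([lhs]), frozenset([rhs]),
                            supp_pair, conf, supp_rhs, conf / supp_rhs,
                        )
                    )
        outranks = (
            worst_rank is not None
            and (best_bg_rank is None or worst_rank < best_bg_rank)
        )
        cores.append(
            CoreRecovery(
                core=core,
                pair_rules_pass=passes,
                pair_supports=supports,
                worst_core_pair_rank=worst_rank,
                best_background_pair_rank=best_bg_rank,
                outranks_background=outranks,
            )
        )
    rules.sort(key=lambda r: (-r.support, -r.confidence, r.text))
    return RecoveryReport(cores=cores, rules=rules)
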