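"""End-to-end analysis of the bundled diabetic-gastroparesis database.

Runs the full chain — item frequencies, Apriori rules with singleton
consequents, FP-growth frequent pairs, FP-growth rules with
all-partition consequents — on the 17-trial acupoint database and
writes a deterministic report directory.  Two denominator modes are
offered: ``standard`` divides supports by the 17 transactions;
``formulas`` reproduces the source dataset's 14-formula reporting
convention (pair supports may exceed 1).

Association rules are also exported as a network: acupoint nodes are
connected through one hub node per rule (antecedent items → hub →
consequent items), the layout used by rule-graph visualisations, in
JSON node-link and GraphML dialects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import json
import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .fpgrowth import FPGrowthMiner, pair_patterns
from .rules import AssociationRule, AssociationRuleExtractor, rules_to_frame
from .transactions import TransactionDB, dgp_fixture, item_frequencies

__all__ = ["AnalysisReport", "run_dgp_analysis", "export_rule_graph", "build_rule_graph"]

#: A pattern must appear in at least this many trials to enter the
#: frequent-pair table (the smallest count clearing 20% of 14 formulas).
PAIR_MIN_COUNT = 3


@dataclass
class AnalysisReport:
    """All tables of one pipeline run, plus provenance.

    Every cell is recomputable from the database and the recorded
    parameters; writing the report twice yields byte-identical files.
    """

    mode: str
    frequency: pd.DataFrame
    apriori_rules: pd.DataFrame
    frequent_pairs: pd.DataFrame
    fp_rules: pd.DataFrame
    rule_objects: list[AssociationRule]
    graph: nx.DiGraph
    provenance: dict

    def write(self, outdir: str | Path) -> Path:
        """Write the report directory (CSV tables, graph files, provenance)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.frequency.to_csv(outdir / "frequency.csv", index=False)
        self.apriori_rules.to_csv(outdir / "apriori_rules.csv", index=False)
        self.frequent_pairs.to_csv(outdir / "frequent_pairs.csv", index=False)
        self.fp_rules.to_csv(outdir / "fp_rules.csv", index=False)
        export_rule_graph(self.rule_objects, outdir / "rule_graph.json")
        export_rule_graph(self.rule_objects, outdir / "rule_graph.graphml")
        with open(outdir / "provenance.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.provenance, fh, sort_keys=True)
        return outdir


def _fmt(frame: pd.DataFrame, columns: Sequence[str], decimals: int) -> pd.DataFrame:
    out = frame.copy()
    for col in columns:
        out[col] = out[col].map(lambda v: f"{v:.{decimals}f}")
    return out


def run_dgp_analysis(
    mode: str = "standard",
    db: TransactionDB | None = None,
    min_support: float = 0.2,
    min_confidence: float = 0.6,
) -> AnalysisReport:
    """Run the full analysis on the bundled database (or a replacement).

    Parameters
    ----------
    mode : {"standard", "formulas"}
        Support-denominator convention: transaction count, or the
        source dataset's 14-formula convention.
    db : TransactionDB, optional
        Replacement database (e.g. a permutation of the fixture for
        determinism checks); defaults to the bundled fixture.
    """
    if mode not in ("standard", "formulas"):
        raise ValueError(f"unknown mode {mode!r} (expected 'standard' or 'formulas')")
    denominator: str | int = "n" if mode == "standard" else "formulas"
    if db is None:
        db = dgp_fixture(denominator)
    else:
        from .transactions import resolve_denominator

        db = db.with_denominator(resolve_denominator(denominator, db))

    frequency = _fmt(item_frequencies(db), ["fraction"], 6)

    apriori = AssociationRuleExtractor(
        min_support=min_support,
        min_confidence=min_confidence,
        consequents="singleton",
        algorithm="apriori",
        denominator=denominator,
    ).fit(db)
    apriori_rules = _fmt(
        rules_to_frame(apriori.rules_),
        ["support", "confidence", "expected_confidence", "lift"],
        7,
    )

    pair_miner = FPGrowthMiner(
        min_support=min_support,
        max_itemset_size=2,
        denominator=denominator,
        min_count=PAIR_MIN_COUNT,
    ).fit(db)
    frequent_pairs = pair_patterns(pair_miner.itemsets_)

    fp = AssociationRuleExtractor(
        min_support=min_support,
        min_confidence=min_confidence,
        consequents="all",
        algorithm="fpgrowth",
        denominator=denominator,
    ).fit(db)
    fp_rules = _fmt(
        rules_to_frame(fp.rules_),
        ["support", "expected_confidence"],
        6,
    )
    fp_rules = _fmt(fp_rules, ["confidence", "lift"], 2)

    graph = build_rule_graph(fp.rules_)
    provenance = {
        "mode": mode,
        "support_denominator": db.support_denominator,
        "n_transactions": len(db),
        "n_items": len(db.vocabulary),
        "min_support": min_support,
        "min_confidence": min_confidence,
        "pair_min_count": PAIR_MIN_COUNT,
        "database_sha256": db.content_hash(),
        "package_version": __version__,
        "rule_grouping": (
            "rules sharing an antecedent item are grouped together in the "
            "exported tables; no similarity clustering is applied"
        ),
    }
    return AnalysisReport(
        mode=mode,
        frequency=frequency,
        apriori_rules=apriori_rules,
        frequent_pairs=frequent_pairs,
        fp_rules=fp_rules,
        rule_objects=fp.rules_,
        graph=graph,
        provenance=provenance,
    )


def build_rule_graph(rules: Sequence[AssociationRule]) -> nx.DiGraph:
    """Build the hub-style rule network.

    Nodes are acupoints plus one hub per rule; edges run antecedent
    item → hub → consequent item.  Hub nodes carry the rule metrics.
    Construction order is fully sorted, so serialisation is stable.
    """
    if not rules:
        raise ValueError("cannot build a rule graph from an empty rule list")
    graph = nx.DiGraph()
    items = sorted({i for r in rules for i in r.lhs | r.rhs})
    for item in items:
        graph.add_node(item, kind="item")
    for idx, rule in enumerate(sorted(rules, key=lambda r: r.text)):
        hub = f"rule[{rule.text}]"
        graph.add_node(
            hub,
            kind="rule",
            support=round(rule.support, 7),
            confidence=round(rule.confidence, 7),
            lift=round(rule.lift, 7),
        )
        for item in sorted(rule.lhs):
            graph.add_edge(item, hub)
        for item in sorted(rule.rhs):
            graph.add_edge(hub, item)
    return graph


def export_rule_graph(
    rules: Sequence[AssociationRule] | nx.DiGraph, path: str | Path
) -> Path:
    """Write the rule network as JSON node-link or GraphML (by extension)."""
    graph = rules if isinstance(rules, nx.DiGraph) else build_rule_graph(rules)
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(graph, path, named_key_ids=True)
    elif path.suffix == ".json":
        data = nx.node_link_data(graph, edges="links")
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unsupported graph format {path.suffix!r} (.json or .graphml)")
    return path


def item_degree_ranking(graph: nx.DiGraph) -> list[tuple[str, int]]:
    """Acupoint nodes ranked by total degree in the rule network."""
    degs = [
        (node, graph.degree(node))
        for node, data in graph.nodes(data=True)
        if data.get("kind") == "item"
    ]
    degs.sort(key=lambda kv: (-kv[1], kv[0]))
    return degs
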