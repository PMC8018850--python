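# acumine

Association-rule mining of acupoint prescriptions.

Acupuncture trials report the *set* of acupoints stimulated in their
treatment arm — a prescription such as `{CV12, ST36, PC6}`.  Treating each
trial's prescription as one transaction turns "which acupoints are used
together?" into classic market-basket analysis.  `acumine` implements that
analysis end to end for evidence-synthesis work: frequent-itemset mining
with both **Apriori** (level-wise candidate generation with anti-monotone
pruning) and **FP-growth** (recursive conditional-pattern-base mining over a
prefix tree), an exhaustive brute-force reference miner, association-rule
generation, and a planted-core synthetic transaction generator so the whole
chain is testable without external data.  It ships with a 17-trial database
of randomized controlled trials (RCTs) of acupuncture for diabetic
gastroparesis (DGP), covering 29 distinct acupoints.

For a rule LHS → RHS over a transaction database with denominator *N*:

- support(X) = count(X) / N, where count(X) is the number of transactions
  containing every item of X;
- support(rule) = supp(LHS ∪ RHS);
- confidence = supp(LHS ∪ RHS) / supp(LHS) — an estimate of P(RHS | LHS);
- expected confidence = supp(RHS) — the baseline P(RHS);
- lift = confidence / expected confidence, symmetric in the two sides;
  lift > 1 indicates positive association.

Rules are filtered at minimum support 20% and minimum confidence 60% by
default (inclusive) and sorted by support descending, confidence
descending, then rule text.  The bundled database supports two support
denominators: the standard transaction count (*N* = 17, all supports ≤ 1)
and a `formulas` convention (*N* = 14 distinct formulas counted over all 17
trials), which is how the frequent-pair supports in the source dataset were
reported — under it, supports may exceed 1 (e.g. the pair (CV12, ST36)
occurs in 15 trials: 15/14 ≈ 1.071429).

## Worked example

```python
from acumine import AssociationRuleExtractor, dgp_fixture, item_frequencies

db = dgp_fixture("formulas")          # 17 trials, 14-formula denominator
print(item_frequencies(db).head(5).to_string(index=False))

ext = AssociationRuleExtractor(min_support=0.2, min_confidence=0.6,
                               consequents="singleton", algorithm="apriori",
                               denominator="formulas").fit(db)
for rule in ext.rules_[:5]:
    print(rule)
```

prints

```
item  count  fraction
CV12     16  1.142857
ST36     16  1.142857
 PC6     10  0.714286
ST25      7  0.500000
BL21      5  0.357143
{CV12} -> {ST36}  supp=1.0714286 conf=0.9375000 expconf=1.1428571 lift=0.820312
{ST36} -> {CV12}  supp=1.0714286 conf=0.9375000 expconf=1.1428571 lift=0.820312
{CV12,PC6} -> {ST36}  supp=0.7142857 conf=1.0000000 expconf=1.1428571 lift=0.875000
{PC6,ST36} -> {CV12}  supp=0.7142857 conf=1.0000000 expconf=1.1428571 lift=0.875000
{PC6} -> {CV12}  supp=0.7142857 conf=1.0000000 expconf=1.1428571 lift=0.875000
```

CV12 and ST36 appear in 16 of the 17 trials and co-occur in 15, so
`{CV12} -> {ST36}` tops the support-sorted rule list with confidence
15/16 ≈ 0.94; `{CV12,PC6} -> {ST36}` has confidence 1.0 because every
trial using both CV12 and PC6 also used ST36.  (Under the 14-formula
denominator the ubiquitous CV12/ST36 have expected confidence > 1, which
pushes their lifts below 1 — a known artefact of that reporting
convention; the standard `"n"` mode keeps all metrics in range.)

## Command line

```bash
acumine freq --out freq.csv                       # per-acupoint frequencies
acumine mine --algorithm fpgrowth --out out/      # itemsets + rules + pairs
acumine reproduce --mode formulas --out report/   # full report directory
acumine simulate --spec spec.yaml --out sim.basket
```

`acumine reproduce` writes `frequency.csv`, `apriori_rules.csv`,
`frequent_pairs.csv`, `fp_rules.csv`, a rule network in JSON node-link and
GraphML dialects (acupoint nodes linked through one hub node per rule),
and `provenance.yaml`; the output is byte-identical across runs and across
transaction orderings.

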