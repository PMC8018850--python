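# Methods

## Data model

A prescription is the set of acupoints one randomized trial used in its
acupuncture arm; a transaction database is an ordered list of
prescriptions over the union vocabulary.  Items are normalized to
meridian-prefix codes (uppercase letters then digits, e.g. `CV12`);
duplicate items within a prescription collapse (set semantics), while
identical prescriptions from different trials remain distinct
transactions — the bundled database contains several trials that used the
same three-point formula `{CV12, ST36, PC6}`, and pattern counts are only
meaningful if each trial counts once.

The bundled database holds 17 diabetic-gastroparesis RCTs over 29
distinct acupoints, shipped as a basket-format text file and exposed via
`dgp_fixture()`.

### Support denominators

Counts are always taken over the transactions.  The divisor that turns a
count into a "support" is configurable:

- `"n"` (default): the number of transactions; supports are proper
  fractions in [0, 1].
- `"formulas"`: a fixed divisor of 14, the number of distinct formula
  columns in the source dataset's reporting convention.  Counting 17
  trials but dividing by 14 makes supports above 1 possible (the pair
  (CV12, ST36) occurs in 15 trials → 15/14 ≈ 1.071).  This mode exists
  to reproduce reported values exactly; it is deliberately not the
  default because it is non-standard, and the package never propagates
  it implicitly.
- an explicit integer, for anything else.

The minimum-support threshold is resolved against the *configured*
denominator: `min_count = ceil(min_support × denominator)`, inclusive.
Under `formulas` (denominator 14) a 20% threshold therefore keeps
patterns occurring in ≥ 3 trials; under `"n"` (17) it keeps ≥ 4.  All
three mining backends resolve the threshold identically, so they always
return the same patterns under every mode.

## Mining algorithms

Three interchangeable backends return identical itemsets and counts:

- **Apriori** — level-wise: frequent size-k sets sharing a (k−1)-prefix
  in lexicographic order join into (k+1)-candidates; candidates with any
  infrequent k-subset are pruned before a single exact counting pass per
  level.  No hashing or sampling approximations: the data scale (tens of
  transactions, dozens of items) never warrants them.
- **FP-growth** — the database is compressed into a prefix tree with
  items in global order (descending support count, ties lexicographic —
  no order is canonical, and this one minimizes tree size in the common
  case); mining recurses over conditional pattern bases with explicit
  conditional trees (clarity over pseudo-projection micro-optimization),
  emitting all combinations directly once a conditional tree degenerates
  to a single path.
- **Brute force** — enumerates every subset of the individually frequent
  items (a superset of an infrequent item cannot be frequent) and counts
  it directly.  It is the testing oracle for the other two and refuses
  vocabularies whose frequent-item count exceeds a guard limit
  (default 20) to bound the 2^|V| enumeration.

## Rule generation

Every frequent itemset of size ≥ 2 is split into antecedent/consequent
pairs under one of two policies: `singleton` (one item on the right, the
classic presentation) or `all` (every bipartition).  Metrics follow the
standard definitions (see README); confidence never depends on the
denominator choice because it is a ratio of counts.  Thresholds are
inclusive with a 1e-12 float tolerance; ordering is support descending,
confidence descending, then lexicographic on the canonical rule text, so
output is deterministic across runs, processes and input orderings.
Generating rules from itemsets mined at a stricter support than requested
raises an error rather than silently under-reporting.  A second,
mining-free generator (`rules_brute_force`) enumerates disjoint
LHS/RHS pairs straight from transaction counts and serves as the rule
oracle.

## Pipeline report

`run_dgp_analysis` produces four tables from the bundled database — item
frequencies; Apriori rules with singleton consequents (0.2 / 0.6
thresholds); size-2 frequent patterns mined with an absolute floor of 3
trials (20% of 14 formulas, the smallest count clearing the threshold);
and FP-growth rules with all-partition consequents — plus a rule network
(acupoint nodes connected through one hub node per rule, hub attributes
carrying support/confidence/lift) in JSON node-link and GraphML dialects,
and a provenance block (parameters, an order-invariant SHA-256 of the
database content, package version).  Rule tables group naturally by
shared antecedent items; no similarity clustering of rules is applied,
because no well-defined criterion for one was available — the report
header records this grouping choice.  Numeric formatting is fixed
(frequencies and pair supports to 6 decimals, singleton-rule metrics to
7, all-partition confidences to 2) so reports are byte-identical across
runs and across transaction orderings.

## Synthetic generator

`generate_db` emulates the structure of the clinical database: per
transaction, each planted core itemset is included wholesale with
probability `p_core` (independent draws per core; cores may overlap),
then every vocabulary item not already present is included independently
with probability `p_bg`; transactions below `min_items` are redrawn from
the same single `numpy` Generator stream (bounded at 1000 attempts, then
the spec is declared infeasible).  Draw order is fixed — cores in listed
order, background items in sorted order — so a seed fully determines the
database, bit for bit.

What it does *not* emulate: correlated background items, meridian-level
structure, trial-size conventions, or publication bias.  Passing
recovery tests therefore show that the mining chain finds block-planted
co-occurrence against independent noise — not that it would resolve
correlated confounding in real prescription data.

`recovery_check` judges a generated database by two criteria per core:
all ordered within-core pair rules meet the support/confidence
thresholds, and every core pair outranks every background-only pair
(neither item in any core) in the support-sorted pair ranking.  Pair
supports are recounted directly from the transactions, independent of
any mining backend.  The reference validation setting is 200
transactions, a 3-item core at `p_core` 0.9 against `p_bg` 0.1 over 20
items — the core's empirical support then concentrates within ±0.06 of
0.9 (binomial 99% envelope), comfortably above the 0.2 threshold.

## Numerical and testing choices

- Threshold comparisons are inclusive (≥), with a 1e-12 absolute
  tolerance against float representation error; itemset counting itself
  is exact integer arithmetic throughout.
- All sorted outputs break ties lexicographically on item codes or rule
  text; nothing iterates over unsorted sets when writing output, so
  results are independent of hash randomization.
- The randomized equivalence suite (Apriori ≡ FP-growth ≡ brute force,
  and generated rules ≡ rule oracle) runs on 100 databases of ≤ 8 items
  and ≤ 12 transactions with thresholds drawn from {0.1, …, 0.9} — small
  enough for exhaustive enumeration, large enough to exercise joins,
  pruning, conditional trees and single-path shortcuts.
- Property tests are derandomized (fixed Hypothesis seeds) so the suite
  is reproducible.

## Known limitations

- The 14-formula denominator is a reporting convention of the source
  dataset that cannot be derived from the bundled transactions (17
  trials, 11 unique formulas); it is therefore exposed as an explicit
  mode rather than inferred.
- Only support/confidence/expected-confidence/lift are computed; no
  conviction, leverage, or statistical significance testing of rules.
- No maximal/closed itemset condensation, top-k mining, or streaming
  variants; the intended scale is evidence-synthesis databases of tens
  to hundreds of transactions.
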