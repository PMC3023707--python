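# Methods

## The model

`mfpt` is an associative classifier for protein subcellular localization.
Each protein is a *transaction*: a set of integer item codes, one per
discretized genomic feature (motif signals, overall-sequence properties,
whole-genome expression statistics).  Codes are globally unique across
features and the largest code of each feature's block means "no record".
The five compartment classes are C (cytoplasm), N (nucleus),
M (mitochondria), T (membrane/transmembrane) and E (secretory pathway:
endoplasmic reticulum or extracellular).

Training mines one ordered rule list per compartment (one-vs-rest) with a
greedy mine-select-remove loop:

1. **Mine.**  Build an FP-tree over the current working database and
   extract the complete set of frequent itemsets with FP-growth.  By
   default patterns are mined from the target-class rows only
   (`mining_scope="positives_only"`); mining from the full working database
   is available and produces the same kind of candidates at higher cost.
2. **Score.**  Each frequent itemset is a candidate rule
   *antecedent → compartment*.  On the full working database, `hits` is the
   number of transactions containing the antecedent, `positives` the hits
   carrying the target label, `hit_rate = positives / hits`, and the
   ranking score is `hit_rate * sqrt(hits)` — purity damped toward rules
   with real support.
3. **Select.**  Candidates with `hits < min_support` or
   `hit_rate < min_hit_rate` are insignificant and discarded; the best
   survivor is kept.  Ranking is by score; exact ties break by higher
   hit-rate, then more hits, then the lexicographically smallest
   antecedent, so mining is fully deterministic.  (Descriptions of this
   family of methods are ambiguous about ranking by score versus raw
   hit-rate; we treat the score as primary because it is the only
   quantitatively defined performance measure, and expose
   `selection_policy="hit_rate"` for the alternative reading.)
4. **Remove.**  Every transaction containing the selected antecedent —
   whatever its label — leaves the working database; the loop repeats.

The loop ends when no candidate clears both floors or after `max_loops`
iterations (default 100, a pure safety cap: each accepted rule removes at
least `min_support` transactions, so termination needs no cap).

Prediction integrates the per-compartment lists: among all rules whose
antecedent is contained in the transaction and whose *training* hit-rate
clears the prediction threshold, the highest hit-rate wins (ties: more
hits, then higher score, then the model's compartment order C, N, M, T, E).
If no rule qualifies the classifier abstains — a real outcome, reported as
such rather than forced into a class.  Conflict resolution by score instead
of hit-rate is available via `conflict_policy`.

## FP-tree mining

The FP-tree follows the classical design: a null root, item-prefix
subtrees, and a header table mapping each frequent item to its total
support and a node-link chain (maintained in node-creation order) through
all nodes carrying that item.  Construction scans the database twice —
once to count supports and fix the frequency-descending item order, once to
insert each transaction's frequent items in that order.  Support ties in
the item order break by ascending item code; an explicit
`item_order_override` can pin any other total order (useful to reproduce
textbook worked examples whose tie order is conventional).  The mined
pattern *set* is invariant to the tie order; only the tree shape varies.

FP-growth recurses over conditional pattern bases and conditional trees,
with the standard single-path shortcut (a single-path conditional tree
yields all combinations of its items directly).  `min_support` is an
absolute transaction count throughout, and duplicate items within one
transaction are collapsed before counting, so supports are
transaction-membership counts.

Correctness is anchored to `brute_force_frequent`, an independent
exhaustive subset-enumeration oracle (guarded to ≤ 20 distinct items); the
test suite checks exact agreement of itemsets and supports over hundreds of
randomized databases.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_support` | 2 | minimum transactions a rule must hit (absolute count) |
| `min_hit_rate` | 0.5 | minimum class purity of a rule's hits |
| `max_loops` | 100 | safety cap on greedy iterations per class |
| `mining_scope` | `positives_only` | where candidate patterns are mined |
| `selection_policy` | `score` | candidate ranking (`score` or `hit_rate`) |
| `min_antecedent_len` | 1 | shortest admissible antecedent |
| prediction threshold | `min_hit_rate` | training-hit-rate cut at predict time |

Lower support floors admit more, weaker rules; raising the prediction
threshold (e.g. from 0.5 to 0.65) trades coverage for precision —
coverage is provably non-increasing in the threshold for a fixed model.

## Feature schema

The bundled `yeast19` profile maps 19 genomic features onto global codes
1–113; each feature's block ends in its missing code (e.g. HDEL: 82 absent,
83 present, 84 no record).  Two printed-source quirks are resolved in
favour of the code ranges: GLYC occupies codes 4–14 (ten value bins plus
missing code 14, although its bin count is elsewhere printed as 11), and
MAYOUNG occupies 45–55 (value codes 45–54, missing 55, although its prose
description starts the run at 44, a code that belongs to TMS1).

Numeric features (isoelectric point and the four expression statistics)
have no published cut points; they are discretized by equal-occupancy
quantile edges fitted on training data only, persisted with the model so
held-out data are encoded identically.  Binning is left-closed/half-open
with clamping below the first and above the last edge, so encoding is total
— every raw record, including an all-missing one, encodes to exactly one
code per feature.

## Synthetic benchmark

The original curated yeast corpus (Localized-1342 and the companion
unannotated set of 4700 proteins) is not distributable with the package,
so every corpus-dependent headline figure reported for this family of
methods — overall accuracies near 80%, specific rule counts, specific
prediction counts at the 0.5/0.65 thresholds — is out of scope here and is
replaced by property-based checks on synthetic data with known ground
truth.  Nothing in this package asserts those corpus figures; what the
tests and the acceptance script compute is printed by them at run time.

The generator plants class-predictive itemset rules in otherwise
structureless data.  Carriers of a planted antecedent receive the rule's
target label at a controlled hit-rate; all other features draw uniformly
over their value bins, missing with probability 0.05; background rows draw
labels from the class priors.  Labels inside a planted block are assigned
by exact counts (largest-remainder apportionment over the non-target
classes, then shuffled) rather than independent Bernoulli draws: the
planted hit-rate is a design parameter of the benchmark, not a quantity to
be re-estimated, and exact assignment makes recovery tests sharp — the
realized rate deviates from the planted one only through rounding and
chance antecedent carriers elsewhere.

The standard benchmark (`benchmark_spec`) uses n = 2000 transactions,
uniform priors over the five compartments, and one planted three-item rule
per compartment at hit-rates 0.70 / 0.80 / 0.95 / 0.85 / 0.90 with 300
carriers each, on a generic schema of 19 ten-bin features.  Ten value bins
per feature keep chance co-occurrence between rows low (two random rows
share about two items), which mirrors the sparsity that makes support-2
mining feasible, and three-item antecedents over such features are
essentially never shadowed by a proper subset with an identical extension.
The generator makes no attempt to simulate real yeast feature marginals or
correlations (a Zipf `bin_skew` option exists to stress tie-breaking);
passing recovery tests therefore demonstrates correctness of the mining
machinery under the model's own assumptions, not predictive performance on
real proteomes.

## Evaluation protocol

Hold-out evaluation uses a seeded, optionally stratified 70/30 split.
Accuracy counts abstentions as errors (conservative); a covered-only
accuracy is reported alongside.  Per-compartment ROC curves sweep the
transaction score for a class — the maximum training hit-rate over the
class's firing rules, 0 when none fires, the only continuous per-class
quantity the model produces — and AUC is the trapezoidal area (computed
via scikit-learn's `roc_curve`/`auc`).  k-fold cross-validation partitions
the data exactly (fold sizes differ by at most one; n = 1342 with k = 5
gives folds 269/269/268/268/268) and reports the mean and *population*
variance of the fold accuracies.

## Problem sizes in the acceptance script

`scripts/acceptance.py` recomputes everything from scratch at the study
conditions above: the five-transaction worked example, a 200-database
oracle sweep, recovery/coverage/hold-out measurements on the n = 2000
benchmark, and five-fold cross-validation on an n = 1342 benchmark
(coverage 200 per rule, `max_loops` 15 per fold — the planted signal is
always found in the first loops, and truncating the long tail of weak
noise rules keeps the five-fold sweep brisk without affecting recovery).

## Known limitations

- Exhaustive support-2 mining is exponential in the worst case; dense or
  heavily correlated binary-coded data can make the candidate set explode.
  The miner is pure Python and sized for the corpus scale it targets
  (thousands of transactions, tens of items each).
- Rules are not pruned or generalized beyond the greedy loop, and rule
  hit-rates are raw training proportions, not calibrated probabilities.
- Abstention handling, the ROC score definition, and cross-compartment
  conflict resolution are this package's own constructions where the
  method family leaves them unspecified; each is switchable where a
  defensible alternative exists.
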