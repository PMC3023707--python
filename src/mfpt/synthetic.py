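"""Synthetic labeled transaction databases with planted class rules.

The generator emulates the statistical structure the miner assumes: every
sample carries one code per feature (categorical bins plus a per-feature
missing code), and class-predictive signal enters only through *planted
rules* — fixed itemsets whose carriers are labeled with the rule's target
class at a controlled hit-rate.  All non-antecedent features are drawn
uniformly over the feature's value bins (missing with a small probability),
and background samples draw labels from the class priors, so any structure
the miner finds beyond the planted rules is sampling noise.

Label assignment inside a planted block is by exact counts
(round(coverage * hit_rate) carriers get the target label, the rest are
spread over the other classes by their priors' largest remainders, then
shuffled), so the realized hit-rate of a planted rule differs from the
planted value only through rounding and accidental antecedent carriers
elsewhere in the database.  This makes planted hit-rates sharp benchmarks
for parameter-recovery tests instead of binomial draws.

``benchmark_spec`` builds the standard five-compartment benchmark used
throughout the package's tests: n = 2000, uniform priors over C, N, M, T, E
and one planted three-item rule per compartment at hit-rates
0.70/0.80/0.95/0.85/0.90 with 300 carriers each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._transactions import Transaction, TransactionDB
from .schema import FeatureSchema, FeatureSpec


def synthetic_schema(n_features: int = 19, n_bins: int = 10,
                     class_labels: Sequence[str] = ("C", "N", "M", "T", "E"),
                     ) -> FeatureSchema:
    """A generic schema: ``n_features`` categorical features with ``n_bins``
    value bins plus a missing code each, contiguous global codes from 1."""
    feats, first = [], 1
    for i in range(n_features):
        last = first + n_bins  # n_bins value codes + 1 missing code
        feats.append(FeatureSpec(f"F{i + 1:02d}", "categorical", first, last))
        first = last + 1
    return FeatureSchema(feats, class_labels=list(class_labels), name="synthetic")


@dataclass(frozen=True)
class PlantedRule:
    """A ground-truth rule: carriers of ``antecedent`` are labeled
    ``target_class`` with probability ``hit_rate``; ``coverage`` carriers
    are planted."""

    antecedent: frozenset
    target_class: str
    hit_rate: float
    coverage: int

    def __init__(self, antecedent, target_class, hit_rate, coverage):
        object.__setattr__(self, "antecedent", frozenset(antecedent))
        object.__setattr__(self, "target_class", str(target_class))
        object.__setattr__(self, "hit_rate", float(hit_rate))
        object.__setattr__(self, "coverage", int(coverage))
        if not 0 < self.hit_rate <= 1:
            raise ValueError("hit_rate must be in (0, 1]")
        if self.coverage < 1:
            raise ValueError("coverage must be positive")


@dataclass
class GeneratorSpec:
    """Full description of one synthetic database draw."""

    schema: FeatureSchema
    n: int
    class_priors: Dict[str, float]
    planted: List[PlantedRule] = field(default_factory=list)
    missing_prob: float = 0.05
    bin_skew: float = 0.0  # Zipf-like exponent over bins; 0 = uniform
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_priors.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class priors sum to {total}, not 1")
        if not 0 <= self.missing_prob < 1:
            raise ValueError("missing_prob must be in [0, 1)")
        budget = sum(r.coverage for r in self.planted)
        if budget > self.n:
            raise ValueError(
                f"planted coverages sum to {budget} > n = {self.n}"
            )
        for r in self.planted:
            feats = [self.schema.feature_of_code(c).name for c in r.antecedent]
            if len(set(feats)) != len(feats):
                raise ValueError(
                    f"planted antecedent {sorted(r.antecedent)} uses one "
                    f"feature twice"
                )
            for code in r.antecedent:
                f = self.schema.feature_of_code(code)
                if code == f.missing_code:
                    raise ValueError(
                        f"planted antecedent may not use missing code {code}"
                    )


def _bin_probs(n_bins: int, skew: float) -> np.ndarray:
    if skew <= 0:
        return np.full(n_bins, 1.0 / n_bins)
    w = 1.0 / np.arange(1, n_bins + 1) ** skew
    return w / w.sum()


def _exact_label_counts(n_other: int, priors: Dict[str, float],
                        exclude: str) -> List[Tuple[str, int]]:
    """Largest-remainder apportionment of n_other labels over the classes
    other than ``exclude``, proportional to their priors."""
    others = [(c, p) for c, p in priors.items() if c != exclude and p > 0]
    if not others:
        others = [(c, 1.0) for c in priors if c != exclude]
    if not others:
        raise ValueError("need at least two classes to plant an imperfect rule")
    total = sum(p for _, p in others)
    quotas = [(c, n_other * p / total) for c, p in others]
    counts = {c: int(q) for c, q in quotas}
    rem = n_other - sum(counts.values())
    for c, _ in sorted(quotas, key=lambda cq: (cq[1] - int(cq[1])), reverse=True)[:rem]:
        counts[c] += 1
    return [(c, k) for c, k in counts.items() if k > 0]


def generate(spec: GeneratorSpec) -> TransactionDB:
    """Draw one database from the spec; byte-identical for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    schema = spec.schema
    feats = list(schema)
    probs = {f.name: _bin_probs(f.n_bins, spec.bin_skew) for f in feats}

    def draw_row(fixed: Dict[str, int]) -> frozenset:
        items = []
        for f in feats:
            if f.name in fixed:
                items.append(fixed[f.name])
            elif rng.random() < spec.missing_prob:
                items.append(f.missing_code)
            else:
                b = rng.choice(f.n_bins, p=probs[f.name])
                items.append(f.first_code + int(b))
        return frozenset(items)

    rows: List[Tuple[frozenset, str]] = []
    for rule in spec.planted:
        fixed = {
            schema.feature_of_code(c).name: c for c in rule.antecedent
        }
        n_pos = int(round(rule.coverage * rule.hit_rate))
        labels = [rule.target_class] * n_pos
        for c, k in _exact_label_counts(rule.coverage - n_pos,
                                        spec.class_priors, rule.target_class):
            labels.extend([c] * k)
        labels = list(np.array(labels, dtype=object)[rng.permutation(len(labels))])
        for lab in labels:
            rows.append((draw_row(fixed), lab))

    n_background = spec.n - len(rows)
    classes = list(spec.class_priors)
    pvec = np.array([spec.class_priors[c] for c in classes])
    bg_labels = rng.choice(len(classes), size=n_background, p=pvec)
    for k in bg_labels:
        rows.append((draw_row({}), classes[int(k)]))

    order = rng.permutation(len(rows))
    width = len(str(len(rows)))
    return TransactionDB(
        [
            Transaction(f"S{i + 1:0{width}d}", rows[j][0], rows[j][1])
            for i, j in enumerate(order)
        ]
    )


@dataclass(frozen=True)
class RealizedRule:
    """A planted rule with its realized counts in one generated database."""

    planted: PlantedRule
    hits: int
    positives: int

    @property
    def hit_rate(self) -> float:
        if self.hits == 0:
            raise ValueError("no hits realized")
        return self.positives / self.hits


def truth_table(spec: GeneratorSpec, db: TransactionDB) -> List[RealizedRule]:
    """Realized hits/positives of every planted rule by direct scan of the
    generated database (the ground truth for recovery tests)."""
    out = []
    for rule in spec.planted:
        hits = positives = 0
        for t in db:
            if rule.antecedent <= t.items:
                hits += 1
                if t.label == rule.target_class:
                    positives += 1
        out.append(RealizedRule(rule, hits, positives))
    return out


BENCHMARK_HIT_RATES = {"C": 0.70, "N": 0.80, "M": 0.95, "T": 0.85, "E": 0.90}


def benchmark_spec(seed: int = 0, n: int = 2000, coverage: int = 300,
                   schema: Optional[FeatureSchema] = None) -> GeneratorSpec:
    """The standard five-compartment benchmark.

    One planted rule per compartment on three distinct features each (rules
    use disjoint feature triples so carriers of different rules overlap only
    by chance), hit-rates 0.70/0.80/0.95/0.85/0.90, uniform class priors.
    """
    schema = schema or synthetic_schema()
    classes = list(BENCHMARK_HIT_RATES)
    if schema.n_features < 3 * len(classes):
        raise ValueError("benchmark needs 3 distinct features per class")
    planted = []
    feats = list(schema)
    for k, cls in enumerate(classes):
        trio = feats[3 * k: 3 * k + 3]
        # bin index varies with the class to avoid shared antecedent items
        antecedent = {f.first_code + (k % f.n_bins) for f in trio}
        planted.append(
            PlantedRule(antecedent, cls, BENCHMARK_HIT_RATES[cls], coverage)
        )
    priors = {c: 1.0 / len(classes) for c in classes}
    return GeneratorSpec(schema, n, priors, planted, missing_prob=0.05,
                         seed=seed)
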