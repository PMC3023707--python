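"""Greedy minimal-rule-set induction from frequent patterns (mFPT).

For one target compartment the loop is:

1. mine the complete set of frequent patterns from the current working
   database (by default from its target-class rows only);
2. evaluate each pattern as a candidate rule against the full working
   database — ``hits`` is the number of transactions containing the
   antecedent, ``hit_rate`` the fraction of hits carrying the target label —
   and rank candidates by score = hit_rate * sqrt(hits);
3. discard candidates below the support or hit-rate floor, select the best;
4. remove every transaction hit by the selected rule and repeat.

The loop stops when no candidate survives the floors or a safety cap on
iterations is reached.  Because each accepted rule removes at least
``min_support`` transactions, the working database shrinks strictly and the
loop always terminates.  Mining is fully deterministic: ties are broken by
hit-rate, then hits, then the lexicographically smallest antecedent.

A multi-class model is five (in the localization profile) independent
one-vs-rest rule sets mined this way, one per compartment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from ._transactions import Item, Transaction, TransactionDB
from .fptree import MiningParams, Pattern, build_fptree, fp_growth


@dataclass(frozen=True)
class Rule:
    """An association rule antecedent -> target_class with its statistics.

    hits counts every transaction containing the antecedent; positives those
    whose label equals the target class; hit_rate = positives / hits; the
    ranking score is hit_rate * sqrt(hits).
    """

    antecedent: frozenset
    target_class: str
    hits: int
    positives: int
    loop_index: int = 0

    def __post_init__(self):
        if not self.antecedent:
            raise ValueError("rule antecedent must be non-empty")
        if self.positives > self.hits:
            raise ValueError("positives cannot exceed hits")

    @property
    def usable(self) -> bool:
        return self.hits > 0

    @property
    def hit_rate(self) -> float:
        if self.hits == 0:
            raise ValueError("hit_rate undefined for a rule with zero hits")
        return self.positives / self.hits

    @property
    def score(self) -> float:
        return score_rule(self)

    def matches(self, t: Transaction) -> bool:
        return self.antecedent <= t.items

    def sorted_items(self) -> Tuple[Item, ...]:
        return tuple(sorted(self.antecedent, key=lambda i: (type(i).__name__, i)))


def score_rule(r: Rule) -> float:
    """Rule ranking score: hit_rate * sqrt(hits)."""
    if r.hits == 0:
        raise ValueError("score undefined for a rule with zero hits")
    return r.hit_rate * math.sqrt(r.hits)


@dataclass
class RuleMiningParams:
    """Induction parameters.

    min_support and min_hit_rate are the significance floors: candidates
    with fewer hits or a lower hit-rate are discarded.  mining_scope chooses
    whether frequent patterns come from the target-class rows only
    (``positives_only``, the default) or from the whole working database;
    hit-rates are always evaluated on the whole working database either way.
    selection_policy ranks candidates by ``score`` (default) or by raw
    ``hit_rate``.  max_loops is a pure safety cap.
    """

    min_support: int = 2
    min_hit_rate: float = 0.5
    max_loops: int = 100
    mining_scope: str = "positives_only"
    selection_policy: str = "score"
    min_antecedent_len: int = 1

    def __post_init__(self):
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not 0.0 <= self.min_hit_rate <= 1.0:
            raise ValueError("min_hit_rate must be in [0, 1]")
        if self.mining_scope not in ("positives_only", "full_db"):
            raise ValueError(f"unknown mining_scope {self.mining_scope!r}")
        if self.selection_policy not in ("score", "hit_rate"):
            raise ValueError(f"unknown selection_policy {self.selection_policy!r}")


@dataclass
class RuleSet:
    """Ordered rules for one target class, in selection order."""

    target_class: str
    rules: List[Rule] = field(default_factory=list)
    params: Optional[RuleMiningParams] = None

    def __len__(self):
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


@dataclass
class MultiClassModel:
    """One rule set per class plus the parameters they were mined with."""

    rulesets: Dict[str, RuleSet]
    params: RuleMiningParams
    class_order: List[str] = field(default_factory=list)
    schema_ref: Optional[str] = None
    bin_edges_snapshot: Optional[Dict[str, list]] = None

    def __post_init__(self):
        if not self.class_order:
            self.class_order = list(self.rulesets)
        for tag, rs in self.rulesets.items():
            if rs.target_class != tag:
                raise ValueError(f"rule set keyed {tag!r} targets {rs.target_class!r}")

    def all_rules(self) -> List[Rule]:
        return [r for tag in self.class_order for r in self.rulesets[tag]]

    @property
    def n_rules(self) -> int:
        return sum(len(rs) for rs in self.rulesets.values())


def evaluate_pattern(p: Pattern, db: TransactionDB, target_class: str) -> Rule:
    """Turn a frequent pattern into a candidate rule by direct counting.

    The returned rule may have zero hits (``usable`` is False); callers must
    discard such rules since the hit-rate is undefined.
    """
    hits = positives = 0
    for t in db:
        if p.itemset <= t.items:
            hits += 1
            if t.label == target_class:
                positives += 1
    return Rule(p.itemset, target_class, hits, positives)


def _candidate_key(r: Rule, policy: str) -> tuple:
    """Sort key: maximize score (or hit-rate), break ties by hit-rate, then
    hits, then the lexicographically smallest antecedent."""
    primary = r.score if policy == "score" else r.hit_rate
    return (-primary, -r.hit_rate, -r.hits, r.sorted_items())


class _BitmapIndex:
    """Vertical bitmap index of a working database for fast hit counting."""

    def __init__(self, db: TransactionDB, target_class: str):
        self.item_masks: Dict[Item, int] = {}
        self.positive_mask = 0
        self.n = len(db)
        for idx, t in enumerate(db):
            bit = 1 << idx
            for item in t.items:
                self.item_masks[item] = self.item_masks.get(item, 0) | bit
            if t.label == target_class:
                self.positive_mask |= bit

    def match_mask(self, itemset) -> int:
        mask = -1
        for item in itemset:
            m = self.item_masks.get(item, 0)
            mask = m if mask == -1 else mask & m
            if not mask:
                return 0
        return 0 if mask == -1 else mask

    def counts(self, itemset) -> Tuple[int, int]:
        mask = self.match_mask(itemset)
        return mask.bit_count(), (mask & self.positive_mask).bit_count()


def mfpt_iterate(db: TransactionDB, target_class: str,
                 params: RuleMiningParams) -> RuleSet:
    """Run the greedy mine-select-remove loop for one target class."""
    if not db.is_labeled():
        if len(db) == 0:
            return RuleSet(target_class, [], params)
        raise ValueError("rule mining requires a fully labeled database")
    if not any(t.label == target_class for t in db):
        warnings.warn(
            f"no transactions labeled {target_class!r}; empty rule set",
            stacklevel=2,
        )
        return RuleSet(target_class, [], params)

    working = list(db.transactions)
    mining_params = MiningParams(min_support=params.min_support)
    rules: List[Rule] = []
    for loop in range(1, params.max_loops + 1):
        if params.mining_scope == "positives_only":
            scope = [t for t in working if t.label == target_class]
        else:
            scope = working
        if not scope:
            break
        patterns = fp_growth(
            build_fptree(TransactionDB(scope), mining_params), mining_params
        )
        index = _BitmapIndex(TransactionDB(working), target_class)
        best: Optional[Rule] = None
        best_key = None
        min_len = params.min_antecedent_len
        for p in patterns:
            if len(p.itemset) < min_len:
                continue
            hits, positives = index.counts(p.itemset)
            if hits < params.min_support:
                continue
            if positives / hits < params.min_hit_rate:
                continue
            cand = Rule(p.itemset, target_class, hits, positives, loop_index=loop)
            key = _candidate_key(cand, params.selection_policy)
            if best is None or key < best_key:
                best, best_key = cand, key
        if best is None:
            break
        rules.append(best)
        working = [t for t in working if not best.antecedent <= t.items]
        if not working:
            break
    return RuleSet(target_class, rules, params)


def train_model(db: TransactionDB, classes: Sequence[str],
                params: Optional[RuleMiningParams] = None) -> MultiClassModel:
    """Mine one rule set per class (one-vs-rest) from a labeled database.

    Each class is mined independently from the full database, so the rule
    sets do not interact; integration happens at prediction time.
    """
    params = params or RuleMiningParams()
    classes = list(classes)
    if len(db):
        known = set(classes)
        bad = [t.id for t in db if t.label not in known]
        if bad:
            raise ValueError(
                f"{len(bad)} transactions carry labels outside {classes}: "
                f"{bad[:5]}"
            )
    rulesets = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tag in classes:
            rulesets[tag] = mfpt_iterate(db, tag, params)
    return MultiClassModel(rulesets, params, class_order=classes)
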