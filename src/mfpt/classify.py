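"""Apply a multi-class rule model to transactions.

A rule fires on a transaction when its antecedent is a subset of the
transaction's items.  Prediction integrates the per-compartment rule sets:
among all firing rules whose training hit-rate clears the threshold, the
one with the highest hit-rate wins (ties: more hits, then higher score,
then the model's class order).  When no rule qualifies the prediction
abstains — a real outcome, since rule sets need not cover feature space.

The threshold is applied to the rule's *training* hit-rate; nothing is
re-estimated on the data being predicted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from ._transactions import Transaction, TransactionDB
from .rule_mining import MultiClassModel, Rule

ABSTAIN = "ABSTAIN"

_POLICIES = ("hit_rate", "score")


def matches(r: Rule, t: Transaction) -> bool:
    """True iff the rule's antecedent is contained in the transaction."""
    return r.antecedent <= t.items


@dataclass(frozen=True)
class PredictionResult:
    """One transaction's prediction: class tag or ABSTAIN, with the winning
    rule and its training hit-rate as the confidence."""

    id: str
    predicted: str
    matched_rule: Optional[Rule] = None
    confidence: float = 0.0

    def __post_init__(self):
        if (self.predicted == ABSTAIN) != (self.matched_rule is None):
            raise ValueError("ABSTAIN iff no matched rule")


def predict(model: MultiClassModel, t: Transaction,
            min_hit_rate: float = 0.5,
            conflict_policy: str = "hit_rate") -> PredictionResult:
    """Predict one transaction's class by rule-set integration."""
    if conflict_policy not in _POLICIES:
        raise ValueError(f"unknown conflict_policy {conflict_policy!r}")
    class_rank = {c: k for k, c in enumerate(model.class_order)}
    best: Optional[Rule] = None
    best_key = None
    for rule in model.all_rules():
        if rule.hit_rate < min_hit_rate or not matches(rule, t):
            continue
        primary = rule.hit_rate if conflict_policy == "hit_rate" else rule.score
        key = (-primary, -rule.hits, -rule.score,
               class_rank.get(rule.target_class, len(class_rank)))
        if best is None or key < best_key:
            best, best_key = rule, key
    if best is None:
        return PredictionResult(t.id, ABSTAIN)
    return PredictionResult(t.id, best.target_class, best, best.hit_rate)


def predict_all(model: MultiClassModel, db: TransactionDB,
                min_hit_rate: float = 0.5,
                conflict_policy: str = "hit_rate",
                ) -> Tuple[List[PredictionResult], Dict[str, int]]:
    """Predict every transaction; summarize counts per class and abstentions.

    For a fixed model, coverage (non-abstaining predictions) is
    non-increasing in the threshold.
    """
    results = [predict(model, t, min_hit_rate, conflict_policy) for t in db]
    summary: Dict[str, int] = {c: 0 for c in model.class_order}
    summary[ABSTAIN] = 0
    for r in results:
        summary[r.predicted] = summary.get(r.predicted, 0) + 1
    return results, summary


def coverage(results: List[PredictionResult]) -> int:
    """Number of non-abstaining predictions."""
    return sum(1 for r in results if r.predicted != ABSTAIN)
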