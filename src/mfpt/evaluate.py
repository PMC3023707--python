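"""Evaluation: train/test splits, accuracy, one-vs-rest ROC, k-fold CV.

The protocol mirrors the standard benchmark design for rule-based
localization predictors: a stratified-or-plain 70/30 split, correct
prediction rate with abstentions counted as errors (conservative; a
coverage-conditional accuracy is also reported), per-compartment ROC
curves where each transaction's score for a class is the maximum training
hit-rate over that class's firing rules (0 if none fires), and k-fold
cross-validation reporting the mean and population variance of the fold
accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from ._transactions import Transaction, TransactionDB
from .classify import ABSTAIN, PredictionResult, matches, predict_all
from .rule_mining import MultiClassModel, RuleMiningParams, train_model


@dataclass
class SplitSpec:
    """Train/test split specification (default 70/30)."""

    train_fraction: float = 0.7
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def split(db: TransactionDB, spec: SplitSpec) -> Tuple[TransactionDB, TransactionDB]:
    """Seeded, disjoint, exhaustive train/test partition.

    Train size is floor(train_fraction * n); with stratification per-class
    rounding may shift the split by one.
    """
    if not db.is_labeled():
        raise ValueError("split requires a fully labeled database")
    idx = np.arange(len(db))
    strat = db.labels if spec.stratified else None
    train_idx, test_idx = train_test_split(
        idx, train_size=spec.train_fraction, random_state=spec.seed,
        shuffle=True, stratify=strat,
    )
    return db.subset(list(train_idx)), db.subset(list(test_idx))


def correct_rate(preds: Sequence[PredictionResult], db: TransactionDB,
                 abstain_is_error: bool = True) -> float:
    """Fraction of labeled transactions predicted correctly.

    With ``abstain_is_error`` False, abstentions are dropped from the
    denominator (coverage-conditional accuracy).
    """
    truth = {t.id: t.label for t in db}
    if {p.id for p in preds} != set(truth):
        raise ValueError("prediction ids do not match the database ids")
    pairs = [(p.predicted, truth[p.id]) for p in preds]
    if not abstain_is_error:
        pairs = [pq for pq in pairs if pq[0] != ABSTAIN]
    if not pairs:
        raise ValueError("no predictions to score")
    return sum(1 for p, q in pairs if p == q) / len(pairs)


def per_class_precision_recall(preds: Sequence[PredictionResult],
                               db: TransactionDB,
                               classes: Sequence[str]) -> Dict[str, Dict[str, float]]:
    truth = {t.id: t.label for t in db}
    out = {}
    for c in classes:
        tp = sum(1 for p in preds if p.predicted == c and truth[p.id] == c)
        fp = sum(1 for p in preds if p.predicted == c and truth[p.id] != c)
        fn = sum(1 for p in preds if p.predicted != c and truth[p.id] == c)
        out[c] = {
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
        }
    return out


def class_scores(model: MultiClassModel, db: TransactionDB,
                 target_class: str) -> np.ndarray:
    """Per-transaction score for one class: the maximum training hit-rate
    over the class's firing rules, 0 when none fires."""
    rules = list(model.rulesets[target_class])
    out = np.zeros(len(db))
    for i, t in enumerate(db):
        hr = [r.hit_rate for r in rules if matches(r, t)]
        if hr:
            out[i] = max(hr)
    return out


def roc_one_vs_rest(model: MultiClassModel, test_db: TransactionDB,
                    target_class: str) -> Tuple[np.ndarray, np.ndarray, float]:
    """One-vs-rest ROC curve and trapezoidal AUC for one compartment.

    Requires at least one positive and one negative in the test set.
    """
    if not test_db.is_labeled():
        raise ValueError("ROC requires a labeled test set")
    y = np.array([t.label == target_class for t in test_db], dtype=int)
    if y.all() or not y.any():
        raise ValueError(
            f"AUC undefined: test set has no "
            f"{'negatives' if y.all() else 'positives'} for {target_class!r}"
        )
    scores = class_scores(model, test_db, target_class)
    fpr, tpr, _ = _sk_roc_curve(y, scores, drop_intermediate=False)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


@dataclass
class CVResult:
    fold_accuracies: List[float]
    mean: float
    variance: float  # population variance of the fold accuracies
    fold_sizes: List[int] = field(default_factory=list)


def cross_validate(db: TransactionDB, k: int = 5, seed: int = 0,
                   params: Optional[RuleMiningParams] = None,
                   min_hit_rate: Optional[float] = None,
                   stratified: bool = False) -> CVResult:
    """k-fold cross-validation of the full mine-and-predict pipeline.

    Folds partition the data exactly (sizes differ by at most one); each
    fold is predicted by a model trained on the remaining folds.  Reports
    raw fold accuracies, their mean and population variance.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if len(db) < k:
        raise ValueError(f"cannot make {k} folds from {len(db)} transactions")
    if not db.is_labeled():
        raise ValueError("cross-validation requires labels")
    params = params or RuleMiningParams()
    threshold = params.min_hit_rate if min_hit_rate is None else min_hit_rate
    classes = db.classes()
    splitter = (
        StratifiedKFold(k, shuffle=True, random_state=seed)
        if stratified else KFold(k, shuffle=True, random_state=seed)
    )
    accs, sizes = [], []
    idx = np.arange(len(db))
    for train_idx, test_idx in splitter.split(idx, db.labels):
        train = db.subset(list(train_idx))
        test = db.subset(list(test_idx))
        model = train_model(train, classes, params)
        preds, _ = predict_all(model, test, threshold)
        accs.append(correct_rate(preds, test))
        sizes.append(len(test))
    mean = float(np.mean(accs))
    variance = float(np.var(accs))  # population variance (ddof=0)
    return CVResult(accs, mean, variance, sizes)


@dataclass
class EvalReport:
    accuracy: float
    accuracy_covered: float
    coverage: int
    n_test: int
    per_class: Dict[str, Dict[str, float]]
    auc: Dict[str, float]
    roc: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def evaluate_split(db: TransactionDB, spec: SplitSpec,
                   params: Optional[RuleMiningParams] = None,
                   min_hit_rate: Optional[float] = None) -> EvalReport:
    """Train on the split's training part, score the held-out part."""
    params = params or RuleMiningParams()
    threshold = params.min_hit_rate if min_hit_rate is None else min_hit_rate
    train, test = split(db, spec)
    classes = db.classes()
    model = train_model(train, classes, params)
    preds, _ = predict_all(model, test, threshold)
    auc_by_class, roc_by_class = {}, {}
    for c in classes:
        try:
            fpr, tpr, a = roc_one_vs_rest(model, test, c)
        except ValueError:
            continue
        auc_by_class[c] = a
        roc_by_class[c] = (fpr, tpr)
    covered = [p for p in preds if p.predicted != ABSTAIN]
    return EvalReport(
        accuracy=correct_rate(preds, test),
        accuracy_covered=(
            correct_rate(preds, test, abstain_is_error=False)
            if covered else float("nan")
        ),
        coverage=len(covered),
        n_test=len(test),
        per_class=per_class_precision_recall(preds, test, classes),
        auc=auc_by_class,
        roc=roc_by_class,
    )
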