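"""scikit-learn style estimator wrapping the rule miner and classifier.

``MFPTClassifier`` follows the fit/predict contract: ``X`` is either a 2-D
integer array with one item code per feature column (the natural layout for
schema-encoded data, one row per protein) or a sequence of item-code
iterables of arbitrary length.  ``fit`` mines one greedy rule set per class;
``predict`` integrates the rule sets, returning the abstain label where no
rule clears the hit-rate threshold.  ``decision_function`` exposes the
per-class scores (maximum training hit-rate over firing rules), which is
what one-vs-rest ROC analysis sweeps.

The estimator composes with sklearn model selection::

    clf = MFPTClassifier(min_support=2, min_hit_rate=0.5)
    clf.fit(X_train, y_train)
    labels = clf.predict(X_test)
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._transactions import Transaction, TransactionDB
from .classify import ABSTAIN, predict_all
from .evaluate import class_scores
from .rule_mining import MultiClassModel, RuleMiningParams, train_model


def _as_db(X, y=None) -> TransactionDB:
    """Coerce an array or a sequence of item iterables into transactions."""
    if y is not None:
        y = np.asarray(y, dtype=object)
        if len(y) != len(X):
            raise ValueError(f"X has {len(X)} rows but y has {len(y)}")
    arr = None
    if isinstance(X, np.ndarray) or (
        len(X) and not isinstance(X[0], (set, frozenset))
        and all(np.isscalar(v) for v in X[0])
    ):
        arr = np.asarray(X)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            cast = arr.astype(int)
            if not np.array_equal(cast, arr.astype(float)):
                raise ValueError("item codes must be integers")
            arr = cast
        rows: Sequence = arr
    else:
        rows = [list(r) for r in X]
    width = len(str(len(rows)))
    return TransactionDB(
        [
            Transaction(
                f"R{i + 1:0{width}d}",
                (int(v) for v in row),
                None if y is None else str(y[i]),
            )
            for i, row in enumerate(rows)
        ]
    )


class MFPTClassifier(ClassifierMixin, BaseEstimator):
    """Associative classifier built on frequent-pattern-tree rule mining.

    Parameters
    ----------
    min_support : int, default 2
        Minimum number of transactions a rule must hit.
    min_hit_rate : float, default 0.5
        Minimum training hit-rate (class purity among hits) of a rule.
    max_loops : int, default 100
        Safety cap on mine-select-remove iterations per class.
    mining_scope : {"positives_only", "full_db"}
        Where candidate patterns are mined from at each iteration.
    selection_policy : {"score", "hit_rate"}
        Candidate ranking: hit_rate * sqrt(hits) or raw hit-rate.
    min_antecedent_len : int, default 1
        Shortest admissible rule antecedent.
    prediction_threshold : float or None
        Hit-rate cut applied at prediction time; None reuses min_hit_rate.
    conflict_policy : {"hit_rate", "score"}
        How cross-class conflicts between firing rules are resolved.
    abstain_label : str, default "ABSTAIN"
        Label returned when no rule qualifies.

    Attributes
    ----------
    classes_ : ndarray of class labels seen in fit (sorted).
    model_ : the fitted rule sets (:class:`MultiClassModel`).
    n_rules_ : total number of mined rules.
    """

    def __init__(self, min_support: int = 2, min_hit_rate: float = 0.5,
                 max_loops: int = 100, mining_scope: str = "positives_only",
                 selection_policy: str = "score", min_antecedent_len: int = 1,
                 prediction_threshold: Optional[float] = None,
                 conflict_policy: str = "hit_rate",
                 abstain_label: str = ABSTAIN,
                 class_order: Optional[List[str]] = None):
        self.min_support = min_support
        self.min_hit_rate = min_hit_rate
        self.max_loops = max_loops
        self.mining_scope = mining_scope
        self.selection_policy = selection_policy
        self.min_antecedent_len = min_antecedent_len
        self.prediction_threshold = prediction_threshold
        self.conflict_policy = conflict_policy
        self.abstain_label = abstain_label
        self.class_order = class_order

    def _params(self) -> RuleMiningParams:
        return RuleMiningParams(
            min_support=self.min_support,
            min_hit_rate=self.min_hit_rate,
            max_loops=self.max_loops,
            mining_scope=self.mining_scope,
            selection_policy=self.selection_policy,
            min_antecedent_len=self.min_antecedent_len,
        )

    def fit(self, X, y) -> "MFPTClassifier":
        db = _as_db(X, y)
        if not db.is_labeled():
            raise ValueError("y contains missing labels")
        observed = db.classes()
        if self.class_order is not None:
            unknown = set(observed) - set(self.class_order)
            if unknown:
                raise ValueError(f"labels {sorted(unknown)} not in class_order")
            classes = [c for c in self.class_order if c in observed]
        else:
            classes = observed
        self.model_ = train_model(db, classes, self._params())
        self.classes_ = np.array(sorted(observed), dtype=object)
        self.n_rules_ = self.model_.n_rules
        self.n_features_in_ = (
            np.asarray(X).shape[1] if isinstance(X, np.ndarray)
            or (len(X) and np.ndim(X) == 2) else None
        )
        return self

    def _threshold(self) -> float:
        return (
            self.min_hit_rate
            if self.prediction_threshold is None
            else self.prediction_threshold
        )

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        db = _as_db(X)
        preds, _ = predict_all(
            self.model_, db, self._threshold(), self.conflict_policy
        )
        return np.array(
            [
                self.abstain_label if p.predicted == ABSTAIN else p.predicted
                for p in preds
            ],
            dtype=object,
        )

    def decision_function(self, X) -> np.ndarray:
        """Per-class scores, shape (n_samples, n_classes); columns follow
        ``classes_``.  The score is the maximum training hit-rate over the
        class's firing rules (0 when none fires)."""
        check_is_fitted(self, "model_")
        db = _as_db(X)
        return np.column_stack(
            [class_scores(self.model_, db, c) for c in self.classes_]
        )
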