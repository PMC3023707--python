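"""Splits, accuracy, one-vs-rest ROC/AUC, k-fold cross-validation."""

import numpy as np
import pytest

from mfpt import (
    MultiClassModel,
    Rule,
    RuleMiningParams,
    RuleSet,
    Transaction,
    TransactionDB,
    predict_all,
)
from mfpt.classify import PredictionResult
from mfpt.evaluate import (
    SplitSpec,
    correct_rate,
    cross_validate,
    roc_one_vs_rest,
    split,
)
from mfpt.synthetic import benchmark_spec, generate


def _db_of(n, label="N"):
    return TransactionDB([Transaction(str(i), {1, i + 10}, label) for i in range(n)])


def _mixed_db(n):
    labels = ["C", "N", "M", "T", "E"]
    return TransactionDB(
        [Transaction(str(i), {1, i + 10}, labels[i % 5]) for i in range(n)]
    )


class TestSplit:
    def test_seventy_thirty_arithmetic(self):
        db = _mixed_db(1342)
        train, test = split(db, SplitSpec(0.7, seed=0, stratified=False))
        assert (len(train), len(test)) == (939, 403)
        assert {t.id for t in train} | {t.id for t in test} == {t.id for t in db}
        assert not ({t.id for t in train} & {t.id for t in test})

    def test_same_seed_same_split(self):
        db = _mixed_db(100)
        a = split(db, SplitSpec(0.7, seed=5))
        b = split(db, SplitSpec(0.7, seed=5))
        assert [t.id for t in a[0]] == [t.id for t in b[0]]

    def test_half_split_of_two(self):
        db = _mixed_db(2)
        train, test = split(db, SplitSpec(0.5, seed=0, stratified=False))
        assert len(train) == 1 and len(test) == 1

    def test_stratified_preserves_class_balance(self):
        db = _mixed_db(1000)
        train, _ = split(db, SplitSpec(0.7, seed=1, stratified=True))
        counts = {c: train.labels.count(c) for c in "CNMTE"}
        assert all(abs(v - 140) <= 1 for v in counts.values())

    def test_unlabeled_rejected(self):
        db = TransactionDB([Transaction("1", {1}), Transaction("2", {2})])
        with pytest.raises(ValueError, match="labeled"):
            split(db, SplitSpec())


class TestCorrectRate:
    def _preds(self, db, predicted):
        params = RuleMiningParams()
        rule = Rule(frozenset({1}), "N", 10, 8)
        return [
            PredictionResult(t.id, p, rule if p != "ABSTAIN" else None,
                             0.8 if p != "ABSTAIN" else 0.0)
            for t, p in zip(db, predicted)
        ]

    def test_all_correct(self):
        db = _db_of(4)
        assert correct_rate(self._preds(db, ["N"] * 4), db) == 1.0

    def test_half_correct(self):
        db = _db_of(10)
        preds = self._preds(db, ["N"] * 5 + ["ABSTAIN"] * 5)
        assert correct_rate(preds, db) == 0.5
        assert correct_rate(preds, db, abstain_is_error=False) == 1.0

    def test_id_mismatch_rejected(self):
        db = _db_of(3)
        preds = self._preds(db, ["N"] * 3)[:2]
        with pytest.raises(ValueError, match="ids"):
            correct_rate(preds, db)

    def test_planted_rules_bound_holdout_accuracy(self):
        # every transaction carries a planted rule whose hit-rates
        # (0.70-0.95) bound the achievable accuracy well above 0.75
        from mfpt import RuleMiningParams as RMP
        from mfpt import predict_all, train_model

        spec = benchmark_spec(seed=13, n=2000, coverage=400)  # no background
        db = generate(spec)
        train, test = split(db, SplitSpec(0.7, seed=13))
        model = train_model(train, list("CNMTE"), RMP(max_loops=2))
        preds, _ = predict_all(model, test, 0.5)
        assert correct_rate(preds, test) >= 0.75

    def test_majority_predictor_scores_majority_frequency(self):
        db = _mixed_db(50)
        preds = self._preds(db, ["N"] * 50)
        assert correct_rate(preds, db) == pytest.approx(
            db.labels.count("N") / 50
        )


def _score_model(rules_by_class):
    params = RuleMiningParams()
    return MultiClassModel(
        {c: RuleSet(c, rs, params) for c, rs in rules_by_class.items()},
        params, class_order=list(rules_by_class),
    )


class TestROC:
    def test_perfect_separator_has_auc_one(self):
        # rule {7} fires exactly on the positives
        model = _score_model({"N": [Rule(frozenset({7}), "N", 10, 9)]})
        db = TransactionDB(
            [Transaction(str(i), {7, 100 + i}, "N") for i in range(10)]
            + [Transaction(str(i + 10), {8, 100 + i}, "C") for i in range(10)]
        )
        fpr, tpr, auc = roc_one_vs_rest(model, db, "N")
        assert auc == pytest.approx(1.0)
        assert fpr[0] == 0.0 and tpr[-1] == 1.0

    def test_constant_scores_give_half(self):
        model = _score_model({"N": [Rule(frozenset({1}), "N", 10, 9)]})
        db = _mixed_db(40)  # every transaction contains item 1
        _, _, auc = roc_one_vs_rest(model, db, "N")
        assert auc == pytest.approx(0.5)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(11)
        # 2000 balanced transactions; rule items assigned at random
        rows = []
        for i in range(2000):
            items = {int(rng.integers(1, 40))}
            rows.append(Transaction(str(i), items, "N" if i % 2 else "C"))
        db = TransactionDB(rows)
        rules = [
            Rule(frozenset({k}), "N", 10, int(rng.integers(5, 11)))
            for k in range(1, 40)
        ]
        model = _score_model({"N": rules})
        _, _, auc = roc_one_vs_rest(model, db, "N")
        assert auc == pytest.approx(0.5, abs=0.04)

    def test_single_class_test_set_rejected(self):
        model = _score_model({"N": [Rule(frozenset({1}), "N", 10, 9)]})
        with pytest.raises(ValueError, match="AUC undefined"):
            roc_one_vs_rest(model, _db_of(5, "N"), "N")

    def test_curve_is_monotone_from_origin_to_one(self, benchmark,
                                                  benchmark_model):
        _, db, _ = benchmark
        fpr, tpr, auc = roc_one_vs_rest(benchmark_model, db, "M")
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert 0.0 <= auc <= 1.0


class TestCrossValidate:
    def test_fold_sizes_partition_1342(self):
        db = _mixed_db(1342)
        params = RuleMiningParams(max_loops=1)
        cv = cross_validate(db, 5, seed=0, params=params)
        assert sorted(cv.fold_sizes) == [268, 268, 268, 269, 269]
        assert sum(cv.fold_sizes) == 1342

    def test_folds_are_deterministic_and_variance_nonnegative(self):
        spec = benchmark_spec(seed=3, n=400, coverage=60)
        db = generate(spec)
        params = RuleMiningParams(max_loops=3)
        a = cross_validate(db, 4, seed=9, params=params)
        b = cross_validate(db, 4, seed=9, params=params)
        assert a.fold_accuracies == b.fold_accuracies
        assert a.variance >= 0.0
        assert a.mean == pytest.approx(float(np.mean(a.fold_accuracies)))
        assert a.variance == pytest.approx(float(np.var(a.fold_accuracies)))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            cross_validate(_mixed_db(3), 5, params=RuleMiningParams())
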