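"""FP-tree construction and FP-growth mining, anchored to the five-row
worked example and to exhaustive-enumeration oracle equivalence."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfpt import (
    MiningParams,
    Transaction,
    TransactionDB,
    brute_force_frequent,
    build_fptree,
    fp_growth,
    frequency_order,
)
from mfpt.fptree import insert_projected, patterns_as_dict, project_transaction


def random_db(rnd: random.Random, max_items: int = 10,
              max_transactions: int = 40) -> TransactionDB:
    items = list(range(1, rnd.randint(2, max_items + 1)))
    n = rnd.randint(1, max_transactions)
    return TransactionDB(
        [
            Transaction(str(i), rnd.sample(items, rnd.randint(1, len(items))))
            for i in range(n)
        ]
    )


class TestFrequencyOrder:
    def test_worked_example_order(self, worked_example_db, worked_example_params):
        order = frequency_order(worked_example_db, worked_example_params)
        assert order == [("F", 4), ("C", 4), ("A", 3), ("B", 3), ("M", 3)]

    def test_singleton(self):
        db = TransactionDB([Transaction("1", {"X"})])
        assert frequency_order(db, MiningParams(1)) == [("X", 1)]

    def test_nothing_frequent(self):
        db = TransactionDB(
            [Transaction("1", {"X"}), Transaction("2", {"Y"}), Transaction("3", {"Z"})]
        )
        assert frequency_order(db, MiningParams(2)) == []

    def test_default_tie_break_is_ascending_item(self):
        db = TransactionDB(
            [Transaction("1", {3, 1}), Transaction("2", {1, 3}), Transaction("3", {2})]
        )
        assert frequency_order(db, MiningParams(1)) == [(1, 2), (3, 2), (2, 1)]


class TestProjection:
    @pytest.mark.parametrize(
        "tid, expected",
        [(1, "FCAM"), (2, "FCABM"), (3, "FB"), (4, "CB"), (5, "FCAM")],
    )
    def test_worked_example_rows(self, worked_example_db, worked_example_params,
                                 tid, expected):
        tree_order = build_fptree(worked_example_db, worked_example_params).item_order
        t = worked_example_db[tid - 1]
        assert project_transaction(t, tree_order) == tuple(expected)

    def test_no_frequent_items_projects_empty(self):
        t = Transaction("x", {"Q", "Z"})
        assert project_transaction(t, {"F": 0, "C": 1}) == ()


class TestInsertion:
    def test_shared_prefix_counts(self, worked_example_db, worked_example_params):
        # first three insertions: F starts every projection, so (F:3)
        tree = build_fptree(worked_example_db[:3], worked_example_params)
        assert tree.root.children["F"].count == 3

    def test_repeated_path_increments_every_count(self):
        db = TransactionDB(
            [Transaction("1", {"F", "C", "A", "M"}),
             Transaction("2", {"F", "C", "A", "M"})]
        )
        tree = build_fptree(db, MiningParams(1, item_order_override="FCAM"))
        node, counts = tree.root, []
        while node.children:
            (node,) = node.children.values()
            counts.append(node.count)
        assert counts == [2, 2, 2, 2]

    def test_out_of_order_items_rejected(self, worked_example_db,
                                         worked_example_params):
        tree = build_fptree(worked_example_db, worked_example_params)
        with pytest.raises(ValueError, match="order"):
            tree.insert(["A", "F"])

    def test_empty_projection_leaves_tree_unchanged(self, worked_example_db,
                                                    worked_example_params):
        tree = build_fptree(worked_example_db, worked_example_params)
        before = {i: tree.header[i].support for i in tree.header}
        insert_projected(tree, ())
        assert {i: tree.header[i].support for i in tree.header} == before


class TestBuildTree:
    def test_worked_example_has_two_root_branches(self, worked_example_db,
                                                  worked_example_params):
        tree = build_fptree(worked_example_db, worked_example_params)
        assert set(tree.root.children) == {"F", "C"}
        assert tree.root.children["F"].count == 4
        assert tree.root.children["C"].count == 1

    def test_second_branch_appears_with_fourth_transaction(
            self, worked_example_db, worked_example_params):
        assert len(build_fptree(worked_example_db[:3],
                                worked_example_params).root.children) == 1
        assert len(build_fptree(worked_example_db[:4],
                                worked_example_params).root.children) == 2

    def test_empty_db_builds_bare_root(self):
        tree = build_fptree(TransactionDB([]), MiningParams(1))
        assert tree.root.children == {} and tree.header == {}

    def test_identical_transactions_build_single_path(self):
        db = TransactionDB([Transaction(str(i), {1, 2, 3}) for i in range(7)])
        tree = build_fptree(db, MiningParams(1))
        node, depth = tree.root, 0
        while node.children:
            (node,) = node.children.values()
            assert node.count == 7
            depth += 1
        assert depth == 3

    def test_header_conservation(self, worked_example_db, worked_example_params):
        tree = build_fptree(worked_example_db, worked_example_params)
        for item, entry in tree.header.items():
            assert sum(n.count for n in entry.chain()) == entry.support

    def test_child_count_never_exceeds_parent(self, worked_example_db,
                                              worked_example_params):
        tree = build_fptree(worked_example_db, worked_example_params)
        stack = [tree.root]
        while stack:
            node = stack.pop()
            for child in node.children.values():
                if not node.is_root():
                    assert child.count <= node.count
                stack.append(child)


class TestFPGrowth:
    def test_worked_example_contains_full_path_pattern(
            self, worked_example_db, worked_example_params):
        pats = patterns_as_dict(
            fp_growth(build_fptree(worked_example_db, worked_example_params),
                      worked_example_params)
        )
        assert pats[frozenset("FCAM")] == 3

    def test_single_transaction_yields_power_set(self):
        db = TransactionDB([Transaction("1", {"X", "Y"})])
        p = MiningParams(1)
        pats = patterns_as_dict(fp_growth(build_fptree(db, p), p))
        assert pats == {
            frozenset("X"): 1, frozenset("Y"): 1, frozenset("XY"): 1,
        }

    def test_support_anti_monotonicity(self, worked_example_db,
                                       worked_example_params):
        pats = patterns_as_dict(
            fp_growth(build_fptree(worked_example_db, worked_example_params),
                      worked_example_params)
        )
        for itemset, support in pats.items():
            for item in itemset:
                if len(itemset) > 1:
                    sub = itemset - {item}
                    assert pats[sub] >= support

    def test_pattern_set_invariant_under_tie_break_order(self):
        rnd = random.Random(7)
        for _ in range(20):
            db = random_db(rnd, max_items=8, max_transactions=20)
            p1 = MiningParams(2)
            items = sorted(db.distinct_items())
            rnd.shuffle(items)
            p2 = MiningParams(2, item_order_override=items)
            assert patterns_as_dict(fp_growth(build_fptree(db, p1), p1)) == \
                patterns_as_dict(fp_growth(build_fptree(db, p2), p2))


class TestBruteForceOracle:
    def test_power_set_count(self):
        db = TransactionDB([Transaction("1", {1, 2, 3, 4})])
        assert len(brute_force_frequent(db, MiningParams(1))) == 2 ** 4 - 1

    def test_support_above_db_size_yields_nothing(self):
        db = TransactionDB([Transaction("1", {1}), Transaction("2", {1})])
        assert brute_force_frequent(db, MiningParams(3)) == []

    def test_refuses_large_alphabets(self):
        db = TransactionDB([Transaction("1", set(range(25)))])
        with pytest.raises(ValueError, match="20 distinct"):
            brute_force_frequent(db, MiningParams(1))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.sets(st.integers(1, 8), min_size=1, max_size=8),
            min_size=1, max_size=25,
        ),
        min_support=st.integers(1, 3),
    )
    def test_fp_growth_equals_oracle(self, data, min_support):
        db = TransactionDB(
            [Transaction(str(i), items) for i, items in enumerate(data)]
        )
        p = MiningParams(min_support)
        assert patterns_as_dict(fp_growth(build_fptree(db, p), p)) == \
            patterns_as_dict(brute_force_frequent(db, p))
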