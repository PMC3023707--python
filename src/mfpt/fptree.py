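"""Frequent-pattern tree construction and FP-growth itemset mining.

The FP-tree is a prefix tree over frequency-ordered projections of the
transactions.  Each node stores an item, a count (the number of transactions
whose projection passes through the node) and a node-link to the next node
carrying the same item; a header table keeps, for every frequent item, its
total support and the head of its node-link chain.  Two database scans build
the tree: the first counts item supports, the second inserts each
transaction's frequent items in frequency-descending order.

``fp_growth`` then mines the complete set of frequent itemsets from the tree
by recursively building conditional pattern bases and conditional trees
(Han-style pattern growth).  ``brute_force_frequent`` is an independent
exhaustive-enumeration oracle used to verify the miner on small inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from ._transactions import Item, Transaction, TransactionDB

ROOT = object()  # distinguished root marker ("null" root)


@dataclass
class MiningParams:
    """Parameters of the frequent-pattern miner.

    min_support is an absolute transaction count (not a fraction).
    item_order_override, when given, is a sequence of items whose position
    breaks support ties in the frequency-descending order; items not listed
    fall back to the default tie-break (ascending item value).
    """

    min_support: int = 2
    item_order_override: Optional[Sequence[Item]] = None

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError(f"min_support must be >= 1, got {self.min_support}")


@dataclass(frozen=True)
class Pattern:
    """A frequent itemset together with its exact support."""

    itemset: frozenset
    support: int

    def __init__(self, itemset, support: int):
        object.__setattr__(self, "itemset", frozenset(itemset))
        object.__setattr__(self, "support", int(support))


class FPNode:
    """Tree node: item, count, parent link, children map, same-item node-link."""

    __slots__ = ("item", "count", "parent", "children", "node_link")

    def __init__(self, item, count: int = 0, parent: Optional["FPNode"] = None):
        self.item = item
        self.count = count
        self.parent = parent
        self.children: Dict[Item, FPNode] = {}
        self.node_link: Optional[FPNode] = None

    def is_root(self) -> bool:
        return self.item is ROOT

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        label = "null" if self.is_root() else repr(self.item)
        return f"FPNode({label}:{self.count})"


@dataclass
class HeaderEntry:
    item: Item
    support: int
    head: Optional[FPNode] = None
    _tail: Optional[FPNode] = None

    def chain(self) -> List[FPNode]:
        out, node = [], self.head
        while node is not None:
            out.append(node)
            node = node.node_link
        return out


class FPTree:
    """Prefix tree with a frequent-item header table.

    ``item_order`` maps each frequent item to its rank in the
    frequency-descending order; projections must be inserted in that order.
    Node-link chains are extended in node-creation order.
    """

    def __init__(self, order: Sequence[Tuple[Item, int]]):
        self.root = FPNode(ROOT)
        self.header: Dict[Item, HeaderEntry] = {
            item: HeaderEntry(item, support) for item, support in order
        }
        self.item_order: Dict[Item, int] = {
            item: rank for rank, (item, _) in enumerate(order)
        }

    def insert(self, ordered_items: Sequence[Item], count: int = 1) -> None:
        """Insert one projected transaction (see :func:`insert_projected`)."""
        ranks = [self.item_order[i] for i in ordered_items]
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            raise ValueError(
                f"items {list(ordered_items)} are not in the tree's frequency order"
            )
        node = self.root
        for item in ordered_items:
            child = node.children.get(item)
            if child is None:
                child = FPNode(item, 0, parent=node)
                node.children[item] = child
                entry = self.header[item]
                if entry.head is None:
                    entry.head = entry._tail = child
                else:
                    entry._tail.node_link = child
                    entry._tail = child
            child.count += count
            node = child

    def paths_to(self, item: Item) -> List[Tuple[List[Item], int]]:
        """Prefix paths of every node carrying ``item`` (the conditional
        pattern base of ``item``), with the node's count."""
        out = []
        for node in self.header[item].chain():
            path = []
            up = node.parent
            while up is not None and not up.is_root():
                path.append(up.item)
                up = up.parent
            out.append((path[::-1], node.count))
        return out


def frequency_order(db: TransactionDB, params: MiningParams) -> List[Tuple[Item, int]]:
    """Frequent items of ``db`` sorted by support descending.

    Ties are broken by position in ``params.item_order_override`` when given,
    otherwise by ascending item value.  Deterministic for fixed input.
    """
    counts: Dict[Item, int] = {}
    for t in db:
        for item in t.items:
            counts[item] = counts.get(item, 0) + 1
    frequent = [(i, c) for i, c in counts.items() if c >= params.min_support]
    if params.item_order_override is not None:
        pos = {item: k for k, item in enumerate(params.item_order_override)}
        nsup = len(pos)

        def key(pair):
            item, c = pair
            return (-c, pos.get(item, nsup), _sort_key(item))

    else:

        def key(pair):
            item, c = pair
            return (-c, _sort_key(item))

    return sorted(frequent, key=key)


def _sort_key(item):
    # items within one database share a type; the type name guards mixed use
    return (type(item).__name__, item)


def project_transaction(t: Transaction, order: Dict[Item, int]) -> Tuple[Item, ...]:
    """Restrict a transaction to frequent items, sorted frequency-descending."""
    return tuple(sorted((i for i in t.items if i in order), key=order.__getitem__))


def insert_projected(tree: FPTree, ordered_items: Sequence[Item]) -> FPTree:
    """Insert one ordered projection into the tree (in place; returns tree).

    Counts along the shared prefix increase by one and a single new chain of
    count-1 nodes is created for the unshared suffix.  Rejects item lists
    that violate the tree's frequency order.
    """
    if ordered_items:
        tree.insert(ordered_items, 1)
    return tree


def build_fptree(db: TransactionDB, params: MiningParams) -> FPTree:
    """Two-scan FP-tree construction over ``db`` in scan order."""
    order = frequency_order(db, params)
    tree = FPTree(order)
    for t in db:
        insert_projected(tree, project_transaction(t, tree.item_order))
    return tree


def fp_growth(tree: FPTree, params: MiningParams) -> List[Pattern]:
    """Mine every itemset with support >= min_support from an FP-tree.

    The result is a duplicate-free list of patterns with exact supports and
    does not depend on the tie-breaking order used to build the tree.
    """
    out: List[Pattern] = []
    _growth(tree, (), params.min_support, out)
    return out


def _growth(tree: FPTree, suffix: Tuple[Item, ...], min_support: int,
            out: List[Pattern]) -> None:
    path = _single_path(tree)
    if path is not None:
        # single-path shortcut: every combination of path items is frequent
        # with support equal to the count of its deepest member
        for k in range(1, len(path) + 1):
            for combo in itertools.combinations(path, k):
                out.append(Pattern(
                    tuple(i for i, _ in combo) + suffix, combo[-1][1]))
        return
    # process header items least-frequent first (reverse of the tree order)
    items = sorted(tree.header, key=tree.item_order.__getitem__, reverse=True)
    for item in items:
        entry = tree.header[item]
        new_suffix = (item,) + suffix
        out.append(Pattern(new_suffix, entry.support))
        base = tree.paths_to(item)
        cond = _conditional_tree(base, min_support)
        if cond is not None:
            _growth(cond, new_suffix, min_support, out)


def _single_path(tree: FPTree) -> Optional[List[Tuple[Item, int]]]:
    path, node = [], tree.root
    while node.children:
        if len(node.children) > 1:
            return None
        (node,) = node.children.values()
        path.append((node.item, node.count))
    return path


def _conditional_tree(base: List[Tuple[List[Item], int]],
                      min_support: int) -> Optional[FPTree]:
    counts: Dict[Item, int] = {}
    for path, cnt in base:
        for item in path:
            counts[item] = counts.get(item, 0) + cnt
    order = sorted(
        ((i, c) for i, c in counts.items() if c >= min_support),
        key=lambda p: (-p[1], _sort_key(p[0])),
    )
    if not order:
        return None
    tree = FPTree(order)
    rank = tree.item_order
    for path, cnt in base:
        kept = sorted((i for i in path if i in rank), key=rank.__getitem__)
        if kept:
            tree.insert(kept, cnt)
    return tree


_BRUTE_FORCE_MAX_ITEMS = 20


def brute_force_frequent(db: TransactionDB, params: MiningParams) -> List[Pattern]:
    """Exhaustive frequent-itemset enumeration (verification oracle).

    Counts the support of every non-empty subset of the frequent-item
    alphabet by direct scan.  Refuses databases with more than
    20 distinct items, where enumeration becomes unreasonable.
    """
    distinct = db.distinct_items()
    if len(distinct) > _BRUTE_FORCE_MAX_ITEMS:
        raise ValueError(
            f"brute-force oracle limited to {_BRUTE_FORCE_MAX_ITEMS} distinct "
            f"items, got {len(distinct)}"
        )
    singles: Dict[Item, int] = {}
    for t in db:
        for item in t.items:
            singles[item] = singles.get(item, 0) + 1
    alphabet = sorted(
        (i for i, c in singles.items() if c >= params.min_support), key=_sort_key
    )
    sets = [t.items for t in db]
    out: List[Pattern] = []
    for k in range(1, len(alphabet) + 1):
        for combo in itertools.combinations(alphabet, k):
            cset = frozenset(combo)
            support = sum(1 for s in sets if cset <= s)
            if support >= params.min_support:
                out.append(Pattern(cset, support))
    return out


def patterns_as_dict(patterns) -> Dict[frozenset, int]:
    """Canonical comparison form: itemset -> support."""
    out: Dict[frozenset, int] = {}
    for p in patterns:
        if p.itemset in out and out[p.itemset] != p.support:
            raise ValueError(f"conflicting supports for {set(p.itemset)}")
        out[p.itemset] = p.support
    return out
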