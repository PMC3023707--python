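"""Transaction containers shared by the mining, classification and I/O layers.

A *transaction* is one sample (one protein, in the localization profile)
represented as a set of item codes.  Item codes are positive integers in the
application profile, but the mining core only requires items to be hashable
and mutually comparable, so small worked examples can use single-letter
items.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, Optional, Sequence

Item = Hashable


@dataclass(frozen=True)
class Transaction:
    """One sample: an id, a duplicate-free item set, an optional class label."""

    id: str
    items: frozenset
    label: Optional[str] = None

    def __init__(self, id: str, items: Iterable[Item], label: Optional[str] = None):
        object.__setattr__(self, "id", str(id))
        object.__setattr__(self, "items", frozenset(items))
        object.__setattr__(self, "label", label)

    def contains(self, itemset: Iterable[Item]) -> bool:
        return frozenset(itemset) <= self.items


@dataclass
class TransactionDB:
    """An ordered list of transactions with unique ids.

    Order is significant: FP-tree construction inserts projections in scan
    order, so two databases with the same multiset of transactions but a
    different order may build different (equally valid) trees.
    """

    transactions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.id for t in self.transactions]
        if len(set(ids)) != len(ids):
            seen: set = set()
            dupes = sorted({i for i in ids if i in seen or seen.add(i)})
            raise ValueError(f"duplicate transaction ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.transactions)

    def __iter__(self) -> Iterator[Transaction]:
        return iter(self.transactions)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return TransactionDB(self.transactions[i])
        return self.transactions[i]

    @property
    def labels(self) -> list:
        return [t.label for t in self.transactions]

    def is_labeled(self) -> bool:
        return bool(self.transactions) and all(
            t.label is not None for t in self.transactions
        )

    def classes(self) -> list:
        return sorted({t.label for t in self.transactions if t.label is not None})

    def subset(self, indices: Sequence[int]) -> "TransactionDB":
        return TransactionDB([self.transactions[i] for i in indices])

    def with_label(self, label: str) -> "TransactionDB":
        return TransactionDB([t for t in self.transactions if t.label == label])

    def distinct_items(self) -> set:
        out: set = set()
        for t in self.transactions:
            out |= t.items
        return out
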