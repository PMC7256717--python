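"""Level-wise Apriori mining of frequent itemsets.

The miner exploits downward closure (every subset of a frequent itemset is
frequent): level k+1 candidates are generated by joining frequent k-itemsets
that share a (k-1)-prefix, candidates with any infrequent k-subset are pruned
before counting, and counting uses bitset subset tests against each
transaction. Support thresholds are compared exactly in rational arithmetic,
so an itemset whose support equals the minimum is retained — no float
boundary surprises.

:func:`brute_force_frequent` is a deliberately naive oracle that enumerates
every subset of the universe; it exists so the miner can be verified against
an implementation too simple to be wrong.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Iterator

from .errors import GuardError, ValidationError
from .transactions import TransactionDB


def _as_fraction(value: float | Fraction | str | int) -> Fraction:
    # floats go through their decimal repr so 0.2 means exactly 1/5
    if isinstance(value, float):
        return Fraction(str(value))
    return Fraction(value)


@dataclass(frozen=True)
class MiningParams:
    """Thresholds and structural conventions for mining and rule generation.

    Parameters
    ----------
    min_support:
        Minimum itemset support as a fraction of transactions, inclusive.
    min_confidence:
        Minimum rule confidence, inclusive.
    max_len:
        Maximum itemset size mined (and hence maximum total rule length).
    consequent_size:
        Number of items on a rule's right-hand side.
    min_antecedent_size:
        Minimum left-hand-side size; 0 permits rules with an empty
        antecedent, whose confidence is the consequent's own support.
    """

    min_support: Fraction = Fraction(1, 5)
    min_confidence: Fraction = Fraction(4, 5)
    max_len: int = 5
    consequent_size: int = 1
    min_antecedent_size: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "min_support", _as_fraction(self.min_support))
        object.__setattr__(self, "min_confidence", _as_fraction(self.min_confidence))
        if not 0 < self.min_support <= 1:
            raise ValidationError(f"min_support must be in (0, 1], got {self.min_support}")
        if not 0 < self.min_confidence <= 1:
            raise ValidationError(f"min_confidence must be in (0, 1], got {self.min_confidence}")
        if self.max_len < 1:
            raise ValidationError(f"max_len must be positive, got {self.max_len}")
        if self.consequent_size < 1:
            raise ValidationError(f"consequent_size must be positive, got {self.consequent_size}")
        if self.min_antecedent_size < 0:
            raise ValidationError(f"min_antecedent_size must be >= 0, got {self.min_antecedent_size}")


@dataclass(frozen=True)
class Itemset:
    """A frequent itemset with its exact occurrence count and support."""

    items: tuple[str, ...]
    count: int
    support: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(sorted(self.items)))
        if not self.items:
            raise ValidationError("itemset must be non-empty")
        if len(set(self.items)) != len(self.items):
            raise ValidationError(f"duplicate items in {self.items}")

    def __len__(self) -> int:
        return len(self.items)

    def __str__(self) -> str:
        return "{" + ",".join(self.items) + "}"


@dataclass(frozen=True)
class FrequentItemsetResult:
    """All frequent itemsets for one (db, params) pair, canonically ordered."""

    itemsets: tuple[Itemset, ...]
    params: MiningParams
    db_n: int
    _counts: dict[frozenset[str], int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.itemsets, key=lambda s: (len(s.items), s.items)))
        object.__setattr__(self, "itemsets", ordered)
        object.__setattr__(self, "_counts", {frozenset(s.items): s.count for s in ordered})

    def __len__(self) -> int:
        return len(self.itemsets)

    def __iter__(self) -> Iterator[Itemset]:
        return iter(self.itemsets)

    def __contains__(self, items: Iterable[str]) -> bool:
        return frozenset(items) in self._counts

    def count_of(self, items: Iterable[str]) -> int:
        """Occurrence count of a frequent itemset; KeyError if not frequent."""
        return self._counts[frozenset(items)]

    def support_of(self, items: Iterable[str]) -> Fraction:
        return Fraction(self.count_of(items), self.db_n)

    def by_size(self, k: int) -> list[Itemset]:
        return [s for s in self.itemsets if len(s.items) == k]


def _transaction_masks(db: TransactionDB) -> tuple[dict[str, int], list[int]]:
    index = {item: i for i, item in enumerate(db.universe)}
    masks = [sum(1 << index[item] for item in t.items) for t in db]
    return index, masks


def support_count(itemset: Iterable[str], db: TransactionDB) -> int:
    """Number of transactions whose item set is a superset of ``itemset``."""
    target = frozenset(itemset)
    if not target:
        raise ValidationError("support_count requires a non-empty itemset")
    return sum(1 for t in db if target <= t.items)


def mine_frequent(db: TransactionDB, params: MiningParams | None = None) -> FrequentItemsetResult:
    """Mine all itemsets with support >= ``params.min_support`` (inclusive).

    Level-wise Apriori: L1 from single-item counts; C(k+1) by joining pairs
    of Lk sharing their first k-1 items (canonical alphabetical order);
    candidates with any infrequent k-subset pruned before counting. Stops
    when a level is empty or ``max_len`` is reached. A threshold too high
    for any single item yields an empty result, not an error.
    """
    if params is None:
        params = MiningParams()
    if db.n == 0:
        raise ValidationError("cannot mine an empty database")
    index, masks = _transaction_masks(db)
    n = db.n

    def frequent(count: int) -> bool:
        return Fraction(count, n) >= params.min_support

    # L1
    item_counts: dict[str, int] = {item: 0 for item in db.universe}
    for t in db:
        for item in t.items:
            item_counts[item] += 1
    level: dict[tuple[str, ...], int] = {
        (item,): c for item, c in sorted(item_counts.items()) if frequent(c)
    }
    found: dict[tuple[str, ...], int] = dict(level)
    frequent_sets = {frozenset(k) for k in level}
    k = 1
    while level and k < params.max_len:
        candidates: list[tuple[str, ...]] = []
        keys = sorted(level)
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break  # sorted order: shared (k-1)-prefixes are contiguous
                cand = a + (b[-1],)
                if all(frozenset(cand[:j] + cand[j + 1 :]) in frequent_sets for j in range(k + 1)):
                    candidates.append(cand)
        level = {}
        for cand in candidates:
            mask = 0
            for item in cand:
                mask |= 1 << index[item]
            count = sum(1 for m in masks if mask & m == mask)
            if frequent(count):
                level[cand] = count
        found.update(level)
        frequent_sets.update(frozenset(c) for c in level)
        k += 1

    itemsets = tuple(
        Itemset(items, count, Fraction(count, n)) for items, count in sorted(found.items())
    )
    return FrequentItemsetResult(itemsets, params, n)


def brute_force_frequent(
    db: TransactionDB, params: MiningParams | None = None, max_universe: int = 20
) -> FrequentItemsetResult:
    """Exhaustive-enumeration oracle equivalent to :func:`mine_frequent`.

    Enumerates every subset of the universe up to ``max_len`` and counts
    support directly, with no pruning. Guarded against combinatorial
    explosion: a universe larger than ``max_universe`` raises
    :class:`~acurules.errors.GuardError`.
    """
    if params is None:
        params = MiningParams()
    if db.n == 0:
        raise ValidationError("cannot mine an empty database")
    if len(db.universe) > max_universe:
        raise GuardError(
            f"universe of {len(db.universe)} items exceeds the brute-force guard ({max_universe})"
        )
    n = db.n
    itemsets = []
    for size in range(1, min(params.max_len, len(db.universe)) + 1):
        for combo in combinations(db.universe, size):
            count = support_count(combo, db)
            if count and Fraction(count, n) >= params.min_support:
                itemsets.append(Itemset(combo, count, Fraction(count, n)))
    return FrequentItemsetResult(tuple(itemsets), params, n)
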