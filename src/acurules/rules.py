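"""Association-rule generation, metrics, ranking and querying.

A rule X => Y states that prescriptions containing the antecedent X tend to
also contain the consequent Y (co-occurrence, not causality). Four metrics
are attached to every rule, all exact rationals of transaction counts:

* support        — P(X and Y), the joint fraction of transactions;
* confidence     — P(Y | X) = supp(X and Y) / supp(X);
* expected confidence — P(Y), the consequent's marginal support, i.e. the
  confidence a rule would have if X carried no information about Y;
* lift           — confidence / expected confidence; 1 under independence.

Because metrics are exact :class:`~fractions.Fraction` values, the algebraic
identities ``lift * expected_confidence == confidence`` and
``confidence * supp(LHS) == support`` hold exactly, and lift is symmetric
between a rule and its reciprocal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Iterator

from .apriori import FrequentItemsetResult, Itemset, MiningParams
from .errors import ValidationError
from .transactions import TransactionDB


@dataclass(frozen=True)
class AssociationRule:
    """An antecedent => consequent pair with its four metrics."""

    antecedent: tuple[str, ...]
    consequent: tuple[str, ...]
    joint_count: int
    support: Fraction
    confidence: Fraction
    expected_confidence: Fraction
    lift: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "antecedent", tuple(sorted(self.antecedent)))
        object.__setattr__(self, "consequent", tuple(sorted(self.consequent)))
        if not self.consequent:
            raise ValidationError("rule consequent must be non-empty")
        if set(self.antecedent) & set(self.consequent):
            raise ValidationError(
                f"antecedent {self.antecedent} and consequent {self.consequent} overlap"
            )

    @property
    def key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return (self.antecedent, self.consequent)

    def __str__(self) -> str:
        lhs = "{" + ",".join(self.antecedent) + "}"
        rhs = "{" + ",".join(self.consequent) + "}"
        return f"{lhs} => {rhs}"


@dataclass(frozen=True)
class RuleSet:
    """All rules meeting the thresholds for one (db, params) pair."""

    rules: tuple[AssociationRule, ...]
    params: MiningParams
    db_n: int
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        index = {r.key: r for r in self.rules}
        if len(index) != len(self.rules):
            raise ValidationError("duplicate (antecedent, consequent) pairs in rule set")
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self) -> Iterator[AssociationRule]:
        return iter(self.rules)

    def get(self, antecedent: Iterable[str], consequent: Iterable[str]) -> AssociationRule | None:
        return self._index.get((tuple(sorted(antecedent)), tuple(sorted(consequent))))

    def __contains__(self, key: tuple[Iterable[str], Iterable[str]]) -> bool:
        lhs, rhs = key
        return self.get(lhs, rhs) is not None


def generate_rules(
    freq: FrequentItemsetResult, db: TransactionDB, params: MiningParams | None = None
) -> RuleSet:
    """Emit every threshold-passing split of every frequent itemset.

    For each frequent itemset Z and each subset R of Z with
    ``|R| == consequent_size``, the rule (Z \\ R) => R is emitted when the
    antecedent is large enough and confidence meets ``min_confidence``
    (support >= ``min_support`` is inherited from Z being frequent). With
    ``min_antecedent_size = 0``, single-item frequent sets also yield
    {} => {item} rules whose confidence equals the item's own support.
    """
    if params is None:
        params = freq.params
    if params.min_support != freq.params.min_support:
        raise ValidationError(
            f"rule params min_support {params.min_support} does not match the "
            f"support threshold the itemsets were mined at ({freq.params.min_support})"
        )
    if db is not None and db.n != freq.db_n:
        raise ValidationError("database does not match the one the itemsets were mined from")
    n = freq.db_n
    rules = []
    min_size = params.min_antecedent_size + params.consequent_size
    for zset in freq:
        if len(zset.items) < max(min_size, params.consequent_size):
            continue
        for rhs in combinations(zset.items, params.consequent_size):
            lhs = tuple(item for item in zset.items if item not in rhs)
            if len(lhs) < params.min_antecedent_size:
                continue
            lhs_count = n if not lhs else freq.count_of(lhs)
            confidence = Fraction(zset.count, lhs_count)
            if confidence < params.min_confidence:
                continue
            expected = Fraction(freq.count_of(rhs), n)
            rules.append(
                AssociationRule(
                    antecedent=lhs,
                    consequent=rhs,
                    joint_count=zset.count,
                    support=zset.support,
                    confidence=confidence,
                    expected_confidence=expected,
                    lift=confidence / expected,
                )
            )
    rules.sort(key=lambda r: (len(r.antecedent) + len(r.consequent), r.antecedent, r.consequent))
    return RuleSet(tuple(rules), params, n)


def mine_rules(db: TransactionDB, params: MiningParams | None = None) -> RuleSet:
    """Convenience: mine frequent itemsets then generate rules in one call."""
    from .apriori import mine_frequent

    if params is None:
        params = MiningParams()
    return generate_rules(mine_frequent(db, params), db, params)


def _rank_key(rule: AssociationRule):
    return (-rule.support, -rule.confidence, -rule.lift, rule.antecedent, rule.consequent)


def rank_rules(
    ruleset: RuleSet, k: int, with_ties: bool = False
) -> list[AssociationRule] | tuple[list[AssociationRule], list[AssociationRule]]:
    """Top-``k`` rules by support desc, then confidence desc, then lift desc.

    Remaining ties are broken canonically (alphabetical antecedent, then
    consequent) so the order is deterministic. With ``with_ties=True`` also
    returns the full (support, confidence, lift) tie group straddling the
    cut, so callers can see when the k-th place is not unique.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    ordered = sorted(ruleset, key=_rank_key)
    top = ordered[:k]
    if not with_ties:
        return top
    ties: list[AssociationRule] = []
    if len(ordered) > k:
        metric = lambda r: (r.support, r.confidence, r.lift)  # noqa: E731
        boundary = metric(ordered[k - 1])
        if metric(ordered[k]) == boundary:
            ties = [r for r in ordered if metric(r) == boundary]
    return top, ties


def query_rules(
    ruleset: RuleSet,
    lhs_filter: Iterable[str] = (),
    rhs_filter: Iterable[str] = (),
) -> RuleSet:
    """Rules whose antecedent contains ``lhs_filter`` and consequent contains
    ``rhs_filter`` (either filter empty matches everything)."""
    lhs_req, rhs_req = frozenset(lhs_filter), frozenset(rhs_filter)
    matched = tuple(
        r for r in ruleset if lhs_req <= set(r.antecedent) and rhs_req <= set(r.consequent)
    )
    return RuleSet(matched, ruleset.params, ruleset.db_n)


def count_rules(ruleset: RuleSet) -> int:
    """Number of rules in the set."""
    return len(ruleset)
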