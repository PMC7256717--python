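"""Tabular summary exports: item frequencies, rule scatter data, grouped rules.

Everything the analysis reports is emitted as plain data (CSV/JSON) with
metrics rendered to 7 significant decimal places; plotting, if wanted, is a
thin optional layer on top of these tables and never load-bearing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import pandas as pd

from .apriori import FrequentItemsetResult
from .errors import ValidationError
from .rules import AssociationRule, RuleSet
from .transactions import FrequencyTable


def fmt7(value: Fraction | float) -> str:
    """Render a metric with 7 decimal places (``0.6666667``, ``1.2000000``)."""
    return f"{float(value):.7f}"


def _join(items: tuple[str, ...]) -> str:
    return "+".join(items)


def export_frequencies(table: FrequencyTable, path: str | Path) -> int:
    """Write the item frequency ranking as ``item,count`` CSV; returns row count."""
    rows = table.ranking()
    pd.DataFrame(rows, columns=["item", "count"]).to_csv(path, index=False)
    return len(rows)


def export_itemsets(freq: FrequentItemsetResult, path: str | Path) -> int:
    """Write the frequent-itemset report (items joined by ``+``, size, count, support)."""
    rows = [
        {"items": _join(s.items), "size": len(s.items), "count": s.count, "support": fmt7(s.support)}
        for s in freq
    ]
    pd.DataFrame(rows, columns=["items", "size", "count", "support"]).to_csv(path, index=False)
    return len(rows)


def rules_to_frame(ruleset: RuleSet) -> pd.DataFrame:
    """Full rule report as a DataFrame with 7-digit metric strings."""
    rows = [
        {
            "lhs": _join(r.antecedent),
            "rhs": _join(r.consequent),
            "joint_count": r.joint_count,
            "support": fmt7(r.support),
            "confidence": fmt7(r.confidence),
            "expected_confidence": fmt7(r.expected_confidence),
            "lift": fmt7(r.lift),
        }
        for r in ruleset
    ]
    columns = ["lhs", "rhs", "joint_count", "support", "confidence", "expected_confidence", "lift"]
    return pd.DataFrame(rows, columns=columns)


def export_rules(ruleset: RuleSet, path: str | Path) -> int:
    """Write the full rule report CSV; returns the number of rules written."""
    frame = rules_to_frame(ruleset)
    frame.to_csv(path, index=False)
    return len(frame)


def export_rules_json(ruleset: RuleSet, path: str | Path) -> int:
    """JSON export mirroring the CSV schema."""
    records = rules_to_frame(ruleset).to_dict(orient="records")
    Path(path).write_text(json.dumps(records, indent=1) + "\n", encoding="utf-8")
    return len(records)


def export_scatter(ruleset: RuleSet, path: str | Path) -> int:
    """Write one ``(lhs, rhs, support, confidence, lift)`` row per rule.

    This is the data behind the usual support/confidence scatter shaded by
    lift; the row count equals the rule count by construction.
    """
    if len(ruleset) == 0:
        raise ValidationError("cannot export a scatter for an empty rule set")
    rows = [
        {
            "lhs": _join(r.antecedent),
            "rhs": _join(r.consequent),
            "support": fmt7(r.support),
            "confidence": fmt7(r.confidence),
            "lift": fmt7(r.lift),
        }
        for r in ruleset
    ]
    pd.DataFrame(rows, columns=["lhs", "rhs", "support", "confidence", "lift"]).to_csv(
        path, index=False
    )
    return len(rows)


@dataclass(frozen=True)
class RuleGroup:
    """Rules sharing one consequent, with group-level metric ranges."""

    consequent: tuple[str, ...]
    members: tuple[AssociationRule, ...]

    @property
    def max_support(self) -> Fraction:
        return max(r.support for r in self.members)

    @property
    def min_support(self) -> Fraction:
        return min(r.support for r in self.members)

    @property
    def max_confidence(self) -> Fraction:
        return max(r.confidence for r in self.members)

    @property
    def min_confidence(self) -> Fraction:
        return min(r.confidence for r in self.members)

    @property
    def mean_lift(self) -> Fraction:
        return sum(r.lift for r in self.members) / len(self.members)


@dataclass(frozen=True)
class GroupedRuleSummary:
    """Partition of a rule set by consequent, ordered by best member support."""

    groups: tuple[RuleGroup, ...]

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)

    def group_for(self, consequent) -> RuleGroup | None:
        key = tuple(sorted(consequent))
        for g in self.groups:
            if g.consequent == key:
                return g
        return None


def group_rules(ruleset: RuleSet) -> GroupedRuleSummary:
    """Partition rules by identical consequent.

    Every rule lands in exactly one group; groups are ordered by their best
    member's support descending (ties by consequent alphabetically), so the
    leading groups are the consequents of the strongest rules.
    """
    buckets: dict[tuple[str, ...], list[AssociationRule]] = {}
    for r in ruleset:
        buckets.setdefault(r.consequent, []).append(r)
    groups = [RuleGroup(cons, tuple(members)) for cons, members in buckets.items()]
    groups.sort(key=lambda g: (-g.max_support, g.consequent))
    return GroupedRuleSummary(tuple(groups))


def export_grouped(summary: GroupedRuleSummary, path: str | Path) -> int:
    """Write the grouped-rule summary as JSON; returns the group count."""
    payload = [
        {
            "consequent": _join(g.consequent),
            "n_rules": len(g.members),
            "max_support": fmt7(g.max_support),
            "min_support": fmt7(g.min_support),
            "max_confidence": fmt7(g.max_confidence),
            "min_confidence": fmt7(g.min_confidence),
            "mean_lift": fmt7(g.mean_lift),
            "members": [
                {"lhs": _join(r.antecedent), "support": fmt7(r.support), "confidence": fmt7(r.confidence)}
                for r in g.members
            ],
        }
        for g in summary
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    return len(payload)

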