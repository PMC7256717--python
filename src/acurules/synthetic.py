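"""Synthetic transaction databases with planted co-occurrence structure.

The generator emulates the shape of prescription data: a handful of "core"
item combinations that recur wholly across transactions (the shared backbone
of a therapy), superimposed on independent per-item background noise (the
accessory points each study adds). Each transaction includes core k in full
with probability pi_k, and every universe item independently with background
probability p, so the expected support of core k is

    E[supp(C_k)] = pi_k + (1 - pi_k) * p ** len(C_k),

the closed form the recovery report checks against. Because background draws
are independent Bernoulli, pairwise lift between pure background items is 1
in expectation — the natural null for testing that the miner does not invent
structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import yaml

from .apriori import FrequentItemsetResult
from .errors import ValidationError
from .transactions import CODE_PATTERN, Transaction, TransactionDB

logger = logging.getLogger(__name__)


def default_universe(size: int) -> tuple[str, ...]:
    """Synthetic item codes ``SYN1 .. SYN<size>`` (canonical code shape)."""
    return tuple(f"SYN{i}" for i in range(1, size + 1))


@dataclass(frozen=True)
class PlantedModel:
    """Generative model: disjoint planted cores over independent background.

    Parameters
    ----------
    universe_size:
        Number of items M; items are ``SYN1..SYNM`` unless cores introduce
        their own codes (core items must belong to the universe).
    n_transactions:
        Number of transactions N to draw.
    cores:
        List of ``(itemset, pi)`` pairs: core items are included together
        with probability pi per transaction.
    background_rate:
        Independent per-item inclusion probability p, with p < min(pi).
    seed:
        Seed for the PCG64 generator; the database is a pure function of it.
    """

    universe_size: int
    n_transactions: int
    cores: tuple[tuple[tuple[str, ...], float], ...]
    background_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        cores = tuple((tuple(sorted(items)), float(pi)) for items, pi in self.cores)
        object.__setattr__(self, "cores", cores)
        if self.universe_size < 1:
            raise ValidationError("universe_size must be positive")
        if self.n_transactions < 1:
            raise ValidationError("n_transactions must be positive")
        p = self.background_rate
        if not 0 <= p <= 1:
            raise ValidationError(f"background_rate must be in [0, 1], got {p}")
        seen: set[str] = set()
        universe = set(self.universe())
        for items, pi in cores:
            if not items:
                raise ValidationError("core itemsets must be non-empty")
            if not 0 <= pi <= 1:
                raise ValidationError(f"core probability must be in [0, 1], got {pi}")
            if pi > 0 and p >= pi:
                raise ValidationError(
                    f"background_rate {p} must be below core probability {pi}"
                )
            for code in items:
                if not CODE_PATTERN.match(code):
                    raise ValidationError(f"core item {code!r} is not a canonical code")
                if code not in universe:
                    raise ValidationError(f"core item {code!r} outside the universe")
            if seen & set(items):
                raise ValidationError("core itemsets must be pairwise disjoint")
            seen |= set(items)
        if sum(len(items) for items, _ in cores) > self.universe_size:
            raise ValidationError("universe_size smaller than the union of cores")

    def universe(self) -> tuple[str, ...]:
        base = list(default_universe(self.universe_size))
        extra = [c for items, _ in self.cores for c in items if c not in set(base)]
        # cores may name custom codes; they replace trailing synthetic ones
        if extra:
            base = extra + base[: self.universe_size - len(extra)]
        return tuple(sorted(base))

    def expected_support(self, core_index: int) -> float:
        """Closed-form E[supp(C_k)] = pi + (1 - pi) * p^|C|."""
        items, pi = self.cores[core_index]
        return pi + (1.0 - pi) * self.background_rate ** len(items)


def generate_db(model: PlantedModel) -> TransactionDB:
    """Draw a :class:`TransactionDB` from a planted model, reproducibly.

    Per transaction: each core is included wholly with its probability, then
    every universe item independently with the background rate. Transactions
    that come out empty are re-drawn (their count is logged) so the database
    satisfies the non-empty-transaction invariant.
    """
    rng = np.random.default_rng(model.seed)
    universe = model.universe()
    index = {item: i for i, item in enumerate(universe)}
    m = len(universe)
    transactions = []
    redraws = 0
    for t in range(model.n_transactions):
        while True:
            present = rng.random(m) < model.background_rate
            for items, pi in model.cores:
                if rng.random() < pi:
                    for code in items:
                        present[index[code]] = True
            if present.any():
                break
            redraws += 1
        items = frozenset(universe[i] for i in np.flatnonzero(present))
        transactions.append(Transaction(f"T{t + 1:04d}", items))
    if redraws:
        logger.info("re-drew %d empty transactions", redraws)
    return TransactionDB(tuple(transactions))


@dataclass(frozen=True)
class CoreRecovery:
    """Recovery outcome for one planted core."""

    core: tuple[str, ...]
    pi: float
    detected: bool
    expected_support: float
    observed_support: Fraction | None

    @property
    def deviation(self) -> float | None:
        if self.observed_support is None:
            return None
        return float(self.observed_support) - self.expected_support


def recovery_report(model: PlantedModel, mined: FrequentItemsetResult) -> list[CoreRecovery]:
    """Per core: was the full core found frequent, and how far off is its support.

    ``mined`` should come from :func:`generate_db` of the same model, at a
    support threshold between the background scale and min(pi).
    """
    report = []
    for idx, (items, pi) in enumerate(model.cores):
        detected = items in mined
        observed = mined.support_of(items) if detected else None
        report.append(
            CoreRecovery(
                core=items,
                pi=pi,
                detected=detected,
                expected_support=model.expected_support(idx),
                observed_support=observed,
            )
        )
    return report


def save_model(model: PlantedModel, path: str | Path) -> None:
    """Write the model spec as YAML (the config format the CLI reads)."""
    payload = {
        "universe_size": model.universe_size,
        "n_transactions": model.n_transactions,
        "background_rate": model.background_rate,
        "seed": model.seed,
        "cores": [{"items": list(items), "pi": pi} for items, pi in model.cores],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def load_model(path: str | Path) -> PlantedModel:
    """Read a model spec written by :func:`save_model` (or by hand)."""
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(payload, dict):
        raise ValidationError(f"model file {path} is not a mapping")
    try:
        cores = tuple(
            (tuple(core["items"]), float(core["pi"])) for core in payload.get("cores", [])
        )
        return PlantedModel(
            universe_size=int(payload["universe_size"]),
            n_transactions=int(payload["n_transactions"]),
            cores=cores,
            background_rate=float(payload.get("background_rate", 0.0)),
            seed=int(payload.get("seed", 0)),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"invalid model file {path}: {exc}") from exc
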