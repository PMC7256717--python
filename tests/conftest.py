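import numpy as np
import pytest

from acurules import MiningParams, Transaction, TransactionDB, load_fixture


@pytest.fixture(scope="session")
def fixture_db() -> TransactionDB:
    return load_fixture()


@pytest.fixture(scope="session")
def default_params() -> MiningParams:
    return MiningParams()


@pytest.fixture
def toy_db() -> TransactionDB:
    """Three baskets: {A,B}, {A,B,C}, {B,C} (small enough to enumerate by hand)."""
    return db_from_sets([{"AA1", "BB1"}, {"AA1", "BB1", "CC1"}, {"BB1", "CC1"}])


def db_from_sets(sets) -> TransactionDB:
    return TransactionDB(
        tuple(Transaction(f"T{i + 1}", frozenset(s)) for i, s in enumerate(sets))
    )


def random_db(rng: np.random.Generator, max_items: int = 15, max_tx: int = 64) -> TransactionDB:
    """A random database for oracle-equivalence checks: each transaction draws
    a Bernoulli indicator per item; empty transactions are re-drawn."""
    m = int(rng.integers(2, max_items + 1))
    n = int(rng.integers(1, max_tx + 1))
    items = [f"IT{i + 1}" for i in range(m)]
    p = float(rng.uniform(0.1, 0.7))
    sets = []
    for _ in range(n):
        while True:
            mask = rng.random(m) < p
            if mask.any():
                break
        sets.append({items[i] for i in np.flatnonzero(mask)})
    return db_from_sets(sets)
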