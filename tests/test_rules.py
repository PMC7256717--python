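from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acurules import (
    MiningParams,
    ValidationError,
    brute_force_frequent,
    count_rules,
    generate_rules,
    mine_frequent,
    mine_rules,
    query_rules,
    rank_rules,
)

from conftest import db_from_sets, random_db


@pytest.fixture(scope="module")
def fixture_rules(fixture_db, default_params):
    return mine_rules(fixture_db, default_params)


@pytest.fixture(scope="module")
def pairwise_rules(fixture_db):
    """Rules between individual acupoints only (1 item on each side)."""
    return mine_rules(fixture_db, MiningParams(max_len=2, min_antecedent_size=1))


# --------------------------------------------------------------------------- metrics


def test_published_rule_metrics(fixture_rules):
    r = fixture_rules.get({"EXB1"}, {"ST36"})
    assert r is not None
    assert r.support == Fraction(2, 3)
    assert r.confidence == 1
    assert r.expected_confidence == Fraction(3, 4)
    assert r.lift == Fraction(4, 3)


def test_boundary_confidence_retained(fixture_rules):
    r = fixture_rules.get({"BL13"}, {"EXB1"})
    assert r is not None and r.confidence == Fraction(4, 5)  # exactly the threshold


def test_mismatched_thresholds_rejected(fixture_db, default_params):
    freq = mine_frequent(fixture_db, default_params)
    with pytest.raises(ValidationError):
        generate_rules(freq, fixture_db, MiningParams(min_support=0.3))


def test_toy_db_two_rules():
    db = db_from_sets([{"AA1", "BB1"}] * 3)
    rules = mine_rules(db, MiningParams(min_support=0.5, min_confidence=0.8, min_antecedent_size=1))
    assert {r.key for r in rules} == {
        (("AA1",), ("BB1",)),
        (("BB1",), ("AA1",)),
    }


def test_empty_antecedent_rules_when_allowed(fixture_rules):
    """With min_antecedent_size=0 the only {} => {item} rule is for BL13,
    the single acupoint whose marginal support reaches the 0.8 confidence bar."""
    empties = [r for r in fixture_rules if not r.antecedent]
    assert [r.consequent for r in empties] == [("BL13",)]
    (r,) = empties
    assert r.confidence == r.support == r.expected_confidence == Fraction(10, 12)
    assert r.lift == 1


def test_metric_identities_exact(fixture_rules, fixture_db, default_params):
    freq = mine_frequent(fixture_db, default_params)
    n = fixture_db.n
    for r in fixture_rules:
        assert r.lift * r.expected_confidence == r.confidence
        lhs_support = Fraction(freq.count_of(r.antecedent), n) if r.antecedent else 1
        assert r.confidence * lhs_support == r.support
        assert r.support <= r.confidence <= 1
        assert r.support <= min(lhs_support, r.expected_confidence)


def test_reciprocal_rules_share_support_and_lift(fixture_rules):
    seen = 0
    for r in fixture_rules:
        rev = fixture_rules.get(r.consequent, r.antecedent)
        if rev is not None:
            assert rev.support == r.support
            assert rev.lift == r.lift
            seen += 1
    assert seen > 0


# --------------------------------------------------------------------------- counts & monotonicity


def test_fixture_rule_count(fixture_rules):
    assert count_rules(fixture_rules) == 2444


def test_threshold_monotonicity(fixture_db, default_params):
    base = {r.key for r in mine_rules(fixture_db, default_params)}
    for stricter in (
        MiningParams(min_support=0.3),
        MiningParams(min_confidence=0.9),
        MiningParams(min_support=0.4, min_confidence=0.95),
    ):
        subset = {r.key for r in mine_rules(fixture_db, stricter)}
        assert subset <= base


def test_rules_from_oracle_itemsets_match(default_params):
    rng = np.random.default_rng(7)
    for _ in range(20):
        db = random_db(rng, max_items=10, max_tx=40)
        freq_a = mine_frequent(db, default_params)
        freq_b = brute_force_frequent(db, default_params, max_universe=15)
        rules_a = generate_rules(freq_a, db, default_params)
        rules_b = generate_rules(freq_b, db, default_params)
        assert {(r.key, r.support, r.confidence) for r in rules_a} == {
            (r.key, r.support, r.confidence) for r in rules_b
        }


# --------------------------------------------------------------------------- ranking


TABLE2_KEYS = {
    (("BL23",), ("BL13",)),
    (("BL13",), ("BL23",)),
    (("EXB1",), ("ST36",)),
    (("ST36",), ("EXB1",)),
    (("EXB1",), ("BL13",)),
    (("BL13",), ("EXB1",)),
    (("CV17",), ("ST36",)),
    (("ST36",), ("CV17",)),
    (("ST36",), ("BL13",)),
    (("BL13",), ("ST36",)),
}


def test_top10_pairwise_rules(pairwise_rules):
    top = rank_rules(pairwise_rules, 10)
    assert {r.key for r in top} == TABLE2_KEYS


def test_top1_is_bl23_implies_bl13(pairwise_rules):
    (best,) = rank_rules(pairwise_rules, 1)
    assert best.key == (("BL23",), ("BL13",))
    assert best.support == Fraction(3, 4) and best.confidence == 1


def test_rank_k_beyond_size_returns_all_sorted(pairwise_rules):
    ranked = rank_rules(pairwise_rules, 10_000)
    assert len(ranked) == len(pairwise_rules)
    metrics = [(r.support, r.confidence, r.lift) for r in ranked]
    assert metrics == sorted(metrics, reverse=True)


def test_rank_reports_boundary_ties(pairwise_rules):
    top, ties = rank_rules(pairwise_rules, 3, with_ties=True)
    assert len(top) == 3
    # 3rd place (support 2/3, confidence 1, lift 4/3) is shared by two rules
    assert len(ties) == 2
    assert all(
        r.support == Fraction(2, 3) and r.confidence == 1 and r.lift == Fraction(4, 3)
        for r in ties
    )


# --------------------------------------------------------------------------- queries


def test_query_composite_rule_st36_bl12_cv17(fixture_rules):
    hits = query_rules(fixture_rules, lhs_filter={"ST36", "BL12"}, rhs_filter={"CV17"})
    assert len(hits) > 0
    exact = hits.get({"ST36", "BL12"}, {"CV17"})
    assert exact is not None
    assert exact.confidence == Fraction(5, 6)
    assert exact.joint_count == 5


def test_query_composite_rule_exb1_bl12_st36(fixture_rules):
    exact = fixture_rules.get({"EXB1", "BL12"}, {"ST36"})
    assert exact is not None
    assert exact.confidence == 1 and exact.joint_count == 6


def test_query_unknown_code_matches_nothing(fixture_rules):
    assert len(query_rules(fixture_rules, lhs_filter={"PC6"})) == 0


def test_query_empty_filter_matches_all(fixture_rules):
    assert len(query_rules(fixture_rules)) == len(fixture_rules)


# --------------------------------------------------------------------------- independence


@settings(max_examples=5, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_independent_items_have_unit_lift(seed):
    """Two items included independently at rate p: lift of {X} => {Y} should sit
    within 3 binomial standard errors of 1."""
    rng = np.random.default_rng(seed)
    n, p = 4000, 0.55
    draws = rng.random((n, 2)) < p
    sets = []
    for a, b in draws:
        items = {"XX1"} if a else set()
        if b:
            items.add("YY1")
        sets.append(items or {"ZZ1"})
    db = db_from_sets(sets)
    rules = mine_rules(
        db, MiningParams(min_support=0.05, min_confidence=0.05, min_antecedent_size=1, max_len=2)
    )
    r = rules.get({"XX1"}, {"YY1"})
    assert r is not None
    se = (p * (1 - p) / (n * p * p)) ** 0.5  # rough SE of conditional rate
    assert abs(float(r.lift) - 1.0) < 3 * se / p
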