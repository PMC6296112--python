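"""Transaction encoding, apriori correctness, rule scoring and ordering."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from fallmine import apriori, encode_transactions, generate_rules, score_rule
from fallmine.exceptions import ValidationError
from fallmine.rules import RHS_FALL, Transaction
from fallmine.schema import CaseReport, DrugRecord, PreferredTerm

FALL = PreferredTerm("10016173", "fall")
NAUSEA = PreferredTerm("10028813", "nausea")


def brute_force_itemsets(transactions, min_support, maxlen):
    """Exhaustive enumeration oracle: count every subset directly."""
    d = len(transactions)
    items = sorted({it for t in transactions for it in t.items})
    min_count = max(1, math.ceil(min_support * d - 1e-12))
    out = {}
    for k in range(1, min(maxlen, len(items)) + 1):
        for combo in combinations(items, k):
            s = frozenset(combo)
            n = sum(1 for t in transactions if s <= t.items)
            if n >= min_count:
                out[s] = n
    return out


def _tx(*itemsets):
    return [Transaction(f"t{i}", frozenset(s)) for i, s in enumerate(itemsets)]


# ---------------------------------------------------------------- encoding


def test_encode_emits_expected_items():
    r = CaseReport(
        report_id="x",
        age_band="70-79",
        drugs=[
            DrugRecord("fentanyl"),
            DrugRecord("nitrazepam"),
            DrugRecord("ramelteon"),
            DrugRecord("amitriptyline"),
        ],
        events={FALL},
    )
    txs, d = encode_transactions([r], ("age", "n_cns", "n_ccb"))
    assert d == 1
    assert txs[0].items == {"age:70-79", "n_cns:4", RHS_FALL}


def test_encode_class_and_hist_namespaces():
    r = CaseReport(
        report_id="x",
        drugs=[DrugRecord("zolpidem"), DrugRecord("amlodipine")],
        events={NAUSEA},
        histories={"dementia"},
    )
    txs, _ = encode_transactions([r], ("class", "hist"))
    assert txs[0].items == {
        "class:benzodiazepines",
        "class:calcium_channel_blockers",
        "hist:dementia",
    }


def test_encode_keeps_itemless_reports_in_denominator():
    r = CaseReport(report_id="x", drugs=[DrugRecord("acetaminophen")], events={NAUSEA})
    txs, d = encode_transactions([r], ("age", "n_cns"))
    assert d == 1
    assert txs[0].items == frozenset()


def test_encode_rejects_unknown_namespace():
    with pytest.raises(ValidationError):
        encode_transactions([], ("age", "weight"))


def test_encoded_fall_flags_sum_to_fall_count(small_db, small_reports):
    txs, _ = encode_transactions(small_reports, ("age",))
    assert sum(RHS_FALL in t.items for t in txs) == int(small_db.fall.sum())


# ----------------------------------------------------------------- apriori


def test_apriori_on_toy_database_matches_enumeration():
    txs = _tx({"a", "b"}, {"a", "c"}, {"a", "b", "c"}, {"b", "d"}, {"a"})
    mined = {fs.items: fs.count for fs in apriori(txs, 0.2, 3)}
    assert mined == brute_force_itemsets(txs, 0.2, 3)


def test_apriori_min_support_one_keeps_only_universal_items():
    txs = _tx({"a", "b"}, {"a", "c"}, {"a"})
    mined = apriori(txs, 1.0, 3)
    assert {fs.items for fs in mined} == {frozenset({"a"})}


def test_apriori_maxlen_one_gives_frequent_singles():
    txs = _tx({"a", "b"}, {"a", "c"}, {"a"})
    mined = apriori(txs, 0.5, 1)
    assert {fs.items for fs in mined} == {frozenset({"a"}), }


def test_apriori_validates_inputs():
    with pytest.raises(ValidationError):
        apriori([], 0.1, 3)
    with pytest.raises(ValidationError):
        apriori(_tx({"a"}), 0.0, 3)
    with pytest.raises(ValidationError):
        apriori(_tx({"a"}), 0.1, 0)


@given(
    st.lists(
        st.sets(st.sampled_from("abcdefgh")),
        min_size=1,
        max_size=40,
    ),
    st.sampled_from([0.05, 0.1, 0.25, 0.5]),
    st.integers(1, 4),
)
@settings(derandomize=True, deadline=None, max_examples=50)
def test_apriori_equals_enumeration_property(itemsets, min_support, maxlen):
    txs = _tx(*itemsets)
    mined = {fs.items: fs.count for fs in apriori(txs, min_support, maxlen)}
    assert mined == brute_force_itemsets(txs, min_support, maxlen)
    # anti-monotonicity on the mined output
    for s, n in mined.items():
        for sub in map(frozenset, combinations(s, len(s) - 1)):
            if sub:
                assert mined[sub] >= n


# ------------------------------------------------------------- score_rule


def test_independence_gives_unit_lift_and_zero_chi2():
    # n_xy/n_x == n_y/D exactly
    sc = score_rule(10, 100, 200, 2000)
    assert sc.lift == pytest.approx(1.0)
    assert sc.chi_squared == 0.0


def test_degenerate_margins_flagged_not_crashed():
    sc = score_rule(5, 10, 10, 10)  # antecedent in every transaction
    assert math.isnan(sc.chi_squared)
    assert "degenerate" in sc.note
    with pytest.raises(ValidationError):
        score_rule(11, 10, 20, 100)
    with pytest.raises(ValidationError):
        score_rule(1, 0, 5, 10)


@given(
    st.integers(1, 50), st.integers(1, 200),
    st.integers(1, 200), st.integers(300, 5000),
)
@settings(derandomize=True, deadline=None, max_examples=80)
def test_chi2_formula_equals_pearson(n_xy, dx, dy, d):
    n_x, n_y = n_xy + dx, n_xy + dy
    if n_x >= d or n_y >= d or d - n_x - n_y + n_xy < 0:
        return
    sc = score_rule(n_xy, n_x, n_y, d)
    if sc.lift == 1.0:
        return
    table = np.array(
        [[n_xy, n_x - n_xy], [n_y - n_xy, d - n_x - n_y + n_xy]]
    )
    pearson = chi2_contingency(table, correction=False)[0]
    assert sc.chi_squared == pytest.approx(pearson, rel=1e-6)


def test_support_confidence_lift_invariant_chain():
    sc = score_rule(4, 110, 3715, 430587)
    assert sc.support <= sc.confidence <= 1.0
    assert sc.lift == pytest.approx(sc.confidence / (3715 / 430587))


# --------------------------------------------------------- generate_rules


def test_certain_rule_has_confidence_one():
    txs = _tx({"x", RHS_FALL}, {"x", RHS_FALL}, {RHS_FALL}, {"y"})
    itemsets = apriori(txs, 0.25, 2)
    rules = generate_rules(itemsets, txs, RHS_FALL, 0.5)
    rule = next(r for r in rules if r.lhs == frozenset({"x"}))
    assert rule.confidence == 1.0
    assert rule.case_n == 2


def test_min_confidence_above_all_yields_empty():
    txs = _tx({"x", RHS_FALL}, {"x"}, {"x"}, {RHS_FALL})
    itemsets = apriori(txs, 0.25, 2)
    assert generate_rules(itemsets, txs, RHS_FALL, 0.9) == []


def test_missing_consequent_warns_and_returns_empty():
    txs = _tx({"x"}, {"y"})
    itemsets = apriori(txs, 0.5, 2)
    with pytest.warns(UserWarning, match="not a frequent item"):
        assert generate_rules(itemsets, txs, RHS_FALL, 0.1) == []


def test_rules_sorted_by_lift_with_deterministic_ties():
    txs = _tx(
        *([{"a", RHS_FALL}] * 4), *([{"a"}] * 4),
        *([{"b", RHS_FALL}] * 2), *([{"b"}] * 6),
        *([{"c", RHS_FALL}] * 2), *([{"c"}] * 6),
        *([{RHS_FALL}] * 2), *([set()] * 6),
    )
    itemsets = apriori(txs, 1 / len(txs), 2)
    rules = generate_rules(itemsets, txs, RHS_FALL, 0.001)
    lifts = [r.lift for r in rules]
    assert lifts == sorted(lifts, reverse=True)
    tied = [r for r in rules if r.lift == pytest.approx(lifts[-1])]
    lhs_order = [tuple(sorted(r.lhs)) for r in tied if len(r.lhs) == 1]
    assert lhs_order == sorted(lhs_order)  # lexicographic tie-break
    for r in rules:
        assert RHS_FALL not in r.lhs  # X and Y mutually exclusive
        assert r.support <= r.confidence <= 1.0


def test_rules_match_enumeration_on_random_transactions():
    rng = np.random.default_rng(99)
    items = [f"i{k}" for k in range(6)]
    txs = []
    for i in range(150):
        s = {it for it in items if rng.random() < 0.3}
        if rng.random() < 0.15:
            s.add(RHS_FALL)
        txs.append(Transaction(f"t{i}", frozenset(s)))
    itemsets = apriori(txs, 0.01, 3)
    rules = generate_rules(itemsets, txs, RHS_FALL, 0.01)
    counts = brute_force_itemsets(txs, 0.01, 3)
    n_y = counts[frozenset({RHS_FALL})]
    expected = {}
    for s, n in counts.items():
        if RHS_FALL in s and len(s) > 1:
            lhs = s - {RHS_FALL}
            if n / counts[lhs] >= 0.01:
                expected[lhs] = n
    assert {r.lhs: r.case_n for r in rules} == expected
    for r in rules:
        sc = score_rule(r.case_n, counts[r.lhs], n_y, len(txs))
        assert r.lift == pytest.approx(sc.lift)
        assert r.chi_squared == pytest.approx(sc.chi_squared, nan_ok=True)
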