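"""Association-rule mining over report-level items.

Each report becomes a transaction of namespaced items:

* ``age:<band>`` — the 10-year age band (at most one per report)
* ``n_cns:<k>`` — number of distinct CNS-active drugs, emitted for k ≥ 1
* ``n_ccb:<k>`` — number of distinct calcium channel blockers, k ≥ 1
* ``class:<id>`` — exposure to one of the eight ATC classes
* ``hist:<term>`` — a reported comorbidity term
* ``ev:fall_related`` — the fall-related outcome (always emitted when true)

Frequent itemsets are mined with a level-wise apriori (candidate join
on sorted prefixes, subset pruning, anti-monotone support), rules are
generated against a fixed consequent, and each rule is scored with
support, confidence, lift and the chi-squared interest statistic

    chi² = D·(lift−1)²·(support·confidence) / ((confidence−support)·(lift−confidence))

which for a 2×2 cross-classification equals Pearson's chi-squared.
Rules with chi² ≥ 4 (≈ p < 0.05 at 1 df) are flagged significant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from . import drug_classes
from .exceptions import ValidationError
from .schema import CaseReport, FallEventDefinition, DEFAULT_EVENT_DEF, flag_fall_related

RHS_FALL = "ev:fall_related"
CHI2_SIGNIFICANT = 4.0

ITEM_NAMESPACES = ("age", "n_cns", "n_ccb", "class", "hist")


@dataclass(frozen=True, slots=True)
class Transaction:
    report_id: str
    items: frozenset[str]


@dataclass(frozen=True, slots=True)
class FrequentItemset:
    items: frozenset[str]
    count: int
    support: float


@dataclass(frozen=True, slots=True)
class RuleScore:
    support: float
    confidence: float
    lift: float
    chi_squared: float  # NaN when undefined; see note
    note: str | None = None


@dataclass(frozen=True, slots=True)
class AssociationRule:
    lhs: frozenset[str]
    rhs: str
    case_n: int
    support: float
    confidence: float
    lift: float
    chi_squared: float
    significant: bool
    note: str | None = None


def encode_transactions(
    reports: Sequence[CaseReport],
    item_config: Iterable[str] = ITEM_NAMESPACES,
    event_def: FallEventDefinition = DEFAULT_EVENT_DEF,
) -> tuple[list[Transaction], int]:
    """Encode reports as item transactions; returns (transactions, D).

    ``item_config`` selects which antecedent namespaces are emitted;
    the outcome item is always emitted for fall-related reports.  A
    report mapping to no items still contributes an (empty) transaction
    to D.
    """
    namespaces = tuple(item_config)
    unknown = [ns for ns in namespaces if ns not in ITEM_NAMESPACES]
    if unknown:
        raise ValidationError(
            f"unknown item namespace(s) {unknown}; valid: {list(ITEM_NAMESPACES)}"
        )
    out: list[Transaction] = []
    for r in reports:
        items: set[str] = set()
        if "age" in namespaces and r.age_band != "excluded":
            items.add(f"age:{r.age_band}")
        if "n_cns" in namespaces:
            k = drug_classes.count_class_drugs(r, "cns_active")
            if k >= 1:
                items.add(f"n_cns:{k}")
        if "n_ccb" in namespaces:
            k = drug_classes.count_class_drugs(r, "calcium_channel_blockers")
            if k >= 1:
                items.add(f"n_ccb:{k}")
        if "class" in namespaces:
            for cid in drug_classes.report_classes(r) & set(drug_classes.CLASS_IDS):
                items.add(f"class:{cid}")
        if "hist" in namespaces:
            for term in r.histories:
                items.add(f"hist:{term}")
        if flag_fall_related(r, event_def):
            items.add(RHS_FALL)
        out.append(Transaction(report_id=r.report_id, items=frozenset(items)))
    return out, len(out)


def _support_threshold(min_support: float, d_eff: int) -> int:
    # "support >= min_support" as an integer count; epsilon guards the
    # exact-boundary case (e.g. 0.2 of 5 transactions -> count 1)
    return max(1, math.ceil(min_support * d_eff - 1e-12))


def apriori(
    transactions: Sequence[Transaction],
    min_support: float,
    maxlen: int,
    *,
    d_override: int | None = None,
) -> list[FrequentItemset]:
    """All itemsets of size ≤ maxlen with support ≥ min_support.

    Level-wise search: candidates of size k are joins of frequent
    (k−1)-itemsets sharing a (k−2)-prefix, pruned when any (k−1)-subset
    is infrequent; counting is vectorised over a boolean
    transaction × item matrix.  ``d_override`` substitutes the support
    denominator (used for subgroup runs scored against a full-database
    denominator).
    """
    if not transactions:
        raise ValidationError("apriori requires at least one transaction")
    if not (0.0 < min_support <= 1.0):
        raise ValidationError("min_support must be in (0, 1]")
    if maxlen < 1:
        raise ValidationError("maxlen must be >= 1")
    d_eff = d_override if d_override is not None else len(transactions)
    if d_eff <= 0:
        raise ValidationError("support denominator must be positive")
    min_count = _support_threshold(min_support, d_eff)

    items = sorted({it for t in transactions for it in t.items})
    if not items:
        return []
    col = {it: j for j, it in enumerate(items)}
    mat = np.zeros((len(transactions), len(items)), dtype=bool)
    for i, t in enumerate(transactions):
        for it in t.items:
            mat[i, col[it]] = True
    col_counts = mat.sum(axis=0)

    results: list[FrequentItemset] = []
    # level 1
    frequent: list[tuple[str, ...]] = []
    counts: dict[tuple[str, ...], int] = {}
    for it in items:
        n = int(col_counts[col[it]])
        if n >= min_count:
            key = (it,)
            frequent.append(key)
            counts[key] = n
    results.extend(
        FrequentItemset(frozenset(k), counts[k], counts[k] / d_eff) for k in frequent
    )

    k = 2
    prev = frequent
    while prev and k <= maxlen:
        prev_set = set(prev)
        candidates: list[tuple[str, ...]] = []
        for i in range(len(prev)):
            for j in range(i + 1, len(prev)):
                x, y = prev[i], prev[j]
                if x[:-1] != y[:-1]:
                    # prev is lexicographically sorted: once prefixes
                    # diverge no later join partner exists for x
                    break
                cand = x + (y[-1],)
                if all(
                    cand[:m] + cand[m + 1:] in prev_set for m in range(len(cand) - 1)
                ):
                    candidates.append(cand)
        level: list[tuple[str, ...]] = []
        for cand in candidates:
            mask = mat[:, col[cand[0]]]
            for it in cand[1:]:
                mask = mask & mat[:, col[it]]
            n = int(mask.sum())
            if n >= min_count:
                level.append(cand)
                counts[cand] = n
        level.sort()
        results.extend(
            FrequentItemset(frozenset(c), counts[c], counts[c] / d_eff) for c in level
        )
        prev = level
        k += 1
    return results


def score_rule(n_xy: int, n_x: int, n_y: int, d: int) -> RuleScore:
    """Support, confidence, lift and chi-squared from joint counts.

    ``n_xy``: transactions containing X∪{Y}; ``n_x``/``n_y``: marginal
    counts; ``d``: total transactions.  Chi-squared uses the
    support/confidence/lift identity above; at exact independence
    (lift = 1) it is 0 by definition, and for degenerate margins
    (X or Y present in every transaction) it is undefined and returned
    as NaN with a reason.
    """
    if d <= 0 or n_x <= 0 or n_y <= 0:
        raise ValidationError("score_rule requires d > 0, n_x > 0, n_y > 0")
    if n_xy > min(n_x, n_y):
        raise ValidationError("n_xy cannot exceed min(n_x, n_y)")
    support = n_xy / d
    confidence = n_xy / n_x
    lift = confidence / (n_y / d)
    if lift == 1.0:
        return RuleScore(support, confidence, lift, 0.0)
    if n_x == d:
        return RuleScore(
            support, confidence, lift, float("nan"),
            note="degenerate: antecedent present in every transaction",
        )
    if n_y == d:
        return RuleScore(
            support, confidence, lift, float("nan"),
            note="degenerate: consequent present in every transaction",
        )
    chi2 = (
        d * (lift - 1.0) ** 2 * (support * confidence)
        / ((confidence - support) * (lift - confidence))
    )
    return RuleScore(support, confidence, lift, chi2)


def _lhs_sort_key(rule: AssociationRule) -> tuple:
    return (-rule.lift, -rule.support, tuple(sorted(rule.lhs)))


def generate_rules(
    itemsets: Sequence[FrequentItemset],
    transactions: Sequence[Transaction],
    rhs_item: str = RHS_FALL,
    min_confidence: float = 0.001,
    *,
    d_override: int | None = None,
) -> list[AssociationRule]:
    """Rules X → rhs for every frequent itemset containing the consequent.

    One rule per frequent X∪{rhs} with confidence ≥ min_confidence;
    sorted by lift descending (ties: support descending, then
    lexicographic antecedent).  The fixed-consequent restriction is a
    post-filter over the frequent itemsets.
    """
    if not (0.0 < min_confidence <= 1.0):
        raise ValidationError("min_confidence must be in (0, 1]")
    d_eff = d_override if d_override is not None else len(transactions)
    counts = {fs.items: fs.count for fs in itemsets}
    n_y = counts.get(frozenset({rhs_item}))
    if n_y is None:
        warnings.warn(
            f"consequent {rhs_item!r} is not a frequent item; no rules generated",
            stacklevel=2,
        )
        return []
    rules: list[AssociationRule] = []
    for fs in itemsets:
        if rhs_item not in fs.items or len(fs.items) < 2:
            continue
        lhs = fs.items - {rhs_item}
        n_x = counts[lhs]  # guaranteed frequent by anti-monotonicity
        if fs.count / n_x < min_confidence:
            continue
        sc = score_rule(fs.count, n_x, n_y, d_eff)
        rules.append(
            AssociationRule(
                lhs=lhs,
                rhs=rhs_item,
                case_n=fs.count,
                support=sc.support,
                confidence=sc.confidence,
                lift=sc.lift,
                chi_squared=sc.chi_squared,
                significant=(
                    not math.isnan(sc.chi_squared)
                    and sc.chi_squared >= CHI2_SIGNIFICANT
                ),
                note=sc.note,
            )
        )
    rules.sort(key=_lhs_sort_key)
    return rules


def mine_rules(
    reports: Sequence[CaseReport],
    item_config: Iterable[str],
    min_support: float,
    min_confidence: float,
    maxlen: int,
    event_def: FallEventDefinition = DEFAULT_EVENT_DEF,
    *,
    d_override: int | None = None,
) -> list[AssociationRule]:
    """Encode, mine and score in one call (maxlen counts lhs plus rhs)."""
    transactions, _ = encode_transactions(reports, item_config, event_def)
    itemsets = apriori(transactions, min_support, maxlen, d_override=d_override)
    return generate_rules(
        itemsets, transactions, RHS_FALL, min_confidence, d_override=d_override
    )


def rules_to_records(rules: Sequence[AssociationRule]) -> list[dict]:
    """Flatten rules for tabular output (lhs as a sorted comma join)."""
    return [
        {
            "lhs": ",".join(sorted(r.lhs)),
            "rhs": r.rhs,
            "case_n": r.case_n,
            "support": r.support,
            "confidence": r.confidence,
            "lift": r.lift,
            "chi_squared": r.chi_squared,
            "significant": r.significant,
        }
        for r in rules
    ]
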