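"""Generator calibration, determinism, planted effects, exact fixtures."""

import math

import numpy as np
import pytest

from fallmine import (
    SyntheticConfig,
    build_contingency,
    fixture_from_counts,
    fixture_from_strata,
    mine_rules,
    ror,
    score_rule,
)
from fallmine import simulate as sim
from fallmine.drug_classes import CLASS_IDS, count_class_drugs
from fallmine.exceptions import ValidationError
from fallmine.schema import flag_fall_related


def test_null_fall_rate_matches_binomial_oracle():
    # baseline 0.01 with all multipliers 1: the outcome is Binomial(n, 0.01)
    cfg = SyntheticConfig(
        n_reports=50_000, seed=7, baseline_fall_prob=0.01, risk_multipliers={}
    )
    db = sim.generate(cfg)
    rate = db.fall.mean()
    sd = math.sqrt(0.01 * 0.99 / 50_000)
    assert abs(rate - 0.01) < 3 * sd


def test_same_seed_gives_byte_identical_csvs(tmp_path):
    cfg = SyntheticConfig(n_reports=500, seed=123)
    sim.generate(cfg).write_csv(tmp_path / "a")
    sim.generate(SyntheticConfig(n_reports=500, seed=123)).write_csv(tmp_path / "b")
    for name in ("demo.csv", "drug.csv", "reac.csv", "hist.csv", "ground_truth.json"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
    sim.generate(SyntheticConfig(n_reports=500, seed=124)).write_csv(tmp_path / "c")
    assert (tmp_path / "a" / "drug.csv").read_bytes() != (
        tmp_path / "c" / "drug.csv"
    ).read_bytes()


def test_empty_database_writes_valid_headers(tmp_path):
    db = sim.generate(SyntheticConfig(n_reports=0, seed=1))
    paths = db.write_csv(tmp_path)
    assert (tmp_path / "demo.csv").read_text().splitlines()[0] == (
        "report_id,age_description,sex"
    )
    assert paths["drug"].read_text().strip() == "report_id,generic_name,role"


def test_exposure_prevalences_are_calibrated():
    db = sim.generate(SyntheticConfig(n_reports=60_000, seed=5))
    for j, cid in enumerate(CLASS_IDS):
        p = db.config.class_prevalence[cid]
        emp = db.exposed[:, j].mean()
        tol = 4 * math.sqrt(p * (1 - p) / 60_000)
        assert abs(emp - p) < tol, cid


def test_materialized_reports_match_planted_arrays(small_db, small_reports):
    # exposure/count/outcome equivalence between the vectorised arrays
    # and the materialised report objects
    for group in ("benzodiazepines", "cns_active", "calcium_channel_blockers"):
        ct_arr = small_db.contingency(group)
        ct_rep = build_contingency(small_reports, group)
        assert (ct_arr.a, ct_arr.b, ct_arr.c, ct_arr.d) == (
            ct_rep.a, ct_rep.b, ct_rep.c, ct_rep.d,
        )
    n_cns_rep = np.array(
        [count_class_drugs(r, "cns_active") for r in small_reports]
    )
    assert (n_cns_rep == small_db.n_cns).all()
    fall_rep = np.array([flag_fall_related(r) for r in small_reports])
    assert (fall_rep == small_db.fall).all()
    assert all(r.events for r in small_reports)  # never an empty event set


def test_planted_effect_monotone_in_multiplier():
    # both ROR and single-item rule lift increase with the planted multiplier
    rors, lifts = [], []
    for mult in (1.0, 1.5, 2.0, 3.0):
        cfg = SyntheticConfig(
            n_reports=150_000,
            seed=29,
            baseline_fall_prob=0.01,
            risk_multipliers={"class:benzodiazepines": mult},
        )
        db = sim.generate(cfg)
        ct = db.contingency("benzodiazepines")
        rors.append(ror(ct).ror)
        sc = score_rule(ct.a, ct.a + ct.b, ct.a + ct.c, ct.n_reports)
        lifts.append(sc.lift)
    assert rors == sorted(rors)
    assert lifts == sorted(lifts)


def test_polypharmacy_factor_induces_exposure_correlation():
    base = sim.generate(SyntheticConfig(n_reports=40_000, seed=3))
    corr = sim.generate(
        SyntheticConfig(n_reports=40_000, seed=3, polypharmacy_sd=1.5)
    )

    def cooccurrence(db):
        i = CLASS_IDS.index("benzodiazepines")
        j = CLASS_IDS.index("calcium_channel_blockers")
        both = (db.exposed[:, i] & db.exposed[:, j]).mean()
        return both / (db.exposed[:, i].mean() * db.exposed[:, j].mean())

    assert cooccurrence(corr) > cooccurrence(base)


def test_invalid_configs_rejected():
    with pytest.raises(ValidationError):
        sim.generate(SyntheticConfig(n_reports=10, baseline_fall_prob=0.0))
    with pytest.raises(ValidationError):
        sim.generate(
            SyntheticConfig(n_reports=10, cns_count_dist={1: 0.5, 2: 0.4})
        )
    with pytest.raises(ValidationError):
        sim.generate(
            SyntheticConfig(n_reports=10, class_prevalence={"statins": 0.1})
        )
    with pytest.raises(ValidationError):
        sim.generate(SyntheticConfig(n_reports=-1))


def test_fixture_from_counts_reproduces_table_exactly():
    reports = fixture_from_counts(64, 4536, 3651, 422336, "alpha_blockers")
    ct = build_contingency(reports, "alpha_blockers")
    assert (ct.a, ct.b, ct.c, ct.d) == (64, 4536, 3651, 422336)


def test_fixture_from_counts_minimal_and_invalid():
    reports = fixture_from_counts(1, 0, 0, 1, "ssri")
    ct = build_contingency(reports, "ssri")
    assert (ct.a, ct.b, ct.c, ct.d) == (1, 0, 0, 1)
    assert len(reports) == 2
    with pytest.raises(ValidationError):
        fixture_from_counts(0, 0, 0, 0, "ssri")


def test_fixture_stratum_recovers_rule_case_count():
    # a five-CNS-drug stratum of 308 exposed reports, 7 fall-related,
    # against a large unexposed remainder (scaled-down background)
    reports = fixture_from_counts(7, 301, 371, 42629, "n_cns:5")
    rules = mine_rules(reports, ("n_cns",), 1e-6, 0.001, 2)
    rule = next(r for r in rules if r.lhs == frozenset({"n_cns:5"}))
    assert rule.case_n == 7
    assert round(rule.confidence, 4) == round(7 / 308, 4)


def test_fixture_from_strata_supports_item_combos():
    reports = fixture_from_strata(
        [
            (("n_cns:4", "age:70-79"), 110, 4),
            ((), 1000, 10),
        ]
    )
    rules = mine_rules(reports, ("age", "n_cns"), 1e-6, 0.001, 3)
    combo = next(
        r for r in rules if r.lhs == frozenset({"n_cns:4", "age:70-79"})
    )
    assert combo.case_n == 4
    assert round(combo.confidence, 4) == round(4 / 110, 4)
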