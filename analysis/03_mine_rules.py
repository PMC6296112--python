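"""Association-rule mining with the fall-related consequent.

Two passes over the synthetic database from 01_simulate.py:

1. demographic items (age band, CNS-active drug count, CCB count)
   at min support 1e-6, min confidence 0.001, maxlen 3;
2. class + comorbidity items in the ≥60 subgroup at min confidence
   0.01, maxlen 4.

Both tables are sorted by lift; rules with chi-squared ≥ 4 are
flagged significant.

Run from the repository root:  python analysis/03_mine_rules.py
"""

from pathlib import Path

import pandas as pd

from fallmine import load_database_dir
from fallmine.pipeline import RuleRunConfig, _run_rule_pass
from fallmine.schema import DEFAULT_EVENT_DEF

DB_DIR = Path("results/synthetic_db")
OUT_DEMO = Path("results/rules_demographic.csv")
OUT_HIST = Path("results/rules_history.csv")


def main() -> None:
    reports = load_database_dir(DB_DIR)

    demo_cfg = RuleRunConfig(items=("age", "n_cns", "n_ccb"))
    demo, demo_meta = _run_rule_pass(reports, demo_cfg, DEFAULT_EVENT_DEF)
    demo.to_csv(OUT_DEMO, index=False, float_format="%.10g")
    print(
        f"demographic rules: {demo_meta['n_rules']} over "
        f"{demo_meta['subset_size']:,} reports (maxlen 3)"
    )
    with pd.option_context("display.width", 140):
        print(demo.head(10).to_string(index=False))
    n_cns_single = demo[demo["lhs"].str.fullmatch(r"n_cns:\d")]
    print("\nlift by CNS-active drug count (single-item antecedents):")
    print(n_cns_single[["lhs", "case_n", "lift"]].to_string(index=False))

    hist_cfg = RuleRunConfig(
        items=("class", "hist"), min_confidence=0.01, maxlen=4,
        min_age_band="60-69",
    )
    hist, hist_meta = _run_rule_pass(reports, hist_cfg, DEFAULT_EVENT_DEF)
    hist.to_csv(OUT_HIST, index=False, float_format="%.10g")
    print(
        f"\nhistory × class rules (>=60 subgroup): {hist_meta['n_rules']} over "
        f"{hist_meta['subset_size']:,} reports (maxlen 4)"
    )
    print(hist.head(10).to_string(index=False))
    print(f"-> {OUT_DEMO}, {OUT_HIST}")


if __name__ == "__main__":
    main()
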