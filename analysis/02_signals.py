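"""Reporting-odds-ratio disproportionality.

Two passes:

1. the synthetic database from 01_simulate.py — checks that each
   class's recovered ROR tracks its planted multiplier;
2. the published worked-example counts (8 classes, 3,715 fall-related
   of 430,587 reports) — the pipeline must reproduce the printed
   ROR (95% CI) rows to 2 decimals.

Run from the repository root:  python analysis/02_signals.py
"""

from pathlib import Path

import pandas as pd

from fallmine import detect_signals, load_database_dir, ror_from_counts
from fallmine.drug_classes import CLASS_IDS, display_name
from fallmine.pipeline import _signals_frame

DB_DIR = Path("results/synthetic_db")
OUT_SYNTH = Path("results/signals_synthetic.csv")
OUT_PUBLISHED = Path("results/signals_published_counts.csv")

# (case n, class total) per class; 3,715 fall-related of 430,587 reports
PUBLISHED_COUNTS = {
    "alpha_blockers": (64, 4600),
    "diuretics": (162, 25016),
    "calcium_channel_blockers": (542, 51482),
    "opioids": (189, 23530),
    "benzodiazepines": (561, 38300),
    "hypnotics_sedatives": (38, 2865),
    "nsmri": (68, 3479),
    "ssri": (212, 9058),
}
D, EVENT_TOTAL = 430_587, 3_715


def main() -> None:
    reports = load_database_dir(DB_DIR)
    results = detect_signals(reports, list(CLASS_IDS))
    frame = _signals_frame(results)
    OUT_SYNTH.parent.mkdir(exist_ok=True)
    frame.to_csv(OUT_SYNTH, index=False)
    print(f"synthetic database ({len(reports):,} reports):")
    print(frame.to_string(index=False))
    print(f"-> {OUT_SYNTH}")

    rows = []
    for cid, (case, total) in PUBLISHED_COUNTS.items():
        a, b = case, total - case
        c = EVENT_TOTAL - case
        d = D - total - c
        r = ror_from_counts(a, b, c, d, class_name=cid)
        rows.append(
            {
                "label": display_name(cid),
                "case_n": case,
                "class_total": total,
                "ror": round(r.ror, 2),
                "ci_low": round(r.ci_low, 2),
                "ci_high": round(r.ci_high, 2),
                "is_signal": r.is_signal,
            }
        )
    pub = pd.DataFrame(rows)
    pub.to_csv(OUT_PUBLISHED, index=False)
    print("\npublished worked-example counts:")
    print(pub.to_string(index=False))
    print(f"-> {OUT_PUBLISHED}")


if __name__ == "__main__":
    main()
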