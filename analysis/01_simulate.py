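"""Generate the study database: a synthetic SRS snapshot under the
default conditions (realistic age mix, class exposure prevalences,
and multiplicative fall-risk effects), written as the canonical
four-table CSVs plus a ground-truth JSON of the planted parameters.

Run from the repository root:  python analysis/01_simulate.py
"""

from pathlib import Path

from fallmine import SyntheticConfig
from fallmine import simulate as sim

OUT_DIR = Path("results/synthetic_db")
N_REPORTS = 100_000
SEED = 20


def main() -> None:
    cfg = SyntheticConfig(n_reports=N_REPORTS, seed=SEED)
    db = sim.generate(cfg)
    paths = db.write_csv(OUT_DIR)
    truth = db.ground_truth()
    print(f"wrote {db.n_reports:,} reports to {OUT_DIR}/")
    print(f"  fall-related rate: {truth['empirical']['fall_rate']:.4f} "
          f"(baseline {cfg.baseline_fall_prob})")
    print("  class exposure (empirical vs planted):")
    for cid, emp in truth["empirical"]["class_exposure"].items():
        print(f"    {cid:<26s} {emp:.4f} vs {cfg.class_prevalence[cid]:.4f}")
    print("files:", ", ".join(p.name for p in paths.values()))


if __name__ == "__main__":
    main()
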