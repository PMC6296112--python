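"""Shared fixtures and frozen worked-example constants."""

import pandas as pd
import pytest

from fallmine import SyntheticConfig
from fallmine import simulate as sim

# Published signal table for fall-related events over 430,587 reports
# (3,715 fall-related): class -> (case n, class total, ROR, ci_low, ci_high).
TABLE2_ROWS = {
    "alpha_blockers": (64, 4600, 1.63, 1.27, 2.09),
    "diuretics": (162, 25016, 0.74, 0.63, 0.86),
    "calcium_channel_blockers": (542, 51482, 1.26, 1.15, 1.38),
    "opioids": (189, 23530, 0.93, 0.80, 1.07),
    "benzodiazepines": (561, 38300, 1.83, 1.68, 2.01),
    "hypnotics_sedatives": (38, 2865, 1.55, 1.12, 2.14),
    "nsmri": (68, 3479, 2.31, 1.82, 2.95),
    "ssri": (212, 9058, 2.86, 2.49, 3.29),
}
TABLE2_D = 430_587
TABLE2_EVENT_TOTAL = 3_715


def table2_cells(class_id):
    """(a, b, c, d) for one signal-table row."""
    case, total, *_ = TABLE2_ROWS[class_id]
    a = case
    b = total - case
    c = TABLE2_EVENT_TOTAL - case
    d = TABLE2_D - total - c
    return a, b, c, d


@pytest.fixture(scope="session")
def small_db():
    """One modest synthetic database under default (study) conditions."""
    return sim.generate(SyntheticConfig(n_reports=4000, seed=11))


@pytest.fixture(scope="session")
def small_reports(small_db):
    return small_db.to_case_reports()


@pytest.fixture()
def tiny_db_dir(tmp_path):
    """Hand-written three-report database in the canonical dialect."""
    pd.DataFrame(
        {
            "report_id": ["r1", "r2", "r3"],
            "age_description": ["75", "elderly", "20歳代"],
            "sex": ["male", "female", "male"],
        }
    ).to_csv(tmp_path / "demo.csv", index=False)
    pd.DataFrame(
        {
            "report_id": ["r1", "r1", "r2", "r3"],
            "generic_name": ["zolpidem", "amlodipine", "acetaminophen", "paroxetine"],
            "role": ["suspected", "concomitant", "suspected", "suspected"],
        }
    ).to_csv(tmp_path / "drug.csv", index=False)
    pd.DataFrame(
        {
            "report_id": ["r1", "r1", "r2", "r3"],
            "pt_code": ["10016173", "10028813", "10028813", "10013573"],
            "pt_name": ["fall", "nausea", "nausea", "dizziness"],
        }
    ).to_csv(tmp_path / "reac.csv", index=False)
    pd.DataFrame(
        {"report_id": ["r1", "r3"], "term": ["hypertension", "depression"]}
    ).to_csv(tmp_path / "hist.csv", index=False)
    return tmp_path
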