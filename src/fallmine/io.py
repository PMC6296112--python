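"""Reading and writing the canonical four-table CSV database.

Dialect: UTF-8, comma-separated, one header row, long format keyed by
``report_id``:

* ``demo.csv`` — report_id, age_description, sex
* ``drug.csv`` — report_id, generic_name, role
* ``reac.csv`` — report_id, pt_code, pt_name
* ``hist.csv`` — report_id, term

Translation of a real spontaneous-reporting download (Japanese headers,
Shift-JIS, per-agency quirks) belongs in a separate adapter and is out
of scope here; any source can be analysed once reshaped to this dialect.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .exceptions import ParseError, ValidationError
from .schema import ROLES, CaseReport, DrugRecord, PreferredTerm, assign_age_band

logger = logging.getLogger(__name__)

_COLUMNS = {
    "demo": ["report_id", "age_description", "sex"],
    "drug": ["report_id", "generic_name", "role"],
    "reac": ["report_id", "pt_code", "pt_name"],
    "hist": ["report_id", "term"],
}


def _read_table(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{kind} table not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed {kind} table: {exc}", path=str(path)) from exc
    missing = [c for c in _COLUMNS[kind] if c not in df.columns]
    if missing:
        raise ParseError(
            f"{kind} table missing column(s) {missing}", path=str(path), line=1
        )
    blank = df["report_id"].str.strip() == ""
    if blank.any():
        # +2: header row plus 1-based indexing
        raise ParseError(
            "empty report_id", path=str(path), line=int(blank.idxmax()) + 2
        )
    return df


def load_database(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    hist_path: str | Path,
    *,
    return_orphans: bool = False,
) -> list[CaseReport] | tuple[list[CaseReport], dict[str, int]]:
    """Join the four tables into one :class:`CaseReport` per demo row.

    Rows in drug/reac/hist referencing a report_id absent from the demo
    table are orphans: they are logged and counted, never silently
    dropped without trace.  Duplicate report_ids in demo raise
    :class:`ValidationError`.
    """
    demo = _read_table(demo_path, "demo")
    drug = _read_table(drug_path, "drug")
    reac = _read_table(reac_path, "reac")
    hist = _read_table(hist_path, "hist")

    dup = demo["report_id"][demo["report_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(
            f"duplicate report_id in demo table: {sorted(set(dup))[:5]}"
        )

    reports: dict[str, CaseReport] = {}
    for rid, age_desc, sex in demo.itertuples(index=False):
        reports[rid] = CaseReport(
            report_id=rid, age_band=assign_age_band(age_desc), sex=sex
        )

    orphans = {"drug": 0, "reac": 0, "hist": 0}

    for i, (rid, name, role) in enumerate(drug.itertuples(index=False)):
        if rid not in reports:
            orphans["drug"] += 1
            continue
        if role not in ROLES:
            raise ParseError(
                f"invalid drug role {role!r}", path=str(drug_path), line=i + 2
            )
        reports[rid].drugs.append(DrugRecord(generic_name=name, role=role))

    for i, (rid, code, name) in enumerate(reac.itertuples(index=False)):
        if rid not in reports:
            orphans["reac"] += 1
            continue
        if not code.strip():
            raise ParseError("empty pt_code", path=str(reac_path), line=i + 2)
        reports[rid].events.add(PreferredTerm(code=code, name=name))

    for rid, term in hist.itertuples(index=False):
        if rid not in reports:
            orphans["hist"] += 1
            continue
        if term.strip():
            reports[rid].histories.add(term)

    total_orphans = sum(orphans.values())
    if total_orphans:
        logger.warning(
            "orphan rows referencing unknown report_ids: drug=%d reac=%d hist=%d",
            orphans["drug"], orphans["reac"], orphans["hist"],
        )

    out = list(reports.values())
    if return_orphans:
        return out, orphans
    return out


def load_database_dir(db_dir: str | Path, **kw):
    """Load ``demo.csv``/``drug.csv``/``reac.csv``/``hist.csv`` from a directory."""
    d = Path(db_dir)
    return load_database(
        d / "demo.csv", d / "drug.csv", d / "reac.csv", d / "hist.csv", **kw
    )


def write_database(reports: list[CaseReport], out_dir: str | Path) -> dict[str, Path]:
    """Write reports back out in the canonical dialect (inverse of load).

    The demo age_description column is written as the banded value, so
    a round trip preserves ``age_band`` exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    demo_rows, drug_rows, reac_rows, hist_rows = [], [], [], []
    for r in reports:
        age_desc = "" if r.age_band == "excluded" else _band_to_description(r.age_band)
        demo_rows.append((r.report_id, age_desc, r.sex))
        for d in r.drugs:
            drug_rows.append((r.report_id, d.generic_name, d.role))
        for ev in sorted(r.events, key=lambda e: e.code):
            reac_rows.append((r.report_id, ev.code, ev.name))
        for t in sorted(r.histories):
            hist_rows.append((r.report_id, t))
    paths = {}
    for kind, rows in (
        ("demo", demo_rows), ("drug", drug_rows),
        ("reac", reac_rows), ("hist", hist_rows),
    ):
        p = out_dir / f"{kind}.csv"
        pd.DataFrame(rows, columns=_COLUMNS[kind]).to_csv(p, index=False)
        paths[kind] = p
    return paths


def _band_to_description(band: str) -> str:
    # representative in-band age; assign_age_band inverts it
    if band == "<=19":
        return "10"
    if band == ">=90":
        return "90"
    return band.split("-")[0]
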