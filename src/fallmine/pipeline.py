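"""End-to-end orchestration: one config → signal table + two rule tables.

A run mirrors the standard layout of an SRS fall-risk analysis:

* ``signals.csv`` — ROR disproportionality per drug class over the
  full database;
* ``rules_demographic.csv`` — rules over age-band and drug-count items
  (defaults: min support 1e-6, min confidence 0.001, maxlen 3);
* ``rules_history.csv`` — rules over class and comorbidity items in
  the ≥60 subgroup (defaults: min confidence 0.01, maxlen 4);
* ``run_log.json`` — D, exclusion counts, thresholds, version.

Outputs are deterministically ordered; a failure at any stage removes
partial outputs and re-raises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .disproportionality import detect_signals
from .drug_classes import CLASS_IDS, display_name
from .exceptions import ValidationError
from .io import load_database_dir
from .rules import ITEM_NAMESPACES, mine_rules, rules_to_records
from .schema import (
    AGE_BANDS,
    EXCLUDED,
    CaseReport,
    DEFAULT_EVENT_DEF,
    FallEventDefinition,
    flag_fall_related,
)


@dataclass
class RuleRunConfig:
    """Thresholds for one rule-mining pass."""

    items: tuple[str, ...]
    min_support: float = 1e-6
    min_confidence: float = 0.001
    maxlen: int = 3
    #: restrict to reports in this band or older (None = full database)
    min_age_band: str | None = None
    #: support denominator in subgroup runs: the subgroup itself
    #: ("subset") or the full database ("full", compatibility mode)
    support_denominator: str = "subset"

    def validate(self) -> None:
        unknown = [ns for ns in self.items if ns not in ITEM_NAMESPACES]
        if unknown:
            raise ValidationError(f"unknown item namespaces: {unknown}")
        if not self.items:
            raise ValidationError("rule run needs at least one item namespace")
        if not (0.0 < self.min_support <= 1.0):
            raise ValidationError("min_support must be in (0, 1]")
        if not (0.0 < self.min_confidence <= 1.0):
            raise ValidationError("min_confidence must be in (0, 1]")
        if self.maxlen < 1:
            raise ValidationError("maxlen must be >= 1")
        if self.min_age_band is not None and self.min_age_band not in AGE_BANDS:
            raise ValidationError(f"unknown age band {self.min_age_band!r}")
        if self.support_denominator not in ("subset", "full"):
            raise ValidationError("support_denominator must be 'subset' or 'full'")


@dataclass
class RunConfig:
    """Full-analysis configuration (loadable from YAML)."""

    db_dir: str
    output_dir: str
    classes: tuple[str, ...] = CLASS_IDS
    event_pts: tuple[tuple[str, str], ...] | None = None
    demographic_rules: RuleRunConfig = field(
        default_factory=lambda: RuleRunConfig(items=("age", "n_cns", "n_ccb"))
    )
    history_rules: RuleRunConfig = field(
        default_factory=lambda: RuleRunConfig(
            items=("class", "hist"),
            min_confidence=0.01,
            maxlen=4,
            min_age_band="60-69",
        )
    )
    seed: int = 0

    def validate(self) -> None:
        if not self.classes:
            raise ValidationError("class list must be non-empty")
        unknown = [c for c in self.classes if c not in CLASS_IDS]
        if unknown:
            raise ValidationError(f"unknown drug classes: {unknown}")
        self.demographic_rules.validate()
        self.history_rules.validate()

    @property
    def event_def(self) -> FallEventDefinition:
        if self.event_pts is None:
            return DEFAULT_EVENT_DEF
        return FallEventDefinition(pt_set=frozenset(self.event_pts))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for key in ("demographic_rules", "history_rules"):
            if key in kw and isinstance(kw[key], dict):
                sub = dict(kw[key])
                if "items" in sub:
                    sub["items"] = tuple(sub["items"])
                kw[key] = RuleRunConfig(**sub)
        if "classes" in kw:
            kw["classes"] = tuple(kw["classes"])
        if "event_pts" in kw and kw["event_pts"] is not None:
            kw["event_pts"] = tuple((str(c), str(n)) for c, n in kw["event_pts"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} is not a mapping")
        return cls.from_dict(data)


def _age_subset(reports: Sequence[CaseReport], min_band: str) -> list[CaseReport]:
    keep = set(AGE_BANDS[AGE_BANDS.index(min_band):])
    return [r for r in reports if r.age_band in keep]


def _signals_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": s.class_name,
                "label": display_name(s.class_name),
                "case_n": s.case_count,
                "class_total": s.class_total,
                "reporting_ratio_pct": round(s.reporting_ratio, 4),
                "ror": round(s.ror, 4),
                "ci_low": round(s.ci_low, 4),
                "ci_high": round(s.ci_high, 4),
                "is_signal": s.is_signal,
                "corrected": s.corrected,
            }
            for s in results
        ]
    )


def _run_rule_pass(
    reports: Sequence[CaseReport], cfg: RuleRunConfig, event_def: FallEventDefinition
) -> tuple[pd.DataFrame, dict]:
    subset = (
        _age_subset(reports, cfg.min_age_band)
        if cfg.min_age_band is not None
        else list(reports)
    )
    d_override = len(reports) if cfg.support_denominator == "full" else None
    if not subset:
        raise ValidationError("rule-mining subset contains zero reports")
    rules = mine_rules(
        subset,
        cfg.items,
        cfg.min_support,
        cfg.min_confidence,
        cfg.maxlen,
        event_def,
        d_override=d_override,
    )
    frame = pd.DataFrame(
        rules_to_records(rules),
        columns=[
            "lhs", "rhs", "case_n", "support", "confidence",
            "lift", "chi_squared", "significant",
        ],
    )
    meta = {
        "n_rules": len(rules),
        "subset_size": len(subset),
        "support_denominator": (
            len(reports) if cfg.support_denominator == "full" else len(subset)
        ),
        "thresholds": {
            "min_support": cfg.min_support,
            "min_confidence": cfg.min_confidence,
            "maxlen": cfg.maxlen,
            "min_age_band": cfg.min_age_band,
        },
    }
    return frame, meta


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run signals + both rule passes; returns paths of written outputs."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        reports, orphans = load_database_dir(config.db_dir, return_orphans=True)
        if not reports:
            raise ValidationError("database contains zero reports")
        event_def = config.event_def

        signals = detect_signals(reports, list(config.classes), event_def)
        signals_path = out_dir / "signals.csv"
        _signals_frame(signals).to_csv(signals_path, index=False)
        written.append(signals_path)

        demo_frame, demo_meta = _run_rule_pass(
            reports, config.demographic_rules, event_def
        )
        demo_path = out_dir / "rules_demographic.csv"
        demo_frame.to_csv(demo_path, index=False, float_format="%.10g")
        written.append(demo_path)

        hist_frame, hist_meta = _run_rule_pass(
            reports, config.history_rules, event_def
        )
        hist_path = out_dir / "rules_history.csv"
        hist_frame.to_csv(hist_path, index=False, float_format="%.10g")
        written.append(hist_path)

        n_excluded = sum(1 for r in reports if r.age_band == EXCLUDED)
        log = {
            "version": __version__,
            "seed": config.seed,
            "n_reports": len(reports),
            "n_age_excluded": n_excluded,
            "n_fall_related": sum(
                1 for r in reports if flag_fall_related(r, event_def)
            ),
            "orphan_rows": orphans,
            "classes": list(config.classes),
            "n_signals": sum(1 for s in signals if s.is_signal),
            "demographic_rules": demo_meta,
            "history_rules": hist_meta,
        }
        log_path = out_dir / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
        written.append(log_path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return {p.stem: p for p in written}
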