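"""Synthetic spontaneous-reporting databases with known planted structure.

The generator emulates the statistical skeleton a report-level
fall-risk analysis assumes: independent per-class drug exposures,
report ages on the 10-year grid, counts of concomitant CNS-active
drugs and calcium channel blockers, comorbidity terms, and a
fall-related outcome whose probability is multiplicative in the
present risk items,

    P(fall-related | report) = clip( baseline · Π multiplier(item) ).

At the rare outcome rates used here risk ratio ≈ odds ratio ≈ lift, so
a planted multiplier is directly interpretable as the effect each
downstream statistic should recover.

Two layers:

* a vectorised :class:`SyntheticDatabase` of numpy arrays (exposures,
  counts, outcome flags) for calibration studies at scale, with
  `contingency()` computing the same 2×2 counts the report-level path
  produces (an equivalence that is tested, not assumed);
* materialisation to :class:`~fallmine.schema.CaseReport` objects and
  the canonical four-table CSVs, drawing concrete drug names from the
  packaged ATC class lists plus inert filler drugs.

Exact fixtures (:func:`fixture_from_counts`, :func:`fixture_from_strata`)
rebuild databases from printed stratum counts so worked examples route
through the same code paths as simulated runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import io as db_io
from .disproportionality import ContingencyTable
from .drug_classes import CLASS_IDS, CLASS_TABLE, CNS_CLASS_IDS, COMPOSITE_GROUPS
from .exceptions import ValidationError
from .schema import AGE_BANDS, EXCLUDED, CaseReport, DrugRecord, PreferredTerm

# ---------------------------------------------------------------------------
# defaults: the study conditions the generator emulates

# Relative report volume per age band, reconstructed from the
# band-total exposure frequencies of a large national SRS snapshot.
_AGE_WEIGHTS = {
    "<=19": 12613, "20-29": 14667, "30-39": 25000, "40-49": 31667,
    "50-59": 53898, "60-69": 93235, "70-79": 98172, "80-89": 47007,
    ">=90": 5984,
}
_AGE_TOTAL = sum(_AGE_WEIGHTS.values())
DEFAULT_AGE_PROBS: dict[str, float] = {
    b: _AGE_WEIGHTS[b] / _AGE_TOTAL for b in AGE_BANDS
}

#: Fraction of reports whose age description cannot be banded.
DEFAULT_AGE_EXCLUDED_PROB = 0.11

# Per-class exposure probabilities matching the class report
# frequencies observed in a 430k-report SRS snapshot.
DEFAULT_CLASS_PREVALENCE: dict[str, float] = {
    "alpha_blockers": 4600 / 430587,
    "diuretics": 25016 / 430587,
    "calcium_channel_blockers": 51482 / 430587,
    "opioids": 23530 / 430587,
    "benzodiazepines": 38300 / 430587,
    "hypnotics_sedatives": 2865 / 430587,
    "nsmri": 3479 / 430587,
    "ssri": 9058 / 430587,
}

#: Total distinct CNS-active drugs per CNS-exposed report.
DEFAULT_CNS_COUNT_DIST: dict[int, float] = {
    1: 0.62, 2: 0.23, 3: 0.09, 4: 0.04, 5: 0.015, 6: 0.005,
}

#: Distinct calcium channel blockers per CCB-exposed report.
DEFAULT_CCB_COUNT_DIST: dict[int, float] = {1: 0.85, 2: 0.12, 3: 0.03}

DEFAULT_COMORBIDITY_PREVALENCE: dict[str, float] = {
    "hypertension": 0.15,
    "diabetes mellitus": 0.06,
    "type 2 diabetes mellitus": 0.04,
    "depression": 0.04,
    "insomnia": 0.04,
    "schizophrenia": 0.03,
    "pain": 0.03,
    "back pain": 0.02,
    "rheumatoid arthritis": 0.02,
    "dementia": 0.012,
    "osteoporosis": 0.012,
    "chronic hepatitis C": 0.01,
    "benign prostate hypertrophy": 0.01,
    "dementia Alzheimer's type": 0.008,
    "herpes zoster": 0.005,
}

# Multiplicative effects on the fall-related outcome, keyed by the
# same namespaced items rule mining emits.  Class and age effects are
# set to the association sizes reported for a large SRS analysis of
# fall-related events; comorbidity effects are modest plausible values.
DEFAULT_RISK_MULTIPLIERS: dict[str, float] = {
    "class:alpha_blockers": 1.63,
    "class:diuretics": 0.74,
    "class:calcium_channel_blockers": 1.26,
    "class:opioids": 0.93,
    "class:benzodiazepines": 1.83,
    "class:hypnotics_sedatives": 1.55,
    "class:nsmri": 2.31,
    "class:ssri": 2.86,
    "age:<=19": 2.58,
    "age:20-29": 0.70,
    "age:30-39": 0.65,
    "age:40-49": 0.69,
    "age:50-59": 0.68,
    "age:60-69": 0.79,
    "age:70-79": 1.08,
    "age:80-89": 1.59,
    "age:>=90": 1.47,
    "hist:dementia": 2.5,
    "hist:dementia Alzheimer's type": 2.0,
    "hist:herpes zoster": 1.8,
    "hist:depression": 1.6,
    "hist:insomnia": 1.6,
}

DEFAULT_BASELINE_FALL_PROB = 0.008

#: Inert drugs never mapped by the class tables.
FILLER_DRUGS: tuple[str, ...] = (
    "acetaminophen", "warfarin", "aspirin", "metformin", "atorvastatin",
    "rosuvastatin", "esomeprazole", "levothyroxine", "prednisolone",
    "clarithromycin", "cisplatin", "methotrexate",
)

#: Non-fall adverse events used to keep every report's event set non-empty.
FILLER_PTS: tuple[tuple[str, str], ...] = (
    ("10028813", "nausea"),
    ("10019211", "headache"),
    ("10037844", "rash"),
    ("10047700", "vomiting"),
    ("10012735", "diarrhoea"),
    ("10016256", "fatigue"),
    ("10043890", "thrombocytopenia"),
    ("10019851", "hepatic function abnormal"),
)

FALL_PT_CHOICES: tuple[tuple[str, str], ...] = (
    ("10016173", "fall"),
    ("10013573", "dizziness"),
    ("10031127", "orthostatic hypotension"),
)
_FALL_PT_WEIGHTS = (0.6, 0.3, 0.1)

_CNS_CLASS_SIZES = np.array(
    [len(CLASS_TABLE[c][1]) for c in CNS_CLASS_IDS], dtype=int
)


# ---------------------------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Generative parameters for a synthetic SRS database."""

    n_reports: int
    seed: int = 0
    age_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_PROBS))
    age_excluded_prob: float = DEFAULT_AGE_EXCLUDED_PROB
    class_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PREVALENCE))
    cns_count_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CNS_COUNT_DIST))
    ccb_count_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CCB_COUNT_DIST))
    comorbidity_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCE))
    baseline_fall_prob: float = DEFAULT_BASELINE_FALL_PROB
    risk_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_MULTIPLIERS))
    #: standard deviation of a shared latent log-odds shift inducing
    #: positive exposure correlation (polypharmacy); 0 = independent
    polypharmacy_sd: float = 0.0

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ValidationError("n_reports must be nonnegative")
        for name, vec in (
            ("age_probs", self.age_probs),
            ("cns_count_dist", self.cns_count_dist),
            ("ccb_count_dist", self.ccb_count_dist),
        ):
            vals = list(vec.values())
            if any(v < 0 for v in vals):
                raise ValidationError(f"{name} has negative probabilities")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1 (got {sum(vals)!r})")
        if set(self.age_probs) != set(AGE_BANDS):
            raise ValidationError("age_probs must cover exactly the 9 age bands")
        for name, p in (
            ("age_excluded_prob", self.age_excluded_prob),
            ("baseline_fall_prob", self.baseline_fall_prob),
        ):
            if not (0.0 <= p < 1.0):
                raise ValidationError(f"{name} must be in [0, 1)")
        if self.baseline_fall_prob <= 0.0:
            raise ValidationError("baseline_fall_prob must be in (0, 1)")
        for cls, p in self.class_prevalence.items():
            if cls not in CLASS_IDS:
                raise ValidationError(f"unknown class in class_prevalence: {cls!r}")
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"prevalence out of range for {cls!r}")
        for term, p in self.comorbidity_prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"prevalence out of range for {term!r}")
        for item, m in self.risk_multipliers.items():
            if m < 0:
                raise ValidationError(f"negative risk multiplier for {item!r}")
        if self.polypharmacy_sd < 0:
            raise ValidationError("polypharmacy_sd must be nonnegative")


@dataclass
class SyntheticDatabase:
    """Vectorised representation of one generated database.

    ``age_idx`` indexes :data:`~fallmine.schema.AGE_BANDS` (−1 =
    excluded); ``exposed`` is reports × 8 classes; ``hist`` maps terms
    to boolean arrays; ``fall`` is the planted outcome.
    """

    config: SyntheticConfig
    age_idx: np.ndarray
    exposed: np.ndarray
    n_cns: np.ndarray
    n_ccb: np.ndarray
    hist: dict[str, np.ndarray]
    p_fall: np.ndarray
    fall: np.ndarray

    @property
    def n_reports(self) -> int:
        return len(self.fall)

    def exposure_mask(self, group: str) -> np.ndarray:
        """Boolean report mask for a class or composite group."""
        if group in COMPOSITE_GROUPS:
            cols = [CLASS_IDS.index(c) for c in COMPOSITE_GROUPS[group]]
        elif group in CLASS_IDS:
            cols = [CLASS_IDS.index(group)]
        else:
            raise ValidationError(f"unknown drug class or group: {group!r}")
        return self.exposed[:, cols].any(axis=1)

    def contingency(self, group: str) -> ContingencyTable:
        """2×2 fall-related × exposure counts straight from the arrays.

        Count-identical to ``build_contingency`` over the materialised
        reports (every exposed report receives at least one drug of
        each exposed class and filler drugs are never class members).
        """
        mask = self.exposure_mask(group)
        a = int((mask & self.fall).sum())
        b = int((mask & ~self.fall).sum())
        c = int((~mask & self.fall).sum())
        d = int((~mask & ~self.fall).sum())
        return ContingencyTable(a, b, c, d)

    # -- materialisation ----------------------------------------------------

    def to_case_reports(self) -> list[CaseReport]:
        """Materialise concrete reports with drug names, events, histories.

        Deterministic given the config seed, independent of any array
        computations done before the call (separate child RNG stream).
        """
        rng = np.random.default_rng([int(self.config.seed) % (2**31), 7])
        n = self.n_reports
        cns_col = {c: CLASS_IDS.index(c) for c in CNS_CLASS_IDS}
        class_names = {c: sorted(CLASS_TABLE[c][1]) for c in CLASS_IDS}
        hist_terms = sorted(self.hist)
        hist_mat = (
            np.column_stack([self.hist[t] for t in hist_terms])
            if hist_terms else np.zeros((n, 0), dtype=bool)
        )

        # vectorised ancillary draws (loop below only assembles objects)
        role_u = rng.random(n)
        filler_drug_on = rng.random(n) < 0.9
        filler_drug_k = rng.integers(1, 3, size=n)
        fall_pt_idx = rng.choice(len(FALL_PT_CHOICES), size=n, p=_FALL_PT_WEIGHTS)
        extra_pt_on = rng.random(n) < 0.3
        filler_pt_idx = rng.integers(0, len(FILLER_PTS), size=(n, 2))
        filler_drug_idx = rng.integers(0, len(FILLER_DRUGS), size=(n, 2))

        reports: list[CaseReport] = []
        for i in range(n):
            drugs: list[DrugRecord] = []
            role = "suspected" if role_u[i] < 0.7 else "concomitant"
            exposed_cns = [c for c in CNS_CLASS_IDS if self.exposed[i, cns_col[c]]]
            if exposed_cns:
                # one drug per exposed CNS class, extras spread at random
                per_class = {c: 1 for c in exposed_cns}
                extra = int(self.n_cns[i]) - len(exposed_cns)
                for _ in range(max(extra, 0)):
                    open_classes = [
                        c for c in exposed_cns
                        if per_class[c] < len(class_names[c])
                    ]
                    if not open_classes:
                        break
                    per_class[rng.choice(open_classes)] += 1
                for c in exposed_cns:
                    picks = rng.choice(
                        class_names[c], size=per_class[c], replace=False
                    )
                    drugs.extend(DrugRecord(str(p), role) for p in picks)
            for c in ("alpha_blockers", "diuretics"):
                if self.exposed[i, CLASS_IDS.index(c)]:
                    drugs.append(
                        DrugRecord(str(rng.choice(class_names[c])), role)
                    )
            if self.exposed[i, CLASS_IDS.index("calcium_channel_blockers")]:
                picks = rng.choice(
                    class_names["calcium_channel_blockers"],
                    size=int(self.n_ccb[i]), replace=False,
                )
                drugs.extend(DrugRecord(str(p), role) for p in picks)
            if filler_drug_on[i] or not drugs:
                for j in range(int(filler_drug_k[i])):
                    drugs.append(
                        DrugRecord(FILLER_DRUGS[filler_drug_idx[i, j]], "concomitant")
                    )

            events: set[PreferredTerm] = set()
            if self.fall[i]:
                code, name = FALL_PT_CHOICES[fall_pt_idx[i]]
                events.add(PreferredTerm(code, name))
                if extra_pt_on[i]:
                    code, name = FILLER_PTS[filler_pt_idx[i, 0]]
                    events.add(PreferredTerm(code, name))
            else:
                code, name = FILLER_PTS[filler_pt_idx[i, 0]]
                events.add(PreferredTerm(code, name))
                if extra_pt_on[i]:
                    code, name = FILLER_PTS[filler_pt_idx[i, 1]]
                    events.add(PreferredTerm(code, name))

            histories = {
                hist_terms[j] for j in range(len(hist_terms)) if hist_mat[i, j]
            }
            band = EXCLUDED if self.age_idx[i] < 0 else AGE_BANDS[self.age_idx[i]]
            reports.append(
                CaseReport(
                    report_id=f"R{i + 1:07d}",
                    age_band=band,
                    drugs=drugs,
                    events=events,
                    histories=histories,
                )
            )
        return reports

    def write_csv(self, out_dir: str | Path) -> dict[str, Path]:
        paths = db_io.write_database(self.to_case_reports(), out_dir)
        truth_path = Path(out_dir) / "ground_truth.json"
        truth_path.write_text(json.dumps(self.ground_truth(), indent=2, sort_keys=True))
        paths["ground_truth"] = truth_path
        return paths

    def ground_truth(self) -> dict:
        """Planted parameters plus realised empirical rates."""
        cfg = asdict(self.config)
        cfg["cns_count_dist"] = {str(k): v for k, v in cfg["cns_count_dist"].items()}
        cfg["ccb_count_dist"] = {str(k): v for k, v in cfg["ccb_count_dist"].items()}
        empirical = {
            "fall_rate": float(self.fall.mean()) if self.n_reports else 0.0,
            "class_exposure": {
                c: float(self.exposed[:, j].mean()) if self.n_reports else 0.0
                for j, c in enumerate(CLASS_IDS)
            },
        }
        return {"config": cfg, "empirical": empirical}


# ---------------------------------------------------------------------------


def _truncated_count_draw(
    rng: np.random.Generator,
    dist: dict[int, float],
    minimum: np.ndarray,
) -> np.ndarray:
    """Per-report draw from an integer distribution truncated to ≥ minimum."""
    ks = np.array(sorted(dist), dtype=int)
    ps = np.array([dist[int(k)] for k in ks], dtype=float)
    out = np.array(minimum, dtype=int, copy=True)
    u = rng.random(len(minimum))
    for m in np.unique(minimum):
        if m <= 0:
            continue
        sel = minimum == m
        allowed = ks >= m
        if not allowed.any() or ps[allowed].sum() <= 0:
            continue  # distribution cannot reach m: keep the floor m
        pa = ps[allowed] / ps[allowed].sum()
        cdf = np.cumsum(pa)
        idx = np.searchsorted(cdf, u[sel], side="right").clip(0, len(pa) - 1)
        out[sel] = ks[allowed][idx]
    return out


def generate(config: SyntheticConfig) -> SyntheticDatabase:
    """Draw one synthetic database under the configured conditions.

    Exposures are independent Bernoulli per class (optionally
    correlated through a shared latent polypharmacy factor), the total
    CNS drug count follows ``cns_count_dist`` truncated to the number
    of exposed CNS classes (each exposed class contributes at least one
    distinct drug, keeping per-class marginals calibrated), and the
    outcome probability is the clipped multiplicative risk model.
    Same seed → byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(int(config.seed) % (2**31))
    n = config.n_reports

    # age band (-1 = excluded)
    band_p = np.array([config.age_probs[b] for b in AGE_BANDS])
    age_idx = rng.choice(len(AGE_BANDS), size=n, p=band_p)
    age_idx[rng.random(n) < config.age_excluded_prob] = -1

    # per-class exposure
    prev = np.array([config.class_prevalence.get(c, 0.0) for c in CLASS_IDS])
    if config.polypharmacy_sd > 0:
        z = rng.normal(0.0, config.polypharmacy_sd, size=n)[:, None]
        odds = prev / np.maximum(1 - prev, 1e-12) * np.exp(z)
        p_mat = odds / (1 + odds)
    else:
        p_mat = np.broadcast_to(prev, (n, len(CLASS_IDS)))
    exposed = rng.random((n, len(CLASS_IDS))) < p_mat

    # CNS drug count: >= number of exposed CNS classes, capped by the
    # number of distinct substances those classes offer
    cns_cols = [CLASS_IDS.index(c) for c in CNS_CLASS_IDS]
    k_exposed = exposed[:, cns_cols].sum(axis=1)
    n_cns = _truncated_count_draw(rng, config.cns_count_dist, k_exposed)
    cap = exposed[:, cns_cols] @ _CNS_CLASS_SIZES
    n_cns = np.minimum(n_cns, cap)

    ccb_exposed = exposed[:, CLASS_IDS.index("calcium_channel_blockers")]
    n_ccb = _truncated_count_draw(
        rng, config.ccb_count_dist, ccb_exposed.astype(int)
    )
    n_ccb = np.minimum(n_ccb, len(CLASS_TABLE["calcium_channel_blockers"][1]))

    hist = {
        term: rng.random(n) < p
        for term, p in sorted(config.comorbidity_prevalence.items())
    }

    # multiplicative risk over present items, in log space
    mult = config.risk_multipliers
    log_p = np.full(n, np.log(config.baseline_fall_prob))

    def bump(mask: np.ndarray, item: str) -> None:
        m = mult.get(item)
        if m is not None and m != 1.0:
            if m <= 0:
                log_p[mask] = -np.inf
            else:
                log_p[mask] += np.log(m)

    for j, band in enumerate(AGE_BANDS):
        bump(age_idx == j, f"age:{band}")
    for j, cid in enumerate(CLASS_IDS):
        bump(exposed[:, j], f"class:{cid}")
    for k in range(1, int(n_cns.max(initial=0)) + 1):
        bump(n_cns == k, f"n_cns:{k}")
    for k in range(1, int(n_ccb.max(initial=0)) + 1):
        bump(n_ccb == k, f"n_ccb:{k}")
    for term, flags in hist.items():
        bump(flags, f"hist:{term}")

    p_fall = np.clip(np.exp(log_p), 0.0, 1.0 - 1e-9)
    fall = rng.random(n) < p_fall

    return SyntheticDatabase(
        config=config,
        age_idx=age_idx,
        exposed=exposed,
        n_cns=n_cns,
        n_ccb=n_ccb,
        hist=hist,
        p_fall=p_fall,
        fall=fall,
    )


# ---------------------------------------------------------------------------
# exact fixtures from printed counts

_FIXTURE_FALL_PT = PreferredTerm("10016173", "fall")
_FIXTURE_OTHER_PT = PreferredTerm("10028813", "nausea")

# fixed, class-spanning CNS drug sequence for n_cns:k exposure specs
_CNS_SEQUENCE = (
    "fentanyl", "nitrazepam", "ramelteon", "amitriptyline", "sertraline",
    "morphine", "zolpidem", "melatonin", "imipramine", "paroxetine",
)
_CCB_SEQUENCE = tuple(sorted(CLASS_TABLE["calcium_channel_blockers"][1]))


def _apply_exposure(report: CaseReport, spec: str) -> None:
    """Apply one exposure item spec to a report in place.

    Specs: a class/group id (one representative drug), ``n_cns:<k>`` /
    ``n_ccb:<k>`` (k distinct drugs), ``age:<band>``, ``hist:<term>``.
    """
    if spec.startswith("age:"):
        band = spec.split(":", 1)[1]
        if band not in AGE_BANDS:
            raise ValidationError(f"unknown age band in exposure spec: {spec!r}")
        report.age_band = band
        return
    if spec.startswith("hist:"):
        report.histories.add(spec.split(":", 1)[1])
        return
    if spec.startswith("n_cns:"):
        k = int(spec.split(":", 1)[1])
        if not (1 <= k <= len(_CNS_SEQUENCE)):
            raise ValidationError(f"n_cns out of range in exposure spec: {spec!r}")
        report.drugs.extend(DrugRecord(nm) for nm in _CNS_SEQUENCE[:k])
        return
    if spec.startswith("n_ccb:"):
        k = int(spec.split(":", 1)[1])
        if not (1 <= k <= len(_CCB_SEQUENCE)):
            raise ValidationError(f"n_ccb out of range in exposure spec: {spec!r}")
        report.drugs.extend(DrugRecord(nm) for nm in _CCB_SEQUENCE[:k])
        return
    name = spec.split(":", 1)[1] if spec.startswith("class:") else spec
    if name in COMPOSITE_GROUPS and name != "calcium_channel_blockers":
        name = COMPOSITE_GROUPS[name][0]  # representative member class
    if name not in CLASS_IDS:
        raise ValidationError(f"unknown exposure spec: {spec!r}")
    report.drugs.append(DrugRecord(sorted(CLASS_TABLE[name][1])[0]))


def fixture_from_strata(
    strata: Sequence[tuple[Iterable[str], int, int]],
    id_prefix: str = "F",
) -> list[CaseReport]:
    """Exact database from disjoint strata of (exposure specs, n, n_fall).

    Each stratum contributes ``n`` reports carrying the given exposure
    items, ``n_fall`` of which carry the fall PT (the rest a filler
    PT).  Unexposed reports get an inert filler drug so no stratum
    leaks into a drug class by accident.
    """
    reports: list[CaseReport] = []
    counter = 0
    for specs, n_total, n_fall in strata:
        specs = tuple(specs)
        if n_total < 0 or n_fall < 0 or n_fall > n_total:
            raise ValidationError("stratum requires 0 <= n_fall <= n_total")
        for i in range(n_total):
            counter += 1
            r = CaseReport(report_id=f"{id_prefix}{counter:07d}")
            for spec in specs:
                _apply_exposure(r, spec)
            if not r.drugs:
                r.drugs.append(DrugRecord(FILLER_DRUGS[0], "concomitant"))
            r.events.add(_FIXTURE_FALL_PT if i < n_fall else _FIXTURE_OTHER_PT)
            reports.append(r)
    if not reports:
        raise ValidationError("fixture would contain zero reports")
    return reports


def fixture_from_counts(
    a: int, b: int, c: int, d: int, exposure: str | Iterable[str]
) -> list[CaseReport]:
    """Database whose 2×2 table for the exposure is exactly (a, b, c, d).

    ``exposure`` is an exposure spec (or several) as accepted by
    :func:`fixture_from_strata`: a drug class/group id, ``n_cns:<k>``,
    ``n_ccb:<k>``, ``age:<band>`` or ``hist:<term>``.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValidationError("all-zero contingency counts")
    specs = (exposure,) if isinstance(exposure, str) else tuple(exposure)
    return fixture_from_strata([(specs, a + b, a), ((), c + d, c)])
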