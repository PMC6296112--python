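"""Core report-level schema for a spontaneous-reporting-system database.

A report joins four relational tables (demographics, drugs, adverse
events, patient history) into one :class:`CaseReport`.  Ages are
stratified onto a fixed 10-year grid; adverse events are MedDRA
Preferred Terms treated as opaque (code, name) pairs; the fall-related
outcome is defined by a small PT set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .exceptions import ValidationError

#: The nine 10-year age bands, in order.
AGE_BANDS: tuple[str, ...] = (
    "<=19",
    "20-29",
    "30-39",
    "40-49",
    "50-59",
    "60-69",
    "70-79",
    "80-89",
    ">=90",
)

#: Sentinel age band for reports whose age description cannot be
#: placed on the 10-year grid (e.g. "elderly", "unknown", trimesters).
EXCLUDED = "excluded"

#: Display aliases used in formatted output (the last band is
#: conventionally printed as a closed decade).
AGE_BAND_ALIASES: dict[str, str] = {">=90": "90-99", "<=19": "10-19"}

#: Drug role codes: every report lists each drug as suspected,
#: concomitant, or interacting in the adverse event.
ROLES: frozenset[str] = frozenset({"suspected", "concomitant", "interacting"})

# Categorical age descriptions that cannot be banded.  Matching is
# case-insensitive on the whole (trimmed) string; any other string
# without a parseable integer is likewise excluded.
_CATEGORICAL_EXCLUDED = {
    "young adults",
    "adults",
    "adult",
    "elderly",
    "first trimester",
    "second trimester",
    "third trimester",
    "unknown",
    "",
}

_DECADE_RE = re.compile(r"(\d+)\s*(?:歳代|代)")
_INT_RE = re.compile(r"(\d+)")


def band_for_age(age: int) -> str:
    """Map an integer age in years onto the 10-year grid."""
    if age <= 19:
        return "<=19"
    if age >= 90:
        return ">=90"
    return f"{(age // 10) * 10}-{(age // 10) * 10 + 9}"


def assign_age_band(age_description: str) -> str:
    """Assign a raw age description to a band, or :data:`EXCLUDED`.

    Total function: numeric descriptions — plain years ("75"), suffixed
    years ("75歳"), or decade forms ("70歳代" → 70-79) — are banded;
    categorical descriptions ("elderly", "unknown", trimesters, ...)
    and anything without a parseable integer are excluded.
    """
    s = str(age_description).strip()
    if s.lower() in _CATEGORICAL_EXCLUDED:
        return EXCLUDED
    m = _DECADE_RE.search(s)
    if m:
        # decade form: "70歳代" means 70..79, so the decade start bands it
        return band_for_age(int(m.group(1)))
    m = _INT_RE.search(s)
    if m:
        return band_for_age(int(m.group(1)))
    return EXCLUDED


@dataclass(frozen=True, slots=True)
class DrugRecord:
    """One drug listed in a report, with its causality role code."""

    generic_name: str
    role: str = "suspected"
    atc_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"invalid drug role {self.role!r}; expected one of {sorted(ROLES)}"
            )


@dataclass(slots=True)
class PreferredTerm:
    """A MedDRA Preferred Term as an opaque (code, name) pair."""

    code: str
    name: str

    def __hash__(self) -> int:  # events live in sets keyed by code
        return hash(self.code)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PreferredTerm) and self.code == other.code


@dataclass(slots=True)
class CaseReport:
    """One joined spontaneous report.

    ``age_band`` is one of :data:`AGE_BANDS` or :data:`EXCLUDED`;
    ``events`` must be non-empty for a report that contributes to any
    analysis.
    """

    report_id: str
    age_band: str = EXCLUDED
    drugs: list[DrugRecord] = field(default_factory=list)
    events: set[PreferredTerm] = field(default_factory=set)
    histories: set[str] = field(default_factory=set)
    sex: str = ""


#: Default fall-related outcome: the three MedDRA PTs covering falls
#: and their proximate precursors.
FALL_PTS: frozenset[tuple[str, str]] = frozenset(
    {
        ("10016173", "fall"),
        ("10013573", "dizziness"),
        ("10031127", "orthostatic hypotension"),
    }
)


@dataclass(frozen=True)
class FallEventDefinition:
    """The PT set defining the fall-related outcome (extensible)."""

    pt_set: frozenset[tuple[str, str]] = FALL_PTS

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(code for code, _ in self.pt_set)


DEFAULT_EVENT_DEF = FallEventDefinition()


def flag_fall_related(
    report: CaseReport, event_def: FallEventDefinition = DEFAULT_EVENT_DEF
) -> bool:
    """True iff any event PT of the report is in the outcome definition."""
    codes = event_def.codes
    return any(ev.code in codes for ev in report.events)
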