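"""Reporting-odds-ratio disproportionality analysis.

For an index drug class and a target event definition the database is
collapsed to the 2×2 table

==============  ============  ============
                target event  other events
index class         a             b
other drugs         c             d
==============  ============  ============

and the crude reporting odds ratio ROR = (a/c)/(b/d) is computed with
a 95% confidence interval on the log-odds scale (Woolf):

    exp( ln ROR ± 1.96 · sqrt(1/a + 1/b + 1/c + 1/d) )

A class is flagged as a safety signal when the lower CI bound exceeds
1 and at least two target-event cases were reported.  Tables with a
zero cell get the Haldane–Anscombe +0.5 correction to every cell and
an explicit ``corrected`` flag; the case-count filter still uses the
uncorrected count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import drug_classes
from .exceptions import ValidationError
from .schema import CaseReport, FallEventDefinition, DEFAULT_EVENT_DEF, flag_fall_related

Z_95 = 1.96
MIN_CASES_FOR_SIGNAL = 2


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Report counts: a = event & class, b = other events & class,
    c = event & other drugs, d = other events & other drugs."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("contingency table is all zero")

    @property
    def n_reports(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def class_total(self) -> int:
        return self.a + self.b

    @property
    def event_total(self) -> int:
        return self.a + self.c


@dataclass(frozen=True, slots=True)
class SignalResult:
    """One row of a signal table for one drug class."""

    class_name: str
    case_count: int
    class_total: int
    reporting_ratio: float  # 100·a/(a+b)
    ror: float
    ci_low: float
    ci_high: float
    is_signal: bool
    corrected: bool  # Haldane–Anscombe +0.5 applied


def build_contingency(
    reports: list[CaseReport],
    class_name: str,
    event_def: FallEventDefinition = DEFAULT_EVENT_DEF,
) -> ContingencyTable:
    """Collapse reports to the 2×2 table for one class.

    Class membership means any drug in the report maps to the class
    (or composite group); each report is counted exactly once.
    """
    if not reports:
        raise ValidationError("cannot build a contingency table from zero reports")
    drug_classes.group_members(class_name)  # raises KeyError if unknown
    a = b = c = d = 0
    for r in reports:
        exposed = class_name in drug_classes.report_classes(r)
        event = flag_fall_related(r, event_def)
        if exposed:
            if event:
                a += 1
            else:
                b += 1
        elif event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def ror(table: ContingencyTable, class_name: str = "") -> SignalResult:
    """Crude ROR with Woolf 95% CI and the signal flag for one table."""
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        fa, fb, fc, fd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        fa, fb, fc, fd = float(a), float(b), float(c), float(d)
    estimate = (fa / fc) / (fb / fd)
    se = math.sqrt(1 / fa + 1 / fb + 1 / fc + 1 / fd)
    ci_low = math.exp(math.log(estimate) - Z_95 * se)
    ci_high = math.exp(math.log(estimate) + Z_95 * se)
    class_total = a + b
    return SignalResult(
        class_name=class_name,
        case_count=a,
        class_total=class_total,
        reporting_ratio=100.0 * a / class_total if class_total else 0.0,
        ror=estimate,
        ci_low=ci_low,
        ci_high=ci_high,
        is_signal=(ci_low > 1.0 and a >= MIN_CASES_FOR_SIGNAL),
        corrected=corrected,
    )


def ror_from_counts(a: int, b: int, c: int, d: int, class_name: str = "") -> SignalResult:
    """Convenience wrapper: ROR directly from the four cell counts."""
    return ror(ContingencyTable(a, b, c, d), class_name=class_name)


def detect_signals(
    reports: list[CaseReport],
    class_list: list[str],
    event_def: FallEventDefinition = DEFAULT_EVENT_DEF,
) -> list[SignalResult]:
    """One :class:`SignalResult` per requested class, in list order."""
    if not class_list:
        raise ValidationError("class_list must be non-empty")
    for name in class_list:
        try:
            drug_classes.group_members(name)
        except KeyError as exc:
            raise ValidationError(str(exc)) from exc
    # single pass over reports: membership and event flags per report
    tables = {name: [0, 0, 0, 0] for name in class_list}
    for r in reports:
        classes = drug_classes.report_classes(r)
        event = flag_fall_related(r, event_def)
        for name in class_list:
            cell = tables[name]
            if name in classes:
                cell[0 if event else 1] += 1
            else:
                cell[2 if event else 3] += 1
    return [
        ror(ContingencyTable(*tables[name]), class_name=name) for name in class_list
    ]
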