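"""Screening-quality audit: coverage, attendance regularity, and per-test
underuse / overuse / inappropriateness.

For one audit period each sex-applicable (person, test) pair falls in
exactly one cell of a 2x2 :class:`TestTally`: indication is judged by the
rule engine at the period end, and "requested" means some visit inside the
period requested the test. From the tally:

* underuse          = indicated but not requested / all indicated
* overuse           = requested though not indicated / all non-indicated
* inappropriateness = (underused + overused) / denominator, where the
  denominator is all sex-applicable persons (``cases``, the default) or all
  requested tests (``requested``) — both conventions are in circulation.

Percentages are *truncated* (not rounded) to two decimals by default, in
exact integer arithmetic; rounding is available as an option. A zero
denominator makes a proportion not-applicable (``None``), never an error.
"""

from __future__ import annotations

import json
import math
from datetime import date
from typing import Iterable, Literal, Optional

from pydantic import BaseModel, Field

from .engine import RuleSet, is_indicated
from .errors import ConfigError
from .records import PersonRecord, TestCode

Rounding = Literal["truncate", "round"]
Denominator = Literal["cases", "requested"]


def percent(numerator: int, denominator: int, rounding: Rounding = "truncate",
            decimals: int = 2) -> Optional[float]:
    """``100 * numerator / denominator`` at ``decimals`` places.

    Truncation is computed in integer arithmetic so printed-table arithmetic
    is reproduced exactly (e.g. 108/261 -> 41.37, not 41.38). Returns None
    when the denominator is zero.
    """
    if denominator == 0:
        return None
    scale = 10 ** decimals
    if rounding == "truncate":
        return (100 * scale * numerator // denominator) / scale
    return round(100 * numerator / denominator, decimals)


def truncate_value(x: float, decimals: int = 0) -> float:
    """Truncate a float toward zero at ``decimals`` places (epsilon-guarded)."""
    scale = 10 ** decimals
    return math.trunc(x * scale + math.copysign(1e-9, x)) / scale


class TestTally(BaseModel):
    """2x2 indication-by-request counts for one test over one audit period."""

    test_code: TestCode
    indicated_requested: int = 0
    indicated_not_requested: int = 0      # underused
    notindicated_requested: int = 0       # overused
    notindicated_not_requested: int = 0

    @property
    def indicated_total(self) -> int:
        return self.indicated_requested + self.indicated_not_requested

    @property
    def notindicated_total(self) -> int:
        return self.notindicated_requested + self.notindicated_not_requested

    @property
    def requested_total(self) -> int:
        return self.indicated_requested + self.notindicated_requested

    @property
    def cases_total(self) -> int:
        return self.indicated_total + self.notindicated_total


def classify_test_events(cohort: Iterable[PersonRecord], ruleset: RuleSet,
                         period: tuple[date, date]) -> list[TestTally]:
    """Cross-tabulate indication (at period end) against requests (visits
    within the period) for every test with a rule, per sex-applicable person.
    """
    start, end = period
    if start > end:
        raise ValueError("period start must be <= end")
    tallies = {code: TestTally(test_code=code)
               for code in sorted({r.test_code for r in ruleset.rules},
                                  key=lambda c: c.value)}
    for rec in cohort:
        requested: set[TestCode] = set()
        for v in rec.visits:
            if start <= v.date <= end:
                requested.update(v.tests_requested)
        for rule in ruleset.rules_for_sex(rec.sex):
            ind, _ = is_indicated(rec, rule, end)
            req = rule.test_code in requested
            t = tallies[rule.test_code]
            if ind and req:
                t.indicated_requested += 1
            elif ind:
                t.indicated_not_requested += 1
            elif req:
                t.notindicated_requested += 1
            else:
                t.notindicated_not_requested += 1
    return list(tallies.values())


def underuse_proportion(tally: TestTally, rounding: Rounding = "truncate") -> Optional[float]:
    """Percent of indicated cases whose test was never requested."""
    return percent(tally.indicated_not_requested, tally.indicated_total, rounding)


def overuse_proportion(tally: TestTally, rounding: Rounding = "truncate") -> Optional[float]:
    """Percent of non-indicated cases whose test was requested anyway."""
    return percent(tally.notindicated_requested, tally.notindicated_total, rounding)


def inappropriateness(tally: TestTally, denominator: Denominator = "cases",
                      rounding: Rounding = "truncate") -> Optional[float]:
    """Percent of inappropriate (underused + overused) tests.

    ``denominator='cases'`` divides by all sex-applicable persons;
    ``'requested'`` divides by all requested tests.
    """
    num = tally.indicated_not_requested + tally.notindicated_requested
    den = tally.cases_total if denominator == "cases" else tally.requested_total
    return percent(num, den, rounding)


class Coverage(BaseModel):
    attended: int
    eligible: int
    value: float      # percent, two decimals
    headline: int     # percent truncated to an integer

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.attended}/{self.eligible} ({self.headline}%)"


def coverage(attended: int, eligible: int, rounding: Rounding = "truncate") -> Coverage:
    """Screening coverage: attendees over the eligible population."""
    if eligible <= 0:
        raise ValueError("eligible must be > 0")
    if not 0 <= attended <= eligible:
        raise ValueError("attended must be in [0, eligible]")
    value = percent(attended, eligible, rounding)
    return Coverage(attended=attended, eligible=eligible, value=value,
                    headline=int(percent(attended, eligible, rounding, decimals=0)))


def average_percent(values: Iterable[float], rounding: Rounding = "truncate") -> float:
    """Headline (integer-percent) mean of several coverage percentages."""
    values = list(values)
    mean = sum(values) / len(values)
    return truncate_value(mean, 0) if rounding == "truncate" else round(mean, 0)


def irregular_attendance(cohort: Iterable[PersonRecord], period: tuple[date, date],
                         max_gap: int = 365,
                         rounding: Rounding = "truncate") -> Optional[float]:
    """Percent of participants whose attendance over the period was irregular:
    no visit at all in some calendar year of the period, or any gap between
    consecutive visits longer than ``max_gap`` days."""
    start, end = period
    if start > end:
        raise ValueError("period start must be <= end")
    cohort = list(cohort)
    if not cohort:
        return None
    years = range(start.year, end.year + 1)
    irregular = 0
    for rec in cohort:
        dates = sorted(v.date for v in rec.visits if start <= v.date <= end)
        visit_years = {d.year for d in dates}
        gaps = [(b - a).days for a, b in zip(dates, dates[1:])]
        if any(y not in visit_years for y in years) or any(g > max_gap for g in gaps):
            irregular += 1
    return percent(irregular, len(cohort), rounding)


class RequestCounts(BaseModel):
    per_test: dict[TestCode, int]
    total: int


def count_requested(cohort: Iterable[PersonRecord], period: tuple[date, date]) -> RequestCounts:
    """Count test-request events (one per test per visit) within the period."""
    start, end = period
    counts: dict[TestCode, int] = {code: 0 for code in TestCode}
    for rec in cohort:
        for v in rec.visits:
            if start <= v.date <= end:
                for code in v.tests_requested:
                    counts[code] += 1
    return RequestCounts(per_test=counts, total=sum(counts.values()))


class TestQualityRow(BaseModel):
    test_code: TestCode
    tally: TestTally
    underuse: Optional[float]
    overuse: Optional[float]
    inappropriateness: Optional[float]
    requested: int


class QualityReport(BaseModel):
    """The assembled audit: serializable to JSON, renderable as a table."""

    period_start: date
    period_end: date
    n_participants: int
    coverage: Optional[Coverage] = None
    irregular_attendance: Optional[float] = None
    rows: list[TestQualityRow]
    requested_grand_total: int
    denominator_convention: Denominator
    rounding: Rounding

    def row(self, test_code: TestCode) -> TestQualityRow:
        for r in self.rows:
            if r.test_code == test_code:
                return r
        raise KeyError(test_code)

    def to_json(self) -> str:
        return self.model_dump_json(indent=1)

    def to_table(self) -> str:
        def fmt(x: Optional[float]) -> str:
            return "n/a" if x is None else f"{x:g}%"

        lines = [
            f"Screening-quality audit {self.period_start} .. {self.period_end} "
            f"({self.n_participants} participants; denominator={self.denominator_convention}, "
            f"{self.rounding}d percentages)",
        ]
        if self.coverage is not None:
            lines.append(f"Coverage: {self.coverage}")
        if self.irregular_attendance is not None:
            lines.append(f"Irregular attendance: {fmt(self.irregular_attendance)}")
        header = (f"{'Test':<26} {'Underused':>14} {'Overused':>14} "
                  f"{'Inappropriate':>14} {'Requested':>10}")
        lines += ["", header, "-" * len(header)]
        for r in self.rows:
            t = r.tally
            lines.append(
                f"{r.test_code.value:<26} "
                f"{f'{t.indicated_not_requested}/{t.indicated_total}':>7} {fmt(r.underuse):>6} "
                f"{f'{t.notindicated_requested}/{t.notindicated_total}':>7} {fmt(r.overuse):>6} "
                f"{fmt(r.inappropriateness):>14} {r.requested:>10}")
        lines.append("-" * len(header))
        lines.append(f"{'Total requested':<26} {self.requested_grand_total:>72}")
        return "\n".join(lines)


def audit(cohort: list[PersonRecord], ruleset: RuleSet, period: tuple[date, date], *,
          eligible: Optional[int] = None,
          denominator: Denominator = "cases",
          rounding: Rounding = "truncate",
          max_gap: int = 365) -> QualityReport:
    """Full audit of a cohort against a ruleset over a period.

    ``eligible`` (the size of the population invited to screening) enables
    the coverage figure; without it coverage is omitted.
    """
    if denominator not in ("cases", "requested"):
        raise ConfigError(f"unknown denominator convention {denominator!r}")
    tallies = classify_test_events(cohort, ruleset, period)
    counts = count_requested(cohort, period)
    rows = [TestQualityRow(
        test_code=t.test_code, tally=t,
        underuse=underuse_proportion(t, rounding),
        overuse=overuse_proportion(t, rounding),
        inappropriateness=inappropriateness(t, denominator, rounding),
        requested=counts.per_test.get(t.test_code, 0),
    ) for t in tallies]
    cov = coverage(len(cohort), eligible, rounding) if eligible else None
    return QualityReport(
        period_start=period[0], period_end=period[1], n_participants=len(cohort),
        coverage=cov,
        irregular_attendance=irregular_attendance(cohort, period, max_gap, rounding),
        rows=rows, requested_grand_total=counts.total,
        denominator_convention=denominator, rounding=rounding)


def report_to_json(report: QualityReport) -> str:
    return json.dumps(json.loads(report.to_json()), indent=1)
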