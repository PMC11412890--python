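"""Drug–event combination counting and 2×2 contingency tables.

The counting unit throughout is the distinct (report, term) *combination*:
one report mentioning the same preferred term twice contributes once, and a
report with three distinct terms contributes three combinations.  At SOC
level each report contributes once per distinct system organ class after
PT→SOC mapping.  The 2×2 table for a (drug, term) pair is then

    =============  ==============  =============
    .              target term     other terms
    target drug    a               b
    other drugs    c               d
    =============  ==============  =============

with a+b the target drug's total combinations and n = a+b+c+d the total
combination count in the background period.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .faers_io import CleanReport

logger = logging.getLogger(__name__)

__all__ = [
    "CombinationCounts",
    "ContingencyTable",
    "build_combination_counts",
    "make_contingency",
    "stratify",
    "report_terms",
    "UNMAPPED_SOC",
]

UNMAPPED_SOC = "unmapped"

Level = Literal["PT", "SOC"]


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d cells for one (drug, term) pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative contingency cell: {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count a under row/column independence: (a+b)(a+c)/n."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class CombinationCounts:
    """Per-term distinct (report, term) counts for target and background."""

    level: Level
    n_target: Counter
    n_other: Counter
    m_target: int
    m_other: int
    unmapped_pts: frozenset[str] = frozenset()

    def terms(self) -> list[str]:
        return sorted(set(self.n_target) | set(self.n_other))

    def validate(self) -> None:
        if sum(self.n_target.values()) != self.m_target:
            raise ValueError("target combination counts do not sum to M_target")
        if sum(self.n_other.values()) != self.m_other:
            raise ValueError("background combination counts do not sum to M_other")


def report_terms(
    report: CleanReport,
    level: Level = "PT",
    pt_to_soc: Mapping[str, str] | None = None,
    _unmapped: set[str] | None = None,
) -> frozenset[str]:
    """Distinct terms one report contributes at the requested level."""
    if level == "PT":
        return report.reactions
    if pt_to_soc is None:
        raise ValueError("SOC level requires a PT→SOC mapping")
    socs = set()
    for pt in report.reactions:
        soc = pt_to_soc.get(pt.casefold())
        if soc is None:
            if _unmapped is not None:
                _unmapped.add(pt)
            soc = UNMAPPED_SOC
        socs.add(soc)
    return frozenset(socs)


def build_combination_counts(
    target_reports: Iterable[CleanReport],
    background_reports: Iterable[CleanReport],
    level: Level = "PT",
    pt_to_soc: Mapping[str, str] | None = None,
) -> CombinationCounts:
    """Count distinct (report, term) combinations for target and background.

    The two report sets must be disjoint by primaryid: a report is either a
    target-drug report or part of the background, never both.  PTs absent
    from the SOC map are pooled under the reserved ``"unmapped"`` bucket
    and logged.
    """
    target_reports = list(target_reports)
    background_reports = list(background_reports)
    t_ids = {r.primaryid for r in target_reports}
    overlap = t_ids & {r.primaryid for r in background_reports}
    if overlap:
        raise ValueError(
            f"target and background share {len(overlap)} primaryids (e.g. {sorted(overlap)[:3]})"
        )
    unmapped: set[str] = set()
    n_target: Counter = Counter()
    for r in target_reports:
        n_target.update(report_terms(r, level, pt_to_soc, unmapped))
    n_other: Counter = Counter()
    for r in background_reports:
        n_other.update(report_terms(r, level, pt_to_soc, unmapped))
    if unmapped:
        logger.warning(
            "%d PTs missing from the SOC map counted under %r: %s",
            len(unmapped), UNMAPPED_SOC, sorted(unmapped)[:5],
        )
    counts = CombinationCounts(
        level=level,
        n_target=n_target,
        n_other=n_other,
        m_target=sum(n_target.values()),
        m_other=sum(n_other.values()),
        unmapped_pts=frozenset(unmapped),
    )
    counts.validate()
    return counts


def make_contingency(counts: CombinationCounts, term: str) -> ContingencyTable:
    """Build the 2×2 table for one term from combination counts."""
    a = counts.n_target.get(term, 0)
    c = counts.n_other.get(term, 0)
    b = counts.m_target - a
    d = counts.m_other - c
    if b < 0 or d < 0:
        raise ValueError(f"corrupted counts for term {term!r}: a={a}, M_target={counts.m_target}")
    return ContingencyTable(a=a, b=b, c=c, d=d)


_AGE_BANDS = ((0, 18, "<18"), (18, 45, "18-44"), (45, 65, "45-64"), (65, 131, ">=65"))


def age_band(age_years: float | None) -> str | None:
    if age_years is None:
        return None
    for lo, hi, label in _AGE_BANDS:
        if lo <= age_years < hi:
            return label
    return None


def stratify(
    reports: Iterable[CleanReport],
    key: str,
    indications: Sequence[str] | None = None,
) -> tuple[dict, list[CleanReport]]:
    """Partition reports by year, sex or age band, or select by indication.

    Returns ``(strata, missing)``: for ``receipt_year``/``sex``/``age_band``
    the strata are disjoint and exhaustive over reports with a non-missing
    value and ``missing`` collects the rest (an audit bucket, never silently
    dropped).  For ``indication_PT`` each stratum holds the reports whose
    PS-drug indications contain that PT; strata may overlap and ``missing``
    holds reports matching none of the requested indications.
    """
    reports = list(reports)
    strata: dict = {}
    missing: list[CleanReport] = []
    if key == "indication_PT":
        if not indications:
            raise ValueError("indication_PT stratification needs a list of indication PTs")
        wanted = {i.casefold(): i for i in indications}
        strata = {i: [] for i in indications}
        for r in reports:
            hit = False
            for ind in r.indications:
                lab = wanted.get(ind.casefold())
                if lab is not None:
                    strata[lab].append(r)
                    hit = True
            if not hit:
                missing.append(r)
        return strata, missing

    if key == "receipt_year":
        getter = lambda r: r.receipt_year
    elif key == "sex":
        getter = lambda r: r.sex
    elif key == "age_band":
        getter = lambda r: age_band(r.age_years)
    else:
        raise ValueError(f"unsupported stratification key {key!r}")
    for r in reports:
        v = getter(r)
        if v is None:
            missing.append(r)
        else:
            strata.setdefault(v, []).append(r)
    return dict(sorted(strata.items())), missing
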