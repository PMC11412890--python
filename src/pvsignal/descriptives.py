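"""Descriptive summaries of a cleaned report set.

Demographics, seriousness and outcome distributions, reporter/country/route
frequencies, indication ranking and SOC-level combination proportions —
the tables a pharmacovigilance write-up prints before any signal statistic.
Percentages are rounded half-up to two decimals to match printed style.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .contingency import UNMAPPED_SOC, age_band
from .faers_io import CleanReport

__all__ = [
    "percentage",
    "SummaryTable",
    "demographic_summary",
    "indication_ranking",
    "soc_report_proportions",
]


def percentage(numerator: int, denominator: int) -> float:
    """100·numerator/denominator, rounded half-up to 2 decimals.

    A zero denominator yields NaN (undefined) rather than an exception.
    """
    if denominator == 0:
        return math.nan
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class SummaryTable:
    """(block, item, count, percent) rows plus the denominator per block."""

    rows: pd.DataFrame  # columns: block, item, count, percent
    denominators: dict[str, int]

    def block(self, name: str) -> pd.DataFrame:
        return self.rows[self.rows["block"] == name].reset_index(drop=True)


_NOT_SPECIFIED = "Not Specified"

_AGE_BAND_ORDER = ["<18", "18-44", "45-64", ">=65", _NOT_SPECIFIED]


def _count_block(values: Iterable[str | None], order: list[str] | None = None) -> list[tuple[str, int]]:
    c = Counter(_NOT_SPECIFIED if v is None else v for v in values)
    if order is not None:
        return [(k, c[k]) for k in order if k in c]
    return sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))


def demographic_summary(
    reports: Iterable[CleanReport],
    top_countries: int = 5,
) -> SummaryTable:
    """Table of sex, age, year, reporter, country, route, seriousness, outcomes.

    Outcome rows are multi-select (one report can carry several outcomes),
    so outcome percents may jointly exceed 100; every other block uses the
    report count as denominator with missing values as explicit
    "Not Specified" rows.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("demographic_summary needs a non-empty report set")
    n = len(reports)
    rows: list[dict] = []
    denoms: dict[str, int] = {}

    def add_block(block: str, items: list[tuple[str, int]]) -> None:
        denoms[block] = n
        for item, count in items:
            rows.append(
                {"block": block, "item": item, "count": count, "percent": percentage(count, n)}
            )

    sex_labels = {"F": "Female", "M": "Male", None: _NOT_SPECIFIED}
    add_block("sex", _count_block(sex_labels[r.sex] for r in reports))
    add_block(
        "age_group",
        _count_block((age_band(r.age_years) or _NOT_SPECIFIED for r in reports), _AGE_BAND_ORDER),
    )

    ages = np.array([r.age_years for r in reports if r.age_years is not None])
    if ages.size:
        q1, med, q3 = np.percentile(ages, [25, 50, 75])
        rows.append({"block": "age_years", "item": "median", "count": float(med), "percent": math.nan})
        rows.append({"block": "age_years", "item": "q1", "count": float(q1), "percent": math.nan})
        rows.append({"block": "age_years", "item": "q3", "count": float(q3), "percent": math.nan})

    add_block(
        "reporting_year",
        sorted(
            _count_block(str(r.receipt_year) if r.receipt_year else None for r in reports),
            key=lambda kv: kv[0],
        ),
    )
    add_block("reporter", _count_block(r.reporter for r in reports))

    country_counts = Counter(r.country or _NOT_SPECIFIED for r in reports)
    top = country_counts.most_common(top_countries)
    add_block("country", top)

    add_block("route", _count_block(r.route for r in reports))
    add_block(
        "seriousness",
        [("Serious", sum(r.serious for r in reports)),
         ("Non-Serious", sum(not r.serious for r in reports))],
    )
    outcome_counts = Counter(o for r in reports for o in r.outcomes)
    add_block("outcomes", sorted(outcome_counts.items(), key=lambda kv: (-kv[1], kv[0])))

    return SummaryTable(rows=pd.DataFrame(rows), denominators=denoms)


def indication_ranking(reports: Iterable[CleanReport]) -> pd.DataFrame:
    """Indication PTs ranked by report count (ties alphabetical).

    Each report contributes once per distinct indication on its PS drug;
    the percent denominator is the number of reports, so a report with two
    indications is counted under both.
    """
    reports = list(reports)
    n = len(reports)
    counts: Counter = Counter()
    for r in reports:
        counts.update(set(r.indications))
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [{"indication": pt, "count": c, "percent": percentage(c, n)} for pt, c in items]
    )


def soc_report_proportions(
    reports: Iterable[CleanReport],
    pt_to_soc: Mapping[str, str],
) -> pd.DataFrame:
    """Share of drug–event combinations falling under each SOC.

    The numerator is the number of distinct (report, PT) combinations whose
    PT maps to the SOC and the denominator is the total combination count,
    so the percents sum to 100 up to rounding.  Unmapped PTs appear under
    the reserved "unmapped" row.
    """
    soc_counts: Counter = Counter()
    total = 0
    for r in reports:
        for pt in r.reactions:
            soc_counts[pt_to_soc.get(pt.casefold(), UNMAPPED_SOC)] += 1
            total += 1
    items = sorted(soc_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [{"soc": soc, "count": c, "percent": percentage(c, total)} for soc, c in items]
    )
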