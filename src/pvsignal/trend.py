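"""IC-over-time series for a term, per calendar year or cumulatively.

Per-year mode rebuilds all four contingency cells from that year's reports
alone (so sparse years show wide credible intervals); cumulative mode uses
every report up to and including each year, in which case the final point
reproduces the pooled analysis exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from .contingency import build_combination_counts, make_contingency
from .dispro import BcpnnHyper, compute_bcpnn
from .faers_io import CleanReport

__all__ = ["YearlyIcPoint", "ic_time_series", "trend_frame"]


@dataclass(frozen=True)
class YearlyIcPoint:
    year: int
    a: int
    b: int
    c: int
    d: int
    ic: float
    ic_sd: float
    ic_lo: float  # ic − 1.96·sd
    ic_hi: float  # ic + 1.96·sd
    ic025: float  # ic − 2·sd (screening bound)
    n_stratum: int  # total combinations in the stratum
    defined: bool = True


def ic_time_series(
    reports_target: Iterable[CleanReport],
    reports_background: Iterable[CleanReport],
    term: str,
    level: Literal["PT", "SOC"] = "SOC",
    mode: Literal["per_year", "cumulative"] = "per_year",
    pt_to_soc: Mapping[str, str] | None = None,
    hyper: BcpnnHyper = BcpnnHyper(),
) -> list[YearlyIcPoint]:
    """IC and credible bounds for one term, year by year.

    Reports without a receipt year are excluded from every stratum.  A year
    in which no combinations exist at all yields an undefined-flagged point
    (zeros and NaN IC) rather than being dropped, so series stay aligned
    across terms.
    """
    target = [r for r in reports_target if r.receipt_year is not None]
    background = [r for r in reports_background if r.receipt_year is not None]
    years = sorted({r.receipt_year for r in target} | {r.receipt_year for r in background})
    points: list[YearlyIcPoint] = []
    for year in years:
        if mode == "per_year":
            sel = lambda r: r.receipt_year == year
        elif mode == "cumulative":
            sel = lambda r: r.receipt_year <= year
        else:
            raise ValueError(f"unknown mode {mode!r}")
        counts = build_combination_counts(
            [r for r in target if sel(r)],
            [r for r in background if sel(r)],
            level=level,
            pt_to_soc=pt_to_soc,
        )
        n_stratum = counts.m_target + counts.m_other
        if n_stratum == 0:
            points.append(
                YearlyIcPoint(year, 0, 0, 0, 0, float("nan"), float("nan"),
                              float("nan"), float("nan"), float("nan"), 0, defined=False)
            )
            continue
        t = make_contingency(counts, term)
        b = compute_bcpnn(t, hyper)
        points.append(
            YearlyIcPoint(
                year=year, a=t.a, b=t.b, c=t.c, d=t.d,
                ic=b.ic, ic_sd=b.ic_sd, ic_lo=b.ic_lo95, ic_hi=b.ic_hi95,
                ic025=b.ic025, n_stratum=n_stratum,
            )
        )
    return points


def trend_frame(points_by_term: Mapping[str, list[YearlyIcPoint]]) -> pd.DataFrame:
    """Flatten per-term series into one plot-ready table (one row per term-year)."""
    rows = [
        {"term": term, **vars(p)}
        for term, points in points_by_term.items()
        for p in points
    ]
    return pd.DataFrame(rows)
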