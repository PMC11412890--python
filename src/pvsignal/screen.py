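"""Per-algorithm signal criteria, BCPNN strength tiers and overlap summaries.

Default thresholds follow common pharmacovigilance practice:

* ROR:   a ≥ 3 and lower 95% bound of ROR > 1
* PRR:   a ≥ 3 and lower 95% bound of PRR > 1
* MHRA:  PRR > 2 and χ² > 4 and a > 3
* BCPNN: IC − 2SD > 0, with strength tiers −/+/++/+++ at 0 / 1.5 / 3
* MGPS:  EB05 > 2

Note the deliberate asymmetry between the ROR/PRR count gate (a ≥ 3) and
the MHRA gate (a > 3): both are kept verbatim as distinct defaults.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .dispro import DisproResult

__all__ = [
    "ALGORITHMS",
    "SignalCriteria",
    "SignalDecision",
    "OverlapSummary",
    "evaluate_signals",
    "tier_bcpnn",
    "flag_ime",
    "overlap_summary",
]

ALGORITHMS = ("ROR", "PRR", "MHRA", "BCPNN", "MGPS")


@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds for the five positivity rules (strict inequalities)."""

    ror_min_count: int = 3  # a >= this
    ror_lo_gt: float = 1.0
    prr_min_count: int = 3  # a >= this
    prr_lo_gt: float = 1.0
    mhra_prr_gt: float = 2.0
    mhra_chi2_gt: float = 4.0
    mhra_count_gt: int = 3  # a > this
    ic025_gt: float = 0.0
    eb05_gt: float = 2.0

    def __post_init__(self) -> None:
        if self.ror_min_count < 0 or self.prr_min_count < 0 or self.mhra_count_gt < 0:
            raise ValueError("count thresholds must be non-negative")
        for v in (self.ror_lo_gt, self.prr_lo_gt, self.mhra_prr_gt, self.mhra_chi2_gt, self.eb05_gt):
            if not (v == v):  # NaN guard
                raise ValueError("malformed threshold (NaN)")


@dataclass(frozen=True)
class SignalDecision:
    term: str
    a: int
    positive_ror: bool
    positive_prr: bool
    positive_mhra: bool
    positive_bcpnn: bool
    positive_mgps: bool
    bcpnn_tier: str
    ime: bool

    @property
    def n_positive_algorithms(self) -> int:
        return sum(
            (self.positive_ror, self.positive_prr, self.positive_mhra,
             self.positive_bcpnn, self.positive_mgps)
        )

    @property
    def positives(self) -> frozenset[str]:
        flags = (self.positive_ror, self.positive_prr, self.positive_mhra,
                 self.positive_bcpnn, self.positive_mgps)
        return frozenset(alg for alg, f in zip(ALGORITHMS, flags) if f)


def tier_bcpnn(ic025: float) -> str:
    """BCPNN strength tier from the IC − 2SD bound (upper bounds inclusive)."""
    if ic025 <= 0.0:
        return "-"
    if ic025 <= 1.5:
        return "+"
    if ic025 <= 3.0:
        return "++"
    return "+++"


def flag_ime(term: str, ime_list: frozenset[str] | set[str]) -> bool:
    """Case-insensitive exact membership of a PT in the IME list.

    The list is expected casefolded (as :func:`pvsignal.faers_io.load_ime_list`
    returns it); an empty list flags nothing.
    """
    if not ime_list:
        return False
    return term.strip().casefold() in ime_list


def evaluate_signals(
    results: Mapping[str, DisproResult] | Iterable[DisproResult],
    ime_list: frozenset[str] | set[str] | None = None,
    criteria: SignalCriteria = SignalCriteria(),
) -> list[SignalDecision]:
    """Apply all five positivity rules to each term's statistics.

    Undefined-flagged statistics evaluate as negative for their rule.
    Terms with a = 0 are excluded entirely (they would only inflate the
    negative rows).  An empty or missing IME list flags every term False.
    """
    if isinstance(results, Mapping):
        results = results.values()
    ime_list = ime_list or frozenset()
    out: list[SignalDecision] = []
    for r in sorted(results, key=lambda r: r.term):
        a = r.table.a
        if a == 0:
            continue
        ror, prr, chi2 = r.freq.ror, r.freq.prr, r.freq.chi2
        pos_ror = bool(ror.defined and a >= criteria.ror_min_count and ror.lo > criteria.ror_lo_gt)
        pos_prr = bool(prr.defined and a >= criteria.prr_min_count and prr.lo > criteria.prr_lo_gt)
        pos_mhra = bool(
            prr.defined and chi2.defined
            and prr.value > criteria.mhra_prr_gt
            and chi2.chi2 > criteria.mhra_chi2_gt
            and a > criteria.mhra_count_gt
        )
        pos_bcpnn = bool(r.bcpnn.ic025 > criteria.ic025_gt)
        tier = tier_bcpnn(r.bcpnn.ic025) if pos_bcpnn else "-"
        pos_mgps = bool(r.mgps is not None and r.mgps.eb05 > criteria.eb05_gt)
        out.append(
            SignalDecision(
                term=r.term,
                a=a,
                positive_ror=pos_ror,
                positive_prr=pos_prr,
                positive_mhra=pos_mhra,
                positive_bcpnn=pos_bcpnn,
                positive_mgps=pos_mgps,
                bcpnn_tier=tier,
                ime=flag_ime(r.term, ime_list),
            )
        )
    return out


@dataclass
class OverlapSummary:
    """Counts for UpSet/Venn-style multi-algorithm comparison."""

    per_algorithm: dict[str, int]
    patterns: dict[frozenset[str], int]  # non-empty membership pattern -> count
    n_union: int
    n_all_five: int
    ime_by_detected: dict[tuple[bool, bool], int]  # (detected by >=1, ime) -> count
    all_five_ime_split: dict[bool, int]  # ime flag -> count among all-five positives

    def validate(self) -> None:
        if sum(self.patterns.values()) != self.n_union:
            raise ValueError("pattern counts do not sum to the union of positives")


def overlap_summary(decisions: Iterable[SignalDecision]) -> OverlapSummary:
    """Exact counts of every non-empty algorithm-membership pattern.

    The patterns partition the union of positives, so their counts sum to
    its size; the all-five intersection is additionally split by IME flag.
    """
    decisions = list(decisions)
    per_alg = {alg: 0 for alg in ALGORITHMS}
    patterns: Counter = Counter()
    ime_by_detected: Counter = Counter()
    all_five_ime: Counter = Counter({True: 0, False: 0})
    n_union = 0
    for d in decisions:
        pos = d.positives
        for alg in pos:
            per_alg[alg] += 1
        detected = bool(pos)
        ime_by_detected[(detected, d.ime)] += 1
        if detected:
            n_union += 1
            patterns[pos] += 1
        if len(pos) == len(ALGORITHMS):
            all_five_ime[d.ime] += 1
    summary = OverlapSummary(
        per_algorithm=per_alg,
        patterns=dict(patterns),
        n_union=n_union,
        n_all_five=sum(all_five_ime.values()),
        ime_by_detected=dict(ime_by_detected),
        all_five_ime_split=dict(all_five_ime),
    )
    summary.validate()
    return summary
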