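"""Signal criteria, BCPNN tiers, IME flags and overlap summaries."""

import itertools
import math
from dataclasses import replace

import pytest

from pvsignal.contingency import ContingencyTable
from pvsignal.dispro import (
    BcpnnResult,
    Chi2Stat,
    DisproResult,
    FrequentistResult,
    IntervalEstimate,
    MgpsResult,
)
from pvsignal.screen import (
    ALGORITHMS,
    SignalCriteria,
    SignalDecision,
    evaluate_signals,
    flag_ime,
    overlap_summary,
    tier_bcpnn,
)


def make_result(
    term="PT_X", a=10, ror=2.0, ror_lo=1.5, prr=2.0, prr_lo=1.5,
    chi2=10.0, ic025=0.5, eb05=2.5,
):
    t = ContingencyTable(a, 100, 100, 10_000)
    iv = lambda v, lo: IntervalEstimate(v, lo, v * v / lo if lo > 0 else math.inf)
    return DisproResult(
        term=term,
        table=t,
        freq=FrequentistResult(
            ror=iv(ror, ror_lo), prr=iv(prr, prr_lo),
            chi2=Chi2Stat(chi2, 0.01, yates=True),
        ),
        bcpnn=BcpnnResult(
            ic=ic025 + 0.5, ic_sd=0.25, ic025=ic025, ic975=ic025 + 1.0,
            ic_lo95=ic025 + 0.01, ic_hi95=ic025 + 0.99,
        ),
        mgps=MgpsResult(expected=1.0, ebgm=eb05 + 1, eb05=eb05, eb95=eb05 + 2, qn=0.5),
    )


class TestCriteria:
    def test_ror_positive_needs_count_and_lower_bound(self):
        (d,) = evaluate_signals([make_result(a=5, ror_lo=1.2)])
        assert d.positive_ror
        (d,) = evaluate_signals([make_result(a=2, ror=50.0, ror_lo=5.0)])
        assert not d.positive_ror  # count gate

    def test_mhra_count_gate_is_strict(self):
        base = dict(prr=2.5, chi2=5.0)
        (d4,) = evaluate_signals([make_result(a=4, **base)])
        (d3,) = evaluate_signals([make_result(a=3, **base)])
        assert d4.positive_mhra and not d3.positive_mhra

    def test_mhra_positive_implies_prr_above_two(self):
        for prr, chi2, a in itertools.product((1.5, 2.0, 2.5), (3.0, 5.0), (3, 4, 10)):
            (d,) = evaluate_signals([make_result(a=a, prr=prr, chi2=chi2)])
            if d.positive_mhra:
                assert prr > 2.0

    def test_bcpnn_and_mgps_rules(self):
        (d,) = evaluate_signals([make_result(ic025=0.0, eb05=2.0)])
        assert not d.positive_bcpnn and not d.positive_mgps
        (d,) = evaluate_signals([make_result(ic025=0.01, eb05=2.01)])
        assert d.positive_bcpnn and d.positive_mgps

    def test_zero_count_terms_excluded(self):
        assert evaluate_signals([make_result(a=0)]) == []

    def test_undefined_statistics_evaluate_negative(self):
        r = make_result()
        r = replace(r, freq=FrequentistResult(
            ror=IntervalEstimate.undefined(),
            prr=IntervalEstimate.undefined(),
            chi2=Chi2Stat(math.nan, math.nan, True, defined=False),
        ), mgps=None)
        (d,) = evaluate_signals([r])
        assert not (d.positive_ror or d.positive_prr or d.positive_mhra or d.positive_mgps)

    def test_threshold_monotonicity(self):
        """Raising any threshold never increases the positive count."""
        results = [
            make_result(term=f"PT_{i}", a=3 + i, ror_lo=0.5 + 0.3 * i,
                        prr_lo=0.5 + 0.3 * i, prr=1 + 0.5 * i, chi2=i, ic025=-1 + 0.4 * i,
                        eb05=0.5 * i)
            for i in range(10)
        ]
        base = SignalCriteria()
        counts = lambda crit: [
            sum(d.positive_ror for d in evaluate_signals(results, criteria=crit)),
            sum(d.positive_prr for d in evaluate_signals(results, criteria=crit)),
            sum(d.positive_mhra for d in evaluate_signals(results, criteria=crit)),
            sum(d.positive_bcpnn for d in evaluate_signals(results, criteria=crit)),
            sum(d.positive_mgps for d in evaluate_signals(results, criteria=crit)),
        ]
        lo = counts(base)
        hi = counts(SignalCriteria(ror_lo_gt=2.0, prr_lo_gt=2.0, mhra_prr_gt=3.0,
                                   mhra_chi2_gt=8.0, ic025_gt=1.0, eb05_gt=4.0))
        assert all(h <= l for h, l in zip(hi, lo))

    def test_malformed_thresholds_rejected(self):
        with pytest.raises(ValueError):
            SignalCriteria(eb05_gt=math.nan)


class TestTier:
    @pytest.mark.parametrize(
        "ic025, tier",
        [(-1.0, "-"), (0.0, "-"), (1e-9, "+"), (1.5, "+"), (1.51, "++"),
         (3.0, "++"), (3.01, "+++"), (10.0, "+++")],
    )
    def test_boundaries(self, ic025, tier):
        assert tier_bcpnn(ic025) == tier

    def test_tier_consistent_with_positivity(self):
        decisions = evaluate_signals(
            [make_result(term=f"T{i}", ic025=v) for i, v in enumerate((-0.5, 0.0, 0.7, 2.0, 4.0))]
        )
        for d in decisions:
            assert d.positive_bcpnn == (d.bcpnn_tier != "-")


class TestIme:
    def test_membership_and_case(self):
        ime = frozenset({"epistaxis", "haemorrhagic arteriovenous malformation"})
        assert flag_ime("Haemorrhagic arteriovenous malformation", ime)
        assert flag_ime("EPISTAXIS", ime)
        assert not flag_ime("Coagulation factor X level increased", ime)

    def test_empty_list_flags_nothing(self):
        assert not flag_ime("Epistaxis", frozenset())


def make_decision(term, positives, ime=False):
    flags = {f"positive_{alg.lower()}": alg in positives for alg in ALGORITHMS}
    return SignalDecision(term=term, a=5, bcpnn_tier="+", ime=ime, **flags)


class TestOverlap:
    def test_direct_pattern_count(self):
        decisions = [make_decision(f"T{i}", {"ROR", "PRR"}) for i in range(3)]
        s = overlap_summary(decisions)
        assert s.patterns[frozenset({"ROR", "PRR"})] == 3
        assert s.per_algorithm == {"ROR": 3, "PRR": 3, "MHRA": 0, "BCPNN": 0, "MGPS": 0}

    def test_matches_enumeration_and_partition_identity(self, rng):
        decisions = []
        for i in range(200):
            members = {alg for alg in ALGORITHMS if rng.random() < 0.4}
            decisions.append(make_decision(f"T{i}", members, ime=bool(rng.random() < 0.3)))
        s = overlap_summary(decisions)
        # brute-force enumeration over all 2^5−1 patterns
        for pattern in map(frozenset, itertools.chain.from_iterable(
            itertools.combinations(ALGORITHMS, k) for k in range(1, 6)
        )):
            expected = sum(1 for d in decisions if d.positives == pattern)
            assert s.patterns.get(pattern, 0) == expected
        assert sum(s.patterns.values()) == s.n_union
        assert s.n_all_five == sum(s.all_five_ime_split.values())

    def test_order_invariance(self, rng):
        decisions = [
            make_decision(f"T{i}", {alg for alg in ALGORITHMS if rng.random() < 0.5})
            for i in range(50)
        ]
        s1 = overlap_summary(decisions)
        s2 = overlap_summary(list(reversed(decisions)))
        assert s1.patterns == s2.patterns and s1.per_algorithm == s2.per_algorithm

    def test_n_positive_algorithms_counts_flags(self):
        d = make_decision("T", {"ROR", "BCPNN", "MGPS"})
        assert d.n_positive_algorithms == 3
        assert d.positives == frozenset({"ROR", "BCPNN", "MGPS"})
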