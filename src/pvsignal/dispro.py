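"""The five disproportionality statistics.

For a 2×2 table (a, b, c, d) with n = a+b+c+d:

* **ROR** — reporting odds ratio ad/bc with a Wald interval on the log
  scale, se = sqrt(1/a + 1/b + 1/c + 1/d).
* **PRR** — proportional reporting ratio [a/(a+b)] / [c/(c+d)], interval
  on the log scale with se = sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)).
* **MHRA χ²** — the Pearson chi-square with optional Yates continuity
  correction, used in the composite MHRA rule (PRR > 2, χ² > 4, a > 3).
* **BCPNN IC** — the information component log2[P(drug, event) /
  (P(drug)P(event))] under independent Beta posteriors for the three
  probabilities; closed-form posterior moments with the conventional
  hyperparameters α1 = β1 = γ11 = 1, α = β = 2 and γ chosen so the prior
  IC expectation is zero.
* **MGPS EBGM** — DuMouchel's empirical-Bayes geometric mean of the
  relative reporting rate λ = a/E under a two-component gamma mixture
  prior fitted across all (a, E) cells by marginal maximum likelihood.

Zero cells: the frequentist statistics optionally apply the Haldane 0.5
continuity correction; the Bayesian statistics need none.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import optimize, special, stats

from .contingency import ContingencyTable

logger = logging.getLogger(__name__)

__all__ = [
    "IntervalEstimate",
    "Chi2Stat",
    "FrequentistResult",
    "BcpnnHyper",
    "BcpnnResult",
    "MgpsPrior",
    "MgpsResult",
    "DisproResult",
    "MgpsFitError",
    "compute_ror",
    "compute_prr",
    "compute_chi2",
    "frequentist_stats",
    "compute_bcpnn",
    "fit_mgps_prior",
    "compute_ebgm",
    "prr_implied_by_ror",
    "compute_all",
    "DUMOUCHEL_START",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile
LN2 = math.log(2.0)


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with two-sided 95% bounds.

    ``defined`` is False when the statistic could not be computed (zero
    cells without correction); the numeric fields are then NaN.
    """

    value: float
    lo: float
    hi: float
    defined: bool = True
    corrected: bool = False

    @classmethod
    def undefined(cls) -> "IntervalEstimate":
        return cls(math.nan, math.nan, math.nan, defined=False)


@dataclass(frozen=True)
class Chi2Stat:
    chi2: float
    p: float
    yates: bool
    defined: bool = True


@dataclass(frozen=True)
class FrequentistResult:
    ror: IntervalEstimate
    prr: IntervalEstimate
    chi2: Chi2Stat


def _haldane(t: ContingencyTable) -> tuple[float, float, float, float, bool]:
    a, b, c, d = t.as_tuple()
    if min(a, b, c, d) == 0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5, True
    return float(a), float(b), float(c), float(d), False


def compute_ror(t: ContingencyTable, zero_correction: bool = True) -> IntervalEstimate:
    """Reporting odds ratio ad/bc with a 95% Wald interval on the log scale.

    With a zero cell and ``zero_correction`` on, 0.5 is added to all four
    cells (Haldane); with correction off a zero cell yields an
    undefined-flagged result rather than an exception.
    """
    if zero_correction:
        a, b, c, d, corrected = _haldane(t)
    else:
        a, b, c, d, corrected = (*map(float, t.as_tuple()), False)
        if min(a, b, c, d) == 0.0:
            return IntervalEstimate.undefined()
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return IntervalEstimate(
        value=ror,
        lo=math.exp(math.log(ror) - Z95 * se),
        hi=math.exp(math.log(ror) + Z95 * se),
        corrected=corrected,
    )


def compute_prr(t: ContingencyTable, zero_correction: bool = True) -> IntervalEstimate:
    """Proportional reporting ratio with a 95% Wald interval on the log scale."""
    if zero_correction:
        a, b, c, d, corrected = _haldane(t)
    else:
        a, b, c, d, corrected = (*map(float, t.as_tuple()), False)
        if a == 0 or c == 0 or a + b == 0 or c + d == 0:
            return IntervalEstimate.undefined()
    prr = (a / (a + b)) / (c / (c + d))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(var, 0.0))
    return IntervalEstimate(
        value=prr,
        lo=math.exp(math.log(prr) - Z95 * se),
        hi=math.exp(math.log(prr) + Z95 * se),
        corrected=corrected,
    )


def compute_chi2(t: ContingencyTable, yates: bool = True) -> Chi2Stat:
    """MHRA chi-square: n(|ad−bc| − [n/2])² / ((a+b)(c+d)(a+c)(b+d)).

    The Yates continuity term n/2 (default on, the MHRA convention) is
    floored so over-correction can never produce a negative statistic.
    A zero margin yields an undefined-flagged result.
    """
    a, b, c, d = map(float, t.as_tuple())
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0 or n == 0:
        return Chi2Stat(math.nan, math.nan, yates, defined=False)
    dev = abs(a * d - b * c)
    if yates:
        dev = max(dev - n / 2.0, 0.0)
    chi2 = n * dev * dev / margins
    return Chi2Stat(chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)), yates=yates)


def frequentist_stats(
    t: ContingencyTable, zero_correction: bool = True, yates: bool = True
) -> FrequentistResult:
    return FrequentistResult(
        ror=compute_ror(t, zero_correction),
        prr=compute_prr(t, zero_correction),
        chi2=compute_chi2(t, yates),
    )


# --------------------------------------------------------------------------
# BCPNN


@dataclass(frozen=True)
class BcpnnHyper:
    """Beta hyperparameters of the BCPNN model (conventional defaults)."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0


@dataclass(frozen=True)
class BcpnnResult:
    ic: float  # posterior expectation E(IC), bits
    ic_sd: float  # sqrt(V(IC)), bits
    ic025: float  # ic − 2·sd, the screening bound
    ic975: float  # ic + 2·sd
    ic_lo95: float  # ic − 1.96·sd (printed-CI convention)
    ic_hi95: float
    hyper: BcpnnHyper = BcpnnHyper()
    moments: str = "approx"


def compute_bcpnn(
    t: ContingencyTable,
    hyper: BcpnnHyper = BcpnnHyper(),
    moments: Literal["approx", "exact"] = "approx",
) -> BcpnnResult:
    """Posterior moments of the information component.

    The joint cell probability p11, the drug marginal p1 and the event
    marginal p2 carry independent Beta posteriors::

        p11 ~ Beta(a + γ11, n − a + γ − γ11)
        p1  ~ Beta(a + b + α1, n − a − b + α − α1)
        p2  ~ Beta(a + c + β1, n − a − c + β − β1)

    with γ = γ11(n+α)(n+β) / ((a+b+α1)(a+c+β1)) so that the prior IC
    expectation is exactly zero.

    ``moments="approx"`` (default) uses the conventional closed forms —
    E(IC) as the log2 ratio of posterior means and the matching first-order
    variance — which are what published IC / IC−2SD screening values follow;
    on the all-zero table this gives IC = 0 exactly.  ``moments="exact"``
    evaluates E(IC) and V(IC) exactly via digamma/trigamma functions of the
    same posteriors (the two agree as counts grow).
    """
    a = float(t.a)
    n = float(t.n)
    ab = float(t.a + t.b)
    ac = float(t.a + t.c)
    h = hyper
    gamma = h.gamma11 * (n + h.alpha) * (n + h.beta) / ((ab + h.alpha1) * (ac + h.beta1))
    if moments == "approx":
        ic = math.log2(
            (a + h.gamma11) * (n + h.alpha) * (n + h.beta)
            / ((n + gamma) * (ab + h.alpha1) * (ac + h.beta1))
        )
        var = (
            (n - a + gamma - h.gamma11) / ((a + h.gamma11) * (1 + n + gamma))
            + (n - ab + h.alpha - h.alpha1) / ((ab + h.alpha1) * (1 + n + h.alpha))
            + (n - ac + h.beta - h.beta1) / ((ac + h.beta1) * (1 + n + h.beta))
        ) / LN2**2
    elif moments == "exact":
        psi, psi1 = special.digamma, special.polygamma
        ic = (
            psi(a + h.gamma11) - psi(n + gamma)
            - psi(ab + h.alpha1) + psi(n + h.alpha)
            - psi(ac + h.beta1) + psi(n + h.beta)
        ) / LN2
        var = (
            psi1(1, a + h.gamma11) - psi1(1, n + gamma)
            + psi1(1, ab + h.alpha1) - psi1(1, n + h.alpha)
            + psi1(1, ac + h.beta1) - psi1(1, n + h.beta)
        ) / LN2**2
        ic, var = float(ic), float(var)
    else:
        raise ValueError(f"unknown moments mode {moments!r}")
    sd = math.sqrt(max(var, 0.0))
    return BcpnnResult(
        ic=ic,
        ic_sd=sd,
        ic025=ic - 2.0 * sd,
        ic975=ic + 2.0 * sd,
        ic_lo95=ic - Z95 * sd,
        ic_hi95=ic + Z95 * sd,
        hyper=hyper,
        moments=moments,
    )


def sample_bcpnn_posterior(
    t: ContingencyTable,
    hyper: BcpnnHyper = BcpnnHyper(),
    n_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw IC values from the independent-Beta posterior (testing oracle)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    a = float(t.a)
    n = float(t.n)
    ab = float(t.a + t.b)
    ac = float(t.a + t.c)
    h = hyper
    gamma = h.gamma11 * (n + h.alpha) * (n + h.beta) / ((ab + h.alpha1) * (ac + h.beta1))
    p11 = rng.beta(a + h.gamma11, n - a + gamma - h.gamma11, size=n_draws)
    p1 = rng.beta(ab + h.alpha1, n - ab + h.alpha - h.alpha1, size=n_draws)
    p2 = rng.beta(ac + h.beta1, n - ac + h.beta - h.beta1, size=n_draws)
    return np.log2(p11 / (p1 * p2))


# --------------------------------------------------------------------------
# MGPS


class MgpsFitError(RuntimeError):
    """Prior fitting failed to converge; carries the best parameters found."""

    def __init__(self, message: str, best: "MgpsPrior"):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior for the relative reporting rate.

    λ ~ w·Gamma(alpha1, rate beta1) + (1−w)·Gamma(alpha2, rate beta2).
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    loglik: float = math.nan
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shape/rate parameters must be positive")
        if not (0.0 < self.w < 1.0):
            raise ValueError("mixture weight must lie in (0, 1)")


@dataclass(frozen=True)
class MgpsResult:
    expected: float  # E = (a+b)(a+c)/n
    ebgm: float
    eb05: float
    eb95: float
    qn: float  # posterior weight on the first mixture component


DUMOUCHEL_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)

_EXTRA_STARTS = (
    (1.0, 1.0, 1.0, 1.0, 0.5),
    (0.5, 0.5, 3.0, 3.0, 0.2),
    (0.1, 0.05, 5.0, 5.0, 0.5),
    (2.0, 2.0, 0.2, 0.2, 0.5),
    (1.0, 0.2, 2.0, 8.0, 0.4),
)


def _log_nb(a: np.ndarray, e: np.ndarray, shape: float, rate: float) -> np.ndarray:
    """log of the marginal negative-binomial pmf of a | E under Gamma(shape, rate)."""
    # NB(a; r=shape, p=rate/(rate+E))
    log_p = math.log(rate) - np.log(rate + e)
    log_q = np.log(e) - np.log(rate + e)
    return (
        special.gammaln(shape + a)
        - special.gammaln(shape)
        - special.gammaln(a + 1.0)
        + shape * log_p
        + a * log_q
    )


def _mixture_loglik(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    a1, b1, a2, b2 = np.exp(theta[:4])
    # clamp the weight away from 0/1: the optimizer may wander to the boundary
    w = float(np.clip(special.expit(theta[4]), 1e-15, 1.0 - 1e-15))
    l1 = math.log(w) + _log_nb(a, e, a1, b1)
    l2 = math.log1p(-w) + _log_nb(a, e, a2, b2)
    return float(np.sum(np.logaddexp(l1, l2)))


def fit_mgps_prior(
    a: Sequence[float] | np.ndarray,
    e: Sequence[float] | np.ndarray,
    starts: Sequence[tuple[float, float, float, float, float]] | None = None,
    gtol: float = 1e-6,
    maxiter: int = 500,
) -> MgpsPrior:
    """Fit the gamma-mixture prior by marginal maximum likelihood.

    Maximises Σ log[w·NB(a; α1, β1/(β1+E)) + (1−w)·NB(a; α2, β2/(β2+E))]
    over (α1, β1, α2, β2, w) with an unconstrained log/logit
    reparameterisation, L-BFGS-B, and multiple starting points (DuMouchel's
    canonical start first).  Components are returned ordered by ascending
    shape α so fits are comparable across runs.

    Raises :class:`MgpsFitError` (carrying the best parameters found) if no
    start converges.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if a.shape != e.shape or a.ndim != 1:
        raise ValueError("a and E must be 1-D arrays of equal length")
    if len(a) < 50:
        raise ValueError(f"need at least 50 cells to fit the prior, got {len(a)}")
    if np.any(e <= 0):
        raise ValueError("all expected counts E must be positive")

    if starts is None:
        starts = (DUMOUCHEL_START,) + _EXTRA_STARTS

    def objective(th: np.ndarray) -> float:
        ll = _mixture_loglik(th, a, e)
        return -ll if np.isfinite(ll) else 1e300

    # box constraints on the log/logit scale keep exp() finite
    bounds = [(-20.0, 20.0)] * 4 + [(-30.0, 30.0)]
    best: optimize.OptimizeResult | None = None
    any_converged = False
    total_iter = 0
    for s in starts:
        theta0 = np.array([*np.log(s[:4]), special.logit(s[4])])
        res = optimize.minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"gtol": gtol, "maxiter": maxiter},
        )
        total_iter += res.nit
        any_converged = any_converged or res.success
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    a1, b1, a2, b2 = np.exp(best.x[:4])
    w = float(special.expit(best.x[4]))
    if a2 < a1:  # canonical component order: ascending shape
        a1, b1, a2, b2, w = a2, b2, a1, b1, 1.0 - w
    w = min(max(w, 1e-12), 1 - 1e-12)
    prior = MgpsPrior(
        alpha1=float(a1), beta1=float(b1), alpha2=float(a2), beta2=float(b2),
        w=w, loglik=-float(best.fun), n_iter=total_iter,
        converged=any_converged,
    )
    if not any_converged:
        raise MgpsFitError("MGPS prior fit did not converge from any start", prior)
    return prior


def _posterior_mixture(a: float, e: float, prior: MgpsPrior) -> tuple[float, float, float, float, float]:
    """Posterior (Qn, shape1, rate1, shape2, rate2) of λ given a, E."""
    arr_a = np.array([a])
    arr_e = np.array([e])
    l1 = math.log(prior.w) + float(_log_nb(arr_a, arr_e, prior.alpha1, prior.beta1)[0])
    l2 = math.log1p(-prior.w) + float(_log_nb(arr_a, arr_e, prior.alpha2, prior.beta2)[0])
    qn = float(np.exp(l1 - np.logaddexp(l1, l2)))
    return qn, prior.alpha1 + a, prior.beta1 + e, prior.alpha2 + a, prior.beta2 + e


def _posterior_cdf(lam, qn, s1, r1, s2, r2):
    return qn * stats.gamma.cdf(lam, s1, scale=1.0 / r1) + (1.0 - qn) * stats.gamma.cdf(
        lam, s2, scale=1.0 / r2
    )


def _posterior_quantile(q: float, qn, s1, r1, s2, r2, xtol: float = 1e-6) -> float:
    q1 = stats.gamma.ppf(q, s1, scale=1.0 / r1)
    q2 = stats.gamma.ppf(q, s2, scale=1.0 / r2)
    if abs(q1 - q2) < xtol:  # components coincide at this quantile
        return 0.5 * (q1 + q2)
    # the mixture quantile lies between the component quantiles; pad the
    # bracket so both endpoints have strictly opposite signs
    lo, hi = 0.99 * min(q1, q2), 1.01 * max(q1, q2) + xtol
    f = lambda x: _posterior_cdf(x, qn, s1, r1, s2, r2) - q
    while f(lo) > 0.0:
        lo *= 0.5
    while f(hi) < 0.0:
        hi *= 2.0
    return float(optimize.bisect(f, lo, hi, xtol=xtol))


def compute_ebgm(t: ContingencyTable, prior: MgpsPrior) -> MgpsResult:
    """Empirical-Bayes geometric mean and 90% posterior interval (EB05, EB95).

    Posterior of λ is the gamma mixture Qn·Ga(α1+a, β1+E) +
    (1−Qn)·Ga(α2+a, β2+E); EBGM = 2^{E[log2 λ]} via digamma, and the
    quantiles are found by bisection on the mixture CDF to 1e-6 in λ.
    """
    e = t.expected
    a = float(t.a)
    qn, s1, r1, s2, r2 = _posterior_mixture(a, e, prior)
    eblog2 = (
        qn * (special.digamma(s1) - math.log(r1))
        + (1.0 - qn) * (special.digamma(s2) - math.log(r2))
    ) / LN2
    return MgpsResult(
        expected=e,
        ebgm=float(2.0 ** eblog2),
        eb05=_posterior_quantile(0.05, qn, s1, r1, s2, r2),
        eb95=_posterior_quantile(0.95, qn, s1, r1, s2, r2),
        qn=qn,
    )


# --------------------------------------------------------------------------
# Published-table algebra


def prr_implied_by_ror(a: float, m: float, ror: float) -> float:
    """PRR implied by (a, M = a+b, ROR), independent of the background split.

    From PRR = [a/M] / [c/(c+d)] and ROR = ad/(bc) one obtains
    PRR = (a/M)(1 + ROR·(M−a)/a), which lets published ROR/PRR pairs be
    checked for internal consistency without the full database.
    """
    if a <= 0 or a > m or ror <= 0:
        raise ValueError("need 0 < a <= M and ror > 0")
    return (a / m) * (1.0 + ror * (m - a) / a)


# --------------------------------------------------------------------------
# Per-term bundle


@dataclass(frozen=True)
class DisproResult:
    """All five statistics for one (drug, term) pair."""

    term: str
    table: ContingencyTable
    freq: FrequentistResult
    bcpnn: BcpnnResult
    mgps: MgpsResult | None


def compute_all(
    counts,
    prior: MgpsPrior | None = None,
    zero_correction: bool = True,
    yates: bool = True,
    hyper: BcpnnHyper = BcpnnHyper(),
    min_count: int = 1,
) -> dict[str, DisproResult]:
    """Compute every statistic for every term with a ≥ ``min_count``.

    ``counts`` is a :class:`~pvsignal.contingency.CombinationCounts`.  When
    ``prior`` is None and enough cells are available it is fitted here
    across all terms with a ≥ 1 (the standard MGPS workflow).
    """
    from .contingency import make_contingency  # local to avoid cycle at import

    terms = [t for t in counts.terms() if counts.n_target.get(t, 0) >= min_count]
    tables = {t: make_contingency(counts, t) for t in terms}
    if prior is None:
        cells = [(tab.a, tab.expected) for tab in tables.values() if tab.expected > 0]
        if len(cells) >= 50:
            arr = np.array(cells)
            prior = fit_mgps_prior(arr[:, 0], arr[:, 1])
        else:
            logger.warning(
                "only %d cells available (<50): MGPS skipped for this run", len(cells)
            )
    out: dict[str, DisproResult] = {}
    for term, tab in tables.items():
        out[term] = DisproResult(
            term=term,
            table=tab,
            freq=frequentist_stats(tab, zero_correction, yates),
            bcpnn=compute_bcpnn(tab, hyper),
            mgps=compute_ebgm(tab, prior) if prior is not None and tab.expected > 0 else None,
        )
    return out
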