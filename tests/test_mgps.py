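"""MGPS: prior fitting, posterior EBGM/EB05/EB95 and their quadrature oracle."""

import math

import numpy as np
import pytest
from scipy import special, stats

from pvsignal.contingency import ContingencyTable
from pvsignal.dispro import (
    MgpsPrior,
    _mixture_loglik,
    compute_ebgm,
    fit_mgps_prior,
)

TRUE_THETA = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def simulate_cells(rng, n, theta=TRUE_THETA, e_range=(0.1, 10.0)):
    a1, b1, a2, b2, w = theta
    e = rng.uniform(*e_range, n)
    comp = rng.random(n) < w
    lam = np.where(comp, rng.gamma(a1, 1 / b1, n), rng.gamma(a2, 1 / b2, n))
    return rng.poisson(lam * e).astype(float), e


def quadrature_quantiles(a, e, prior, qs=(0.05, 0.95), n_grid=400_000):
    """Independent oracle: trapezoid CDF of the posterior mixture on a λ grid."""
    s1, r1 = prior.alpha1 + a, prior.beta1 + e
    s2, r2 = prior.alpha2 + a, prior.beta2 + e
    f1 = stats.nbinom.pmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
    f2 = stats.nbinom.pmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
    qn = prior.w * f1 / (prior.w * f1 + (1 - prior.w) * f2)
    # integrate in u = log λ so densities with shape < 1 stay finite at the
    # lower end: pdf_u(u) = λ·pdf(λ)
    lo = min(stats.gamma.ppf(1e-9, s1, scale=1 / r1), stats.gamma.ppf(1e-9, s2, scale=1 / r2))
    hi = max(stats.gamma.ppf(1 - 1e-9, s1, scale=1 / r1), stats.gamma.ppf(1 - 1e-9, s2, scale=1 / r2))
    u = np.linspace(math.log(max(lo, 1e-300)), math.log(hi), n_grid)
    lam = np.exp(u)
    pdf_u = lam * (
        qn * stats.gamma.pdf(lam, s1, scale=1 / r1)
        + (1 - qn) * stats.gamma.pdf(lam, s2, scale=1 / r2)
    )
    cdf = np.concatenate([[0.0], np.cumsum((pdf_u[1:] + pdf_u[:-1]) / 2.0 * np.diff(u))])
    cdf /= cdf[-1]
    return [float(np.exp(np.interp(q, cdf, u))) for q in qs]


class TestPriorFit:
    def test_parameter_recovery(self, rng):
        a, e = simulate_cells(rng, 20_000)
        prior = fit_mgps_prior(a, e)
        assert prior.converged
        assert prior.w == pytest.approx(TRUE_THETA[4], abs=0.05)
        for fitted, true in zip(
            (prior.alpha1, prior.beta1, prior.alpha2, prior.beta2), TRUE_THETA[:4]
        ):
            assert fitted == pytest.approx(true, rel=0.25)

    def test_fit_beats_truth_likelihood(self, rng):
        a, e = simulate_cells(rng, 5_000)
        prior = fit_mgps_prior(a, e)
        theta_true = np.array([*np.log(TRUE_THETA[:4]), special.logit(TRUE_THETA[4])])
        assert prior.loglik >= _mixture_loglik(theta_true, a, e) - 1e-6

    def test_single_component_data_collapses_mixture(self, rng):
        """Data from one gamma: the fitted mixture marginal matches the
        single-component marginal (per-cell log-likelihood gap ~ 0)."""
        n = 5_000
        e = rng.uniform(0.1, 10.0, n)
        lam = rng.gamma(2.0, 1 / 4.0, n)
        a = rng.poisson(lam * e).astype(float)
        prior = fit_mgps_prior(a, e)
        single = np.sum(stats.nbinom.logpmf(a, 2.0, 4.0 / (4.0 + e)))
        assert prior.loglik >= single - 0.0005 * n
        # one component dominates or both coincide
        mean1 = prior.alpha1 / prior.beta1
        mean2 = prior.alpha2 / prior.beta2
        assert (
            min(prior.w, 1 - prior.w) < 0.05
            or abs(math.log(mean1 / mean2)) < 0.35
        )

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValueError, match="50"):
            fit_mgps_prior(np.ones(10), np.ones(10))

    def test_nonpositive_expected_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            fit_mgps_prior(np.ones(60), np.zeros(60))


WEAK_PRIOR = MgpsPrior(1.0, 0.1, 1.0, 0.1, 0.5)


class TestPosterior:
    def test_degenerate_prior_closed_form(self):
        """Single Ga(1,1) prior, a=0, E=1 → EBGM = exp(ψ(1))/2."""
        prior = MgpsPrior(1.0, 1.0, 1.0, 1.0, 0.5)
        # a=0 with E=(a+b)(a+c)/n = 1: b=2, c=2, d=2 gives E=(2·2)/6... pick cells
        # directly: a=0,b=1,c=6,d=0 -> E=(1·6)/7; instead use b=c so E=b²/(2b+d)
        t = ContingencyTable(0, 3, 3, 3)  # E = 9/9 = 1
        assert t.expected == pytest.approx(1.0)
        res = compute_ebgm(t, prior)
        assert res.ebgm == pytest.approx(math.exp(special.digamma(1.0)) / 2.0, rel=1e-9)
        assert res.eb05 <= res.ebgm <= res.eb95

    def test_large_count_limit(self):
        """a=1000, E=100 with a weak prior: EBGM within 2% of a/E = 10."""
        t = ContingencyTable(1000, 99_000, 0, 900_000)
        assert t.expected == pytest.approx(100.0)
        res = compute_ebgm(t, WEAK_PRIOR)
        assert res.ebgm == pytest.approx(1000 / 100.0, rel=0.02)
        assert res.eb05 <= res.ebgm <= res.eb95

    def test_quantiles_match_quadrature_oracle(self, rng):
        prior = MgpsPrior(0.7, 0.5, 2.5, 3.0, 0.4)
        for _ in range(20):
            a = int(rng.integers(0, 100))
            b = int(rng.integers(1, 3000))
            c = int(rng.integers(1, 3000))
            d = int(rng.integers(1000, 200_000))
            t = ContingencyTable(a, b, c, d)
            res = compute_ebgm(t, prior)
            q05, q95 = quadrature_quantiles(a, t.expected, prior)
            assert res.eb05 == pytest.approx(q05, abs=1e-4)
            assert res.eb95 == pytest.approx(q95, abs=1e-4)

    def test_shrinkage_toward_prior(self, rng):
        """|log EBGM| never exceeds |log((a+1)/E)| plus prior-mean slack."""
        prior = MgpsPrior(0.7, 0.5, 2.5, 3.0, 0.4)
        prior_mean = prior.w * prior.alpha1 / prior.beta1 + (1 - prior.w) * prior.alpha2 / prior.beta2
        slack = abs(math.log(prior_mean)) + 0.7
        for _ in range(50):
            a = int(rng.integers(1, 200))
            t = ContingencyTable(a, int(rng.integers(1, 2000)), int(rng.integers(1, 2000)),
                                 int(rng.integers(1000, 100_000)))
            res = compute_ebgm(t, prior)
            assert abs(math.log(res.ebgm)) <= abs(math.log((a + 1) / res.expected)) + slack

    def test_invariants_on_random_tables(self, rng):
        prior = MgpsPrior(0.2, 0.1, 2.0, 4.0, 1 / 3)
        for _ in range(30):
            t = ContingencyTable(
                int(rng.integers(0, 50)), int(rng.integers(1, 500)),
                int(rng.integers(1, 500)), int(rng.integers(100, 50_000)),
            )
            res = compute_ebgm(t, prior)
            assert res.eb05 <= res.ebgm <= res.eb95
            assert res.ebgm > 0
            assert 0.0 <= res.qn <= 1.0


class TestPriorValidation:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            MgpsPrior(0.0, 1.0, 1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            MgpsPrior(1.0, 1.0, 1.0, 1.0, 1.0)
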