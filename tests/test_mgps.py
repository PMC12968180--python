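import math

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from faerspv.signals import (
    ContingencyTable, MGPSHyperparams, fit_mgps_hyperparams, mgps,
    mgps_posterior, mgps_simplified,
)


def quadrature_oracle(a, e, h):
    """Posterior EBGM / EBGM05 by direct numerical integration.

    Builds the unnormalised posterior density Poisson(a; lambda E) times
    the gamma-mixture prior, normalises by quadrature, and integrates
    ln(lambda) for the geometric mean and the density for the percentile.
    Independent of the closed-form mixture-posterior route.
    """
    def prior(lam):
        return (h.p_mix * stats.gamma.pdf(lam, h.alpha1, scale=1 / h.beta1)
                + (1 - h.p_mix) * stats.gamma.pdf(lam, h.alpha2, scale=1 / h.beta2))

    def unnorm(lam):
        return stats.poisson.pmf(a, lam * e) * prior(lam)

    upper = (a + 50) / e + 50
    z, _ = integrate.quad(unnorm, 0, upper, limit=400)
    mean_log, _ = integrate.quad(lambda l: math.log(l) * unnorm(l) / z, 1e-12, upper,
                                 limit=400)

    def cdf(x):
        v, _ = integrate.quad(lambda l: unnorm(l) / z, 0, x, limit=400)
        return v

    q05 = optimize.brentq(lambda x: cdf(x) - 0.05, 1e-9, upper, xtol=1e-12)
    return math.exp(mean_log), q05


class TestSimplified:
    def test_hand_value(self):
        r = mgps_simplified(ContingencyTable(5, 10, 20, 400))
        assert r.ebgm == pytest.approx(5.8)

    @pytest.mark.parametrize("cells", [(5, 10, 20, 400), (3, 1, 1, 3), (50, 5, 5, 900)])
    def test_lower_bound_below_point(self, cells):
        r = mgps_simplified(ContingencyTable(*cells))
        assert r.ebgm05 < r.ebgm


class TestFullEB:
    CLASSIC = MGPSHyperparams()  # DuMouchel's classic theta

    @pytest.mark.parametrize("a,e", [(5, 1.0), (2, 0.4), (30, 6.0), (12, 30.0)])
    def test_matches_quadrature_oracle(self, a, e):
        got = mgps_posterior(a, e, self.CLASSIC)
        ebgm, q05 = quadrature_oracle(a, e, self.CLASSIC)
        assert got.ebgm == pytest.approx(ebgm, abs=1e-6)
        assert got.ebgm05 == pytest.approx(q05, abs=1e-6)
        assert got.ebgm05 < got.ebgm

    def test_shrinkage_bounds(self, rng):
        # elevated observed/expected: posterior sits between 1 and O/E
        for _ in range(50):
            a = int(rng.integers(3, 200))
            oe = float(rng.uniform(1.5, 12.0))
            e = a / oe
            r = mgps_posterior(a, e, self.CLASSIC)
            assert 1.0 <= r.ebgm <= oe + 1e-9, (a, e, r.ebgm)

    def test_ebgm_approaches_oe_for_large_counts(self):
        oe = 4.0
        gaps = [abs(mgps_posterior(a, a / oe, self.CLASSIC).ebgm - oe)
                for a in (10, 100, 2000)]
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.02

    def test_hyperparameter_fit_improves_on_truth(self, rng):
        # counts simulated from the classic prior mixture; the fitted theta
        # must achieve at least the truth's marginal likelihood
        h = self.CLASSIC
        n = 300
        expected = rng.uniform(0.3, 8.0, size=n)
        comp = rng.random(n) < h.p_mix
        lam = np.where(comp, rng.gamma(h.alpha1, 1 / h.beta1, size=n),
                       rng.gamma(h.alpha2, 1 / h.beta2, size=n))
        counts = rng.poisson(lam * expected)
        # feed (a, E) directly through the likelihood via stand-in rows
        from faerspv.signals import _neg_marginal_loglik
        from scipy import special
        theta_true = np.array([math.log(h.alpha1), math.log(h.beta1),
                               math.log(h.alpha2), math.log(h.beta2),
                               special.logit(h.p_mix)])
        ll_true = -_neg_marginal_loglik(theta_true, counts.astype(float), expected)

        class FakeTable:
            def __init__(self, a, e):
                self.a = a
                self.expected = e

        fitted, converged = fit_mgps_hyperparams(
            [FakeTable(float(a_i), float(e_i)) for a_i, e_i in zip(counts, expected)])
        theta_fit = np.array([math.log(fitted.alpha1), math.log(fitted.beta1),
                              math.log(fitted.alpha2), math.log(fitted.beta2),
                              special.logit(fitted.p_mix)])
        ll_fit = -_neg_marginal_loglik(theta_fit, counts.astype(float), expected)
        assert converged
        assert ll_fit >= ll_true - 1e-6

    def test_full_eb_requires_tables_for_estimation(self):
        with pytest.raises(ValueError):
            mgps(ContingencyTable(5, 10, 20, 400), mode="full_eb", hyper="estimate")

    def test_full_eb_with_fixed_hyper(self):
        r = mgps(ContingencyTable(5, 10, 20, 400), mode="full_eb", hyper=self.CLASSIC)
        assert r.mode == "full_eb" and r.ebgm05 < r.ebgm
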