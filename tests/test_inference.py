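"""Sufficient statistics, posterior, Phi/Gamma integrals and intervals."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from egocircles.continuum import g
from egocircles.data_io import CostScale
from egocircles.exceptions import (
    DegenerateScaleError,
    DomainError,
    ImproperPosteriorError,
    ValidationError,
)
from egocircles.inference import (
    NetworkSummary,
    confidence_interval,
    log_posterior,
    log_posterior_mu,
    mle_eta,
    phi,
    posterior_cdf,
    summarize,
)


def direct_cdf(u: float, s: NetworkSummary) -> float:
    """Oracle: normalize and integrate the posterior density directly."""
    mode = mle_eta(s)
    shift = float(log_posterior(mode, s))

    def f(e):
        return math.exp(float(log_posterior(e, s)) - shift)

    Z = quad(f, -np.inf, mode, limit=400)[0] + quad(f, mode, np.inf, limit=400)[0]
    if u <= mode:
        return quad(f, -np.inf, u, limit=400)[0] / Z
    return 1.0 - quad(f, u, np.inf, limit=400)[0] / Z


class TestSummarize:
    def test_arithmetic(self):
        s = summarize([10.0, 5.0, 1.0], CostScale(1.0, 10.0))
        assert s.L_tilde == 3
        assert s.L1_tilde == pytest.approx(14.0 / 9.0)
        assert s.t_bar == pytest.approx(14.0 / 27.0)

    def test_boundary_all_at_smax_flagged_improper(self):
        s = summarize([10.0, 10.0], CostScale(1.0, 10.0))
        assert s.t_bar == 0.0 and not s.proper

    def test_symmetric_costs_give_half(self):
        s = summarize([2.0, 8.0, 3.0, 7.0], CostScale(0.0, 10.0))
        assert s.t_bar == pytest.approx(0.5)

    def test_degenerate_scale_and_range_violations(self):
        with pytest.raises(DegenerateScaleError):
            summarize([5.0], (5.0, 5.0))
        with pytest.raises(ValidationError):
            summarize([0.5, 11.0], CostScale(1.0, 10.0))


class TestLogPosterior:
    def test_zero_at_origin(self):
        s = NetworkSummary(10, 4.0)
        assert log_posterior(0.0, s) == 0.0

    def test_mode_solves_implicit_equation(self):
        s = NetworkSummary(40, 0.73 * 40)
        eta_hat = mle_eta(s)
        assert g(eta_hat) == pytest.approx(s.t_bar, abs=1e-9)
        grid = np.linspace(eta_hat - 5, eta_hat + 5, 10001)
        vals = log_posterior(grid, s)
        assert abs(grid[np.argmax(vals)] - eta_hat) < 2e-3

    def test_symmetric_for_half_link(self):
        s = NetworkSummary(1, 0.5)
        etas = np.array([0.3, 1.7, 4.0])
        assert log_posterior(etas, s) == pytest.approx(log_posterior(-etas, s))


class TestMle:
    def test_half_gives_zero(self):
        assert mle_eta(NetworkSummary(10, 5.0)) == 0.0

    def test_round_trip(self):
        t = g(6.0)
        assert mle_eta(NetworkSummary(50, 50 * t)) == pytest.approx(6.0, abs=1e-6)

    @pytest.mark.parametrize("L1", [0.0, 7.0])
    def test_improper_summary_rejected(self, L1):
        with pytest.raises(ImproperPosteriorError):
            mle_eta(NetworkSummary(7, L1))


class TestPhi:
    def test_pure_exponential_closed_forms(self):
        assert phi(math.inf, 3.0, 0) == pytest.approx(1.0 / 3.0, rel=1e-12)
        assert phi(2.0, 1.0, 0) == pytest.approx(1.0 - math.exp(-2.0), rel=1e-10)

    def test_infinite_limit_matches_high_precision_quadrature(self):
        # independent oracle: 30-digit quadrature of the raw integrand
        import mpmath as mp

        mp.mp.dps = 30
        L, R = 10, 3.0
        oracle = float(mp.quad(
            lambda e: (e / (1 - mp.e**-e)) ** L * mp.e**(-R * e),
            [0, 5, 40, mp.inf],
        ))
        assert phi(math.inf, R, L) == pytest.approx(oracle, rel=1e-8)

    def test_divergent_rate_rejected(self):
        with pytest.raises(DomainError):
            phi(math.inf, 0.0, 5)

    def test_gauss_laguerre_variant_agrees(self):
        # the fixed 150-node rule is a coarser but independent evaluator
        from egocircles.inference import _log_phi_inf, _log_phi_inf_laguerre

        for R, L in [(3.0, 10), (11.0, 15), (24.0, 120)]:
            a = _log_phi_inf(R, L)
            b = _log_phi_inf_laguerre(R, L)
            assert b == pytest.approx(a, abs=5e-4)


class TestPosteriorCdf:
    @pytest.mark.parametrize("L,t_bar", [(15, 11 / 15), (50, 0.2), (5, 0.65)])
    def test_matches_direct_quadrature(self, L, t_bar):
        s = NetworkSummary(L, t_bar * L)
        mode = mle_eta(s)
        for u in np.linspace(mode - 4.0, mode + 4.0, 20):
            assert posterior_cdf(u, s) == pytest.approx(
                direct_cdf(u, s), abs=1e-6
            )

    def test_limits_and_branch_boundary(self):
        s = NetworkSummary(12, 8.0)
        assert posterior_cdf(60.0, s) == pytest.approx(1.0, abs=1e-9)
        assert posterior_cdf(-60.0, s) == pytest.approx(0.0, abs=1e-9)
        at_zero = phi(math.inf, s.L1_tilde, 12) / (
            phi(math.inf, s.L1_tilde, 12) + phi(math.inf, 12 - s.L1_tilde, 12)
        )
        assert posterior_cdf(0.0, s) == pytest.approx(at_zero, rel=1e-10)

    def test_monotone(self):
        s = NetworkSummary(20, 13.0)
        us = np.linspace(-6, 10, 40)
        vals = [posterior_cdf(u, s) for u in us]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_improper_rejected(self):
        with pytest.raises(ImproperPosteriorError):
            posterior_cdf(0.0, NetworkSummary(4, 4.0))


class TestConfidenceInterval:
    def test_tail_masses_hit_delta(self):
        s = NetworkSummary(30, 0.8 * 30)
        lo, hi = confidence_interval(s)
        assert posterior_cdf(lo, s) == pytest.approx(0.025, abs=1e-6)
        assert posterior_cdf(hi, s) == pytest.approx(0.975, abs=1e-6)
        assert lo < mle_eta(s) < hi

    def test_symmetric_summary_symmetric_interval(self):
        lo, hi = confidence_interval(NetworkSummary(10, 5.0))
        assert lo == pytest.approx(-hi, abs=1e-6)

    def test_matches_quantiles_of_direct_cdf(self):
        s = NetworkSummary(30, 0.8 * 30)
        lo, hi = confidence_interval(s)
        assert direct_cdf(lo, s) == pytest.approx(0.025, abs=1e-5)
        assert direct_cdf(hi, s) == pytest.approx(0.975, abs=1e-5)

    def test_interval_concentrates_with_network_size(self):
        w30 = np.diff(confidence_interval(NetworkSummary(30, 0.8 * 30)))[0]
        w120 = np.diff(confidence_interval(NetworkSummary(120, 0.8 * 120)))[0]
        assert w120 < w30


class TestDiscretePosterior:
    def test_mu_zero_limit(self):
        assert log_posterior_mu(0.0, 20, 10.0, 4) == pytest.approx(
            20 * math.log(0.25), rel=1e-12
        )

    def test_grid_argmax_matches_stationarity(self):
        # stationarity: d/dmu log P = 0 at the grid argmax
        L, L1, r = 20, 40.0, 4
        grid = np.linspace(-2, 3, 50001)
        vals = log_posterior_mu(grid, L, L1, r)
        mu_star = grid[np.argmax(vals)]
        h = 1e-5
        deriv = (log_posterior_mu(mu_star + h, L, L1, r)
                 - log_posterior_mu(mu_star - h, L, L1, r)) / (2 * h)
        assert abs(deriv) < L * 1e-2

    def test_large_r_mode_consistent_with_continuum(self):
        # argmax(mu) * (r - 1) approaches the continuum eta-hat
        r, L = 400, 60
        t_bar = 0.7
        L1 = t_bar * (r - 1) * L  # discrete moment ~ (r-1) * L1_tilde
        grid = np.linspace(0.0, 0.1, 200001)
        vals = log_posterior_mu(grid, L, L1, r)
        mu_star = grid[np.argmax(vals)]
        eta_cont = mle_eta(NetworkSummary(L, t_bar * L))
        assert mu_star * (r - 1) == pytest.approx(eta_cont, abs=0.05)
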