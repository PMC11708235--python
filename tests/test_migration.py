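"""Migration pipeline: outflux, reach and no-return probabilities,
lambda_mig, waiting time, and the mutation-migration partition."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_bvp

from patchadapt.migration import (
    NoCrossingError,
    SourceGeometry,
    boundary_layer_count,
    conditioned_hit_probability,
    critical_distance,
    lambda_mig,
    mutation_fraction,
    no_return_probability,
    outflux,
    rate_report,
    reach_probability,
    waiting_time,
)
from patchadapt.model import make_model
from patchadapt.mutation import MutationSpec, lambda_mut

from conftest import PARAM_SETS, R, RHO, model_for, profile_for

GEO = SourceGeometry(Rs=1.0, D=4.0)


class TestBoundaryLayer:
    def test_outflux_examples(self):
        # N = sigma2 rho / dx (d=1); n = 2 pi Rs rho dx (d=2);
        # N = 2 sigma2 pi Rs^2 rho / dx (d=3)
        m1 = make_model(d=1, sigma2=0.001, s1=0.05, s2=0.005, rho=216, R=1)
        assert outflux(m1, GEO, 0.01) == pytest.approx(21.6, rel=1e-12)
        m2 = make_model(d=2, sigma2=0.001, s1=0.05, s2=0.005, rho=216, R=1)
        assert boundary_layer_count(m2, GEO, 0.01) == pytest.approx(
            2 * math.pi * 216 * 0.01, rel=1e-12)
        m3 = make_model(d=3, sigma2=0.001, s1=0.05, s2=0.005, rho=216, R=1)
        assert outflux(m3, GEO, 0.01) == pytest.approx(
            2 * 0.001 * math.pi * 216 / 0.01, rel=1e-12)

    def test_layer_too_thick_rejected(self):
        m = model_for("a", 1)
        with pytest.raises(ValueError, match="thin-layer"):
            outflux(m, GEO, 0.5 / m.beta2)


class TestReachProbability:
    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_boundary_condition_and_monotonicity(self, d):
        m = model_for("a", d)
        assert reach_probability(m, 2.0, 2.0) == pytest.approx(1.0)
        r = np.linspace(0.0, 2.0, 50)
        q = reach_probability(m, r, 2.0)
        assert np.all(np.diff(q) > 0)
        assert 0 < q[0] < 1

    def test_one_dimensional_closed_form(self):
        m = model_for("a", 1)
        b2 = m.beta2
        q = reach_probability(m, 1.0, 3.0)
        assert q == pytest.approx(math.cosh(b2) / math.cosh(3 * b2), rel=1e-12)
        assert reach_probability(m, 0.0, 3.0) == pytest.approx(
            1 / math.cosh(3 * b2), rel=1e-12)

    def test_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            reach_probability(model_for("a", 1), 2.5, 2.0)

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_against_direct_bvp_solution(self, d):
        # independent route: solve the linear reach ODE numerically
        m = model_for("a", d)
        s2, sig2 = m.s2, m.sigma2
        Rp = 2.0
        eps = 1e-6

        def rhs(r, y):
            return np.vstack([
                y[1],
                (2 * s2 * y[0] / sig2 - (d - 1) / r * y[1]),
            ])

        def bc(ya, yb):
            return np.array([ya[1], yb[0] - 1.0])

        r0 = np.linspace(eps, Rp, 400)
        y0 = np.vstack([np.exp(m.beta2 * (r0 - Rp)), np.ones_like(r0)])
        sol = solve_bvp(rhs, bc, r0, y0, tol=1e-8, max_nodes=500000)
        assert np.max(sol.rms_residuals) < 1e-8
        sample = np.linspace(0.05, Rp, 30)
        assert np.max(np.abs(sol.sol(sample)[0]
                             - reach_probability(m, sample, Rp))) < 1e-8


class TestConditionedDiffusion:
    @pytest.mark.parametrize("method", ["closed_form", "quadrature"])
    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_hit_probability_contract(self, method, d):
        m = model_for("a", d)
        r_min, Rp = 0.995, 4.0
        r = np.linspace(r_min, Rp, 200)
        v = conditioned_hit_probability(m, r, r_min, Rp, method=method)
        assert v[0] == pytest.approx(0.0, abs=1e-12)
        assert v[-1] == pytest.approx(1.0, rel=1e-12)
        assert np.all(np.diff(v) > 0)

    def test_both_scale_densities_agree(self):
        for d in (1, 2, 3):
            m = model_for("a", d)
            r = np.linspace(0.995, 4.0, 200)
            v_cf = conditioned_hit_probability(m, r, 0.995, 4.0)
            v_q = conditioned_hit_probability(m, r, 0.995, 4.0, method="quadrature")
            assert np.max(np.abs(v_cf - v_q)) < 1e-6


class TestNoReturn:
    def test_reference_value(self):
        # 2 beta2 dx / (1 + e^(-2 beta2 Rs)) at beta2 = sqrt(10), Rs = 1
        m = model_for("a", 1)
        P = no_return_probability(m, GEO, 0.01)
        assert P == pytest.approx(0.06313, abs=5e-6)

    def test_flat_boundary_limit(self):
        # Rs -> infinity: P -> 2 beta2 dx
        m = model_for("a", 1)
        geo = SourceGeometry(Rs=200.0, D=300.0)
        P = no_return_probability(m, geo, 0.01)
        assert P == pytest.approx(2 * m.beta2 * 0.01, rel=1e-12)

    @pytest.mark.parametrize("set_name", list(PARAM_SETS))
    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_quadrature_route_matches_closed_form(self, set_name, d):
        m = model_for(set_name, d)
        dx = 0.01 / m.beta2
        pc = no_return_probability(m, GEO, dx)
        pq = no_return_probability(m, GEO, dx, method="quadrature")
        assert pq == pytest.approx(pc, rel=1e-3)

    def test_linear_in_dx(self):
        m = model_for("a", 2)
        p1 = no_return_probability(m, GEO, 0.01)
        for f in (0.5, 0.1, 0.01):
            assert no_return_probability(m, GEO, 0.01 * f) == pytest.approx(
                f * p1, rel=1e-12)

    def test_r_prime_invariance(self):
        m = model_for("a", 3)
        b2 = m.beta2
        p1 = no_return_probability(m, GEO, 0.005, R_prime=1 + 10 / b2,
                                   method="quadrature")
        p2 = no_return_probability(m, GEO, 0.005, R_prime=1 + 20 / b2,
                                   method="quadrature")
        assert p2 == pytest.approx(p1, rel=1e-2)

    def test_asymptotic_regime_enforced(self):
        m = model_for("a", 1)
        with pytest.raises(ValueError, match="R_prime"):
            no_return_probability(m, GEO, 0.01, R_prime=1.5)
        # but the pre-asymptotic exact route is reachable explicitly
        p = no_return_probability(m, GEO, 0.01, R_prime=1.5, method="exact",
                                  enforce_regime=False)
        assert 0 < p < 1


class TestLambdaMig:
    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_dx_cancels_in_product_route(self, d):
        m = model_for("a", d)
        p = profile_for("a", d)
        b2 = m.beta2
        v1 = lambda_mig(m, GEO, p, method="product", dx=0.01 / b2)
        v2 = lambda_mig(m, GEO, p, method="product", dx=0.005 / b2)
        assert v2 == pytest.approx(v1, rel=1e-6)

    @pytest.mark.parametrize("set_name", list(PARAM_SETS))
    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_closed_form_equals_product(self, set_name, d):
        m = model_for(set_name, d)
        p = profile_for(set_name, d)
        direct = lambda_mig(m, GEO, p)
        product = lambda_mig(m, GEO, p, method="product")
        assert product == pytest.approx(direct, rel=1e-3)

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_strictly_decreasing_in_distance(self, d):
        m = model_for("a", d)
        p = profile_for("a", d)
        Ds = np.linspace(2.2, 5.0, 15)
        lams = [lambda_mig(m, SourceGeometry(Rs=1.0, D=D), p) for D in Ds]
        assert np.all(np.diff(lams) < 0)

    @pytest.mark.parametrize("set_name", list(PARAM_SETS))
    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_log_slope_approaches_decay_rate(self, set_name, d):
        # log lambda_mig falls at beta2 + (d-1)/(2D); the curvature term
        # vanishes only as D -> infinity
        m = model_for(set_name, d)
        p = profile_for(set_name, d, trunc_mult=25.0)
        b2 = m.beta2
        D0 = 2.0 + 15.0 / b2
        h = 0.05 / b2
        lo = lambda_mig(m, SourceGeometry(Rs=1.0, D=D0 - h), p)
        hi = lambda_mig(m, SourceGeometry(Rs=1.0, D=D0 + h), p)
        slope = (math.log(hi) - math.log(lo)) / (2 * h)
        assert slope == pytest.approx(-b2 - (d - 1) / (2 * D0), rel=0.02)

    def test_profile_model_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different model"):
            lambda_mig(model_for("a", 1), GEO, profile_for("b", 1))

    def test_overlapping_patches_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            lambda_mig(model_for("a", 1), SourceGeometry(Rs=1.0, D=1.5),
                       profile_for("a", 1))


class TestWaitingTime:
    def test_travel_term_arithmetic(self):
        # gap of 2 at approach speed beta2 sigma2 = 632.5 generations
        m = model_for("a", 1)
        p = profile_for("a", 1)
        tw = waiting_time(m, GEO, p)
        lam = lambda_mig(m, GEO, p)
        travel = tw - 1 / lam
        assert travel == pytest.approx(2 / (m.beta2 * m.sigma2), rel=1e-12)
        assert travel == pytest.approx(632.4555, rel=1e-6)
        assert tw > 1 / lam

    def test_touching_patches_have_no_travel_term(self):
        m = model_for("a", 1)
        p = profile_for("a", 1)
        geo = SourceGeometry(Rs=1.0, D=2.0 + 1e-12)
        tw = waiting_time(m, geo, p)
        assert tw == pytest.approx(1 / lambda_mig(m, geo, p), rel=1e-9)


class TestPartition:
    def test_mutation_fraction_bounds_and_value(self):
        m = model_for("a", 1)
        p = profile_for("a", 1)
        rep = rate_report(m, GEO, p, MutationSpec(1e-6))
        assert 0 <= rep.mutation_fraction <= 1
        assert rep.mutation_fraction == pytest.approx(
            rep.lambda_mut / (rep.lambda_mut + rep.lambda_mig), rel=1e-12)
        assert mutation_fraction(rep) == rep.mutation_fraction

    def test_critical_distance_root_and_density_invariance(self):
        mu = MutationSpec(1e-6)
        m = model_for("a", 1)
        p = profile_for("a", 1, trunc_mult=32.0)
        d_star = critical_distance(m, p, mu, Rs=1.0)
        lam_at_root = lambda_mig(m, SourceGeometry(Rs=1.0, D=d_star), p)
        assert abs(lam_at_root / lambda_mut(p, mu) - 1) < 1e-10
        # rho scales both rates identically, so the crossing cannot move
        m_hi = model_for("a", 1, rho=100 * RHO)
        p_hi = profile_for("a", 1, rho=100 * RHO, trunc_mult=32.0)
        assert critical_distance(m_hi, p_hi, mu, Rs=1.0) == pytest.approx(
            d_star, abs=1e-9)

    def test_no_crossing_is_explicit(self):
        m = model_for("a", 1)
        p = profile_for("a", 1, trunc_mult=32.0)
        with pytest.raises(NoCrossingError):
            critical_distance(m, p, MutationSpec(1e-6), Rs=1.0,
                              bracket=(8.0, 10.0))


def test_source_geometry_validation():
    with pytest.raises(ValueError):
        SourceGeometry(Rs=-1.0, D=4.0)
    with pytest.raises(ValueError):
        SourceGeometry(Rs=1.0, D=0.0)
    geo = SourceGeometry(Rs=1.0, D=1.9)
    with pytest.raises(ValueError, match="disjoint"):
        geo.validate(model_for("a", 1))
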