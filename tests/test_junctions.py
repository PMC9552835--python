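"""Junction coupling: boundary relations, Newton systems, stenosis drop."""

import math

import numpy as np
import pytest
from scipy.optimize import root

import graftflow as gf
from graftflow.junctions import (JunctionSolveError, PortState,
                                 left_boundary_relation,
                                 right_boundary_relation, solve_junction,
                                 stenosis_pressure_drop)
from graftflow.network import Junction, StenosisSpec, VesselSegment
from graftflow.units import dyn
from graftflow.wall import CORONARY, DEFAULT_P0, FluidProperties, stiffness_f

RHO = 1.06


class TestBoundaryRelations:
    def test_steady_uniform_state_returns_same_flow(self):
        a, q, dx, dt = 0.05, 1.3, 0.25, 1e-4
        s, b = right_boundary_relation(a, q, a, q, a, q, dx, dt)
        assert s * a + b == pytest.approx(q, rel=1e-14)
        s, b = left_boundary_relation(a, q, a, q, a, q, dx, dt)
        assert s * a + b == pytest.approx(q, rel=1e-14)

    def test_slopes_are_plus_minus_dx_over_dt(self):
        dx, dt = 0.3, 2.5e-4
        s_r, _ = right_boundary_relation(1, 0, 1, 0, 1, 0, dx, dt)
        s_l, _ = left_boundary_relation(1, 0, 1, 0, 1, 0, dx, dt)
        assert s_r == pytest.approx(-dx / dt)
        assert s_l == pytest.approx(dx / dt)

    def test_travelling_wave_prediction_matches_characteristics(self):
        """On a resolved right-travelling linear pulse (Q = c (A - A0)),
        the Keller-box relation predicts the endpoint flow within 1%."""
        a0 = math.pi * 0.5**2
        f = stiffness_f(0.5, CORONARY)
        c = math.sqrt(f / (2.0 * RHO))
        dx = 0.1
        dt = 0.5 * dx / c  # resolved: CFL 0.5
        eps = 1e-3 * a0
        width = 40 * dx

        def wave(x, t):
            arg = (x - c * t) / width
            a = a0 + eps * math.exp(-arg * arg)
            return a, c * (a - a0)

        x_m, x_m1 = 0.0, -dx  # endpoint and interior neighbour
        t0 = -width / c  # pulse centred upstream of the end at t=0
        a_m, q_m = wave(x_m, t0)
        a_i, q_i = wave(x_m1, t0)
        a_i1, q_i1 = wave(x_m1, t0 + dt)
        a_m_new, q_m_new = wave(x_m, t0 + dt)
        s, b = right_boundary_relation(a_m, q_m, a_i, q_i, a_i1, q_i1, dx, dt)
        assert s * a_m_new + b == pytest.approx(q_m_new, rel=0.01)


def _port(slope, a_target, q_target, radius, pext=0.0):
    """A PortState whose affine relation passes through the target state."""
    a0 = math.pi * radius**2
    f = stiffness_f(radius, CORONARY)
    b = q_target - slope * a_target
    return PortState(slope=slope, intercept=b, a0=a0, f=f, p0=DEFAULT_P0,
                     pext=pext, a_guess=a_target)


def _independent_residual(junction, ports, rho, dt=1.0, q_prev=0.0):
    """Bernoulli/mass system assembled independently of the solver path."""
    pairs = {
        "bifurcation": [(0, 1), (0, 2)],
        "trifurcation": [(0, 1), (0, 2), (0, 3)],
        "stenosis": [(0, 1)],
        "connector": [(0, 1)],
        "reverse_bifurcation": [(0, 2), (1, 2)],
        "cross_junction": [(0, 2), (0, 1), (0, 3)],
    }[junction.kind]
    ni = len(junction.parents)

    def fun(a):
        q = [p.slope * ai + p.intercept for p, ai in zip(ports, a)]
        tp = [p.pext + p.f * (1 - math.sqrt(p.a0 / ai)) + p.p0
              + 0.5 * rho * (qi / ai) ** 2
              for p, ai, qi in zip(ports, a, q)]
        out = [sum(q[:ni]) - sum(q[ni:])]
        for i, j in pairs:
            r = tp[i] - tp[j]
            if junction.kind == "stenosis":
                r -= stenosis_pressure_drop(q[0], (q[0] - q_prev) / dt,
                                            junction.stenosis)
            # normalise the pressure rows to O(1) so the generic solver's
            # convergence test treats all equations alike
            out.append(r / DEFAULT_P0)
        return out

    return fun


def _random_junction(kind, rng):
    """A random junction system with a physical solution nearby: port
    target states share a common junction pressure and conserve mass, so
    both Newton and the oracle have a well-posed root to find."""
    from graftflow.wall import area_from_pressure

    ni, nj = gf.network.JUNCTION_ARITY[kind]
    radius_parent = rng.uniform(0.1, 0.3)
    radii = [radius_parent * rng.uniform(0.9, 1.1) for _ in range(ni)] + [
        radius_parent * rng.uniform(0.6, 0.9) for _ in range(nj)]
    r = rng.uniform(800.0, 4000.0)  # dx/dt
    p_star = DEFAULT_P0 + dyn(rng.uniform(-5.0, 15.0))
    q_parents = [rng.uniform(0.3, 2.0) for _ in range(ni)]
    split = rng.dirichlet(np.ones(nj)) if nj > 1 else np.array([1.0])
    q_children = list(sum(q_parents) * split)
    ports = []
    for k, rad in enumerate(radii):
        slope = -r if k < ni else r
        f = stiffness_f(rad, CORONARY)
        a_t = area_from_pressure(p_star, math.pi * rad**2, f, DEFAULT_P0)
        q_t = q_parents[k] if k < ni else q_children[k - ni]
        ports.append(_port(slope, a_t, q_t, rad))
    sten = None
    if kind == "stenosis":
        seg = VesselSegment("H", 3.0, radius_parent)
        sten = StenosisSpec("H", 1.0, 0.8, rng.uniform(30, 90)).derive(
            seg, FluidProperties())
    names = [f"p{k}" for k in range(ni)], [f"c{k}" for k in range(nj)]
    junction = Junction(kind, *names, stenosis=sten)
    return junction, ports


class TestSolveJunction:
    def test_symmetric_bifurcation_splits_flow_evenly(self):
        parent = _port(-2000.0, 0.07, 2.0, 0.15)
        child = lambda: _port(2000.0, 0.03, 1.0, 0.10)  # noqa: E731
        junction = Junction("bifurcation", ["p"], ["c1", "c2"])
        a, q, p = solve_junction(junction, [parent, child(), child()], RHO,
                                 dt=1e-4)
        assert q[1] == pytest.approx(q[2], rel=1e-12)
        assert q[0] == pytest.approx(q[1] + q[2], rel=1e-12)

    def test_connector_of_equal_vessels_is_continuous(self):
        left = _port(-2000.0, 0.05, 1.5, 0.126)
        right = _port(2000.0, 0.05, 1.5, 0.126)
        junction = Junction("connector", ["g1"], ["g2"])
        a, q, p = solve_junction(junction, [left, right], RHO, dt=1e-4)
        assert a[0] == pytest.approx(a[1], rel=1e-12)
        assert q[0] == pytest.approx(q[1], rel=1e-12)
        assert p[0] == pytest.approx(p[1], rel=1e-12)

    def test_child_permutation_symmetry(self):
        parent = _port(-1500.0, 0.08, 2.5, 0.16)
        c1 = _port(1500.0, 0.04, 1.4, 0.11)
        c2 = _port(1500.0, 0.02, 0.9, 0.08)
        junction = Junction("bifurcation", ["p"], ["c1", "c2"])
        a12, q12, _ = solve_junction(junction, [parent, c1, c2], RHO, dt=1e-4)
        a21, q21, _ = solve_junction(junction, [parent, c2, c1], RHO, dt=1e-4)
        assert a12[1] == pytest.approx(a21[2], rel=1e-12)
        assert a12[2] == pytest.approx(a21[1], rel=1e-12)
        assert q12[0] == pytest.approx(q21[0], rel=1e-12)

    @pytest.mark.parametrize("kind", ["bifurcation", "trifurcation",
                                      "reverse_bifurcation", "cross_junction",
                                      "connector", "stenosis"])
    def test_newton_matches_brute_force_oracle(self, kind, rng):
        """Newton solutions equal an independent dense root search on the
        3x3 / 4x4 systems to 1e-8 (relative, on the areas)."""
        for trial in range(20):
            junction, ports = _random_junction(kind, rng)
            a_newton, _, _ = solve_junction(junction, ports, RHO, dt=1e-3)
            fun = _independent_residual(junction, ports, RHO, dt=1e-3)
            # dense multi-start search, refined by an independent solver
            best, best_norm = None, np.inf
            for scale in (0.9, 1.0, 1.05, 1.15):
                start = np.array([p.a_guess * scale for p in ports])
                sol = root(fun, start, method="hybr", tol=1e-13)
                norm = np.max(np.abs(fun(sol.x)))
                if norm < best_norm:
                    best, best_norm = sol.x, norm
            assert best_norm < 1e-9, f"oracle failed on trial {trial}"
            np.testing.assert_allclose(a_newton, best, rtol=1e-8)

    def test_nonconvergence_reports_junction(self):
        # an infeasible system: both children demand far more flow than the
        # parent relation can supply at any positive area
        parent = _port(-10.0, 0.05, 0.1, 0.13)
        c1 = _port(1e7, 0.05, 500.0, 0.13)
        c2 = _port(1e7, 0.05, 500.0, 0.13)
        junction = Junction("bifurcation", ["p"], ["c1", "c2"])
        with pytest.raises(JunctionSolveError):
            solve_junction(junction, [parent, c1, c2], RHO, dt=1e-4,
                           max_iter=5)


class TestStenosisPressureDrop:
    @pytest.fixture()
    def spec90(self):
        host = VesselSegment("H", 3.0, 0.15)
        return StenosisSpec("H", 1.0, 1.0, 90.0).derive(host, FluidProperties())

    def test_zero_grade_steady_flow_drops_nothing(self):
        host = VesselSegment("H", 3.0, 0.15)
        spec = StenosisSpec("H", 1.0, 1.0, 0.0).derive(host, FluidProperties())
        assert stenosis_pressure_drop(2.0, 0.0, spec) == 0.0

    def test_pure_inertial_term_at_zero_flow(self, spec90):
        dqdt = 7.5
        assert stenosis_pressure_drop(0.0, dqdt, spec90) == pytest.approx(
            spec90.au * dqdt)
        assert spec90.au == pytest.approx(1.2 * spec90.lu)

    def test_ninety_percent_hand_evaluation(self, spec90):
        """Term-by-term scalar oracle at Q = 1 cm^3/s, steady."""
        mu, rho, alpha = 0.046, 1.06, 1.1
        r0 = 0.15
        a0 = math.pi * r0**2
        ratio = 10.0  # A0/As at 90%
        r_s = math.sqrt((a0 / ratio) / math.pi)
        la = 0.83 * 1.0 + 3.28 * r_s
        kv = 4 * alpha / (alpha - 1) * (la / r0) * (ratio - 1) ** 2
        viscous = mu * kv / (2 * math.pi * r0**3) * 1.0
        turbulent = rho * 1.52 / (2 * a0**2) * (ratio - 1) ** 2 * 1.0
        assert stenosis_pressure_drop(1.0, 0.0, spec90) == pytest.approx(
            viscous + turbulent, rel=1e-12)

    def test_odd_symmetry_in_flow(self, spec90):
        drop_fwd = stenosis_pressure_drop(1.7, 0.0, spec90)
        drop_rev = stenosis_pressure_drop(-1.7, 0.0, spec90)
        assert drop_rev == pytest.approx(-drop_fwd)

    def test_nondecreasing_in_grade_at_fixed_flow(self):
        host = VesselSegment("H", 3.0, 0.15)
        fluid = FluidProperties()
        drops = [
            stenosis_pressure_drop(
                1.0, 0.0,
                StenosisSpec("H", 1.0, 1.0, pct).derive(host, fluid))
            for pct in np.linspace(0.0, 99.0, 34)
        ]
        assert all(b >= a for a, b in zip(drops, drops[1:]))
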