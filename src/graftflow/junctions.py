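"""Junction coupling: boundary relations and nonlinear junction systems.

Segment interiors are advanced independently; their endpoints are closed
by (i) a discrete relation between end area and end flow obtained from
Keller's box scheme on the mass-conservation equation, and (ii) the
junction system enforcing conservation of mass and continuity of total
pressure (Bernoulli) across the joined ports.  The resulting n-equation
nonlinear system in the n unknown port areas is solved by Newton-Raphson
each time step.

Port conventions are topological, not sign-adaptive: a parent joins at
its last gridpoint xM, a child at its first gridpoint x0, and reverse
flow simply appears as negative Q.  A stenosis junction adds the lumped
pressure drop dP = av Q + at Q|Q| + au dQ/dt to its total-pressure
equation.  A cross-junction (sequential graft) behaves like a
trifurcation: the first parent is the common total-pressure reference
for the second parent and both children.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Junction, StenosisSpec

__all__ = [
    "right_boundary_relation",
    "left_boundary_relation",
    "PortState",
    "solve_junction",
    "stenosis_pressure_drop",
    "JunctionSolveError",
    "pressure_pairs",
]


class JunctionSolveError(RuntimeError):
    """Newton iteration at a junction failed to converge."""


def right_boundary_relation(a_m: float, q_m: float, a_m1: float, q_m1: float,
                            a_m1_new: float, q_m1_new: float,
                            dx: float, dt: float) -> tuple[float, float]:
    """Affine map A_M^{n+1} -> Q_M^{n+1} at a parent's distal end.

    Returns (slope, intercept) with slope = -dx/dt; the intercept folds in
    the interior neighbour M-1 at time levels n and n+1 and the endpoint
    at n (Keller box on dA/dt + dQ/dx = 0 over the last cell).
    """
    r = dx / dt
    slope = -r
    intercept = r * (a_m + a_m1 - a_m1_new) - q_m + q_m1 + q_m1_new
    return slope, intercept


def left_boundary_relation(a_0: float, q_0: float, a_1: float, q_1: float,
                           a_1_new: float, q_1_new: float,
                           dx: float, dt: float) -> tuple[float, float]:
    """Affine map A_0^{n+1} -> Q_0^{n+1} at a child's proximal end
    (mirror of the right relation; slope = +dx/dt)."""
    r = dx / dt
    slope = r
    intercept = -r * (a_0 + a_1 - a_1_new) - q_0 + q_1 + q_1_new
    return slope, intercept


@dataclass
class PortState:
    """Everything the junction system needs to know about one port."""

    slope: float  # dQ/dA of the boundary relation (+-dx/dt)
    intercept: float
    a0: float  # unstressed area of the segment, cm^2
    f: float  # wall stiffness, dyn/cm^2
    p0: float  # reference pressure, dyn/cm^2
    pext: float  # tube-law external pressure at t^{n+1}, dyn/cm^2
    a_guess: float  # previous time-step endpoint area

    def flow(self, a: float) -> float:
        return self.slope * a + self.intercept

    def pressure(self, a: float) -> float:
        return self.pext + self.f * (1.0 - (self.a0 / a) ** 0.5) + self.p0

    def dp_da(self, a: float) -> float:
        return 0.5 * self.f * self.a0**0.5 * a**-1.5


def stenosis_pressure_drop(q: float, dq_dt: float, spec: StenosisSpec) -> float:
    """Lumped stenosis drop dP = av Q + at Q|Q| + au dQ/dt (dyn/cm^2);
    the turbulent term follows the sign of Q through Q|Q|."""
    return spec.av * q + spec.at * q * abs(q) + spec.au * dq_dt


def pressure_pairs(junction: Junction) -> list[tuple[int, int]]:
    """Index pairs (i, j) into parents+children whose total pressures are
    equated, per junction kind.  Indices: parents first, then children."""
    ni = len(junction.parents)
    kind = junction.kind
    if kind in ("bifurcation", "trifurcation", "stenosis", "connector"):
        # p1 against every child
        return [(0, ni + c) for c in range(len(junction.children))]
    if kind == "reverse_bifurcation":
        # each parent against the single child
        return [(0, ni), (1, ni)]
    if kind == "cross_junction":
        # behaves like a trifurcation: p1 is the common reference
        return [(0, ni), (0, 1), (0, ni + 1)]
    raise ValueError(f"unsupported junction kind {kind!r}")


def solve_junction(junction: Junction, ports: list[PortState], rho: float,
                   dt: float, q_throat_prev: float = 0.0,
                   tol: float = 1e-10, max_iter: int = 50,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the junction system for the port areas at n+1.

    ``ports`` lists parents first then children, in the junction's order.
    Returns (areas, flows, pressures).  Newton-Raphson from the previous
    time-step areas, analytic Jacobian, step damping x0.5 whenever an
    iterate would leave an area nonpositive.
    """
    n = len(ports)
    ni = len(junction.parents)
    pairs = pressure_pairs(junction)
    assert len(pairs) == n - 1

    sten = junction.stenosis
    a = np.array([p.a_guess for p in ports], dtype=float)
    res = np.empty(n)
    jac = np.empty((n, n))

    def residual_jacobian(a_vec):
        q = np.array([p.flow(ai) for p, ai in zip(ports, a_vec)])
        press = np.array([p.pressure(ai) for p, ai in zip(ports, a_vec)])
        v = q / a_vec
        tp = press + 0.5 * rho * v * v
        # d(total pressure)_k / d a_k
        dtp = np.array([
            p.dp_da(ai) + rho * qi * (p.slope * ai - qi) / ai**3
            for p, ai, qi in zip(ports, a_vec, q)
        ])
        res[0] = q[:ni].sum() - q[ni:].sum()
        jac[0, :] = [p.slope for p in ports]
        jac[0, ni:] *= -1.0
        for row, (i, j) in enumerate(pairs, start=1):
            res[row] = tp[i] - tp[j]
            jac[row, :] = 0.0
            jac[row, i] = dtp[i]
            jac[row, j] = -dtp[j]
            if sten is not None:
                # dP acts between p1 and c1 of the stenosis junction
                q_throat = q[0]
                dq_dt = (q_throat - q_throat_prev) / dt
                res[row] -= stenosis_pressure_drop(q_throat, dq_dt, sten)
                ddrop_dq = sten.av + 2.0 * sten.at * abs(q_throat) + sten.au / dt
                jac[row, 0] -= ddrop_dq * ports[0].slope
        return res, jac, q, press

    last_norm = np.inf
    for _ in range(max_iter):
        r_vec, j_mat, q, press = residual_jacobian(a)
        norm = float(np.max(np.abs(r_vec)))
        if norm < tol:
            return a, q, press
        if norm > 0.999 * last_norm and norm < 1e-7:
            # stalled at the floating-point floor of the pressure terms
            return a, q, press
        last_norm = norm
        try:
            step = np.linalg.solve(j_mat, r_vec)
        except np.linalg.LinAlgError as exc:
            raise JunctionSolveError(
                f"singular Jacobian at {junction.kind} junction "
                f"({junction.parents} -> {junction.children})"
            ) from exc
        a_new = a - step
        damp = 0
        while np.any(a_new <= 0.0) and damp < 30:
            step *= 0.5
            a_new = a - step
            damp += 1
        if damp >= 30:
            raise JunctionSolveError(
                f"persistent negative-area iterate at {junction.kind} junction "
                f"({junction.parents} -> {junction.children})"
            )
        a = a_new
    r_vec, _, q, press = residual_jacobian(a)
    norm = float(np.max(np.abs(r_vec)))
    if norm < 1e-6:
        return a, q, press
    raise JunctionSolveError(
        f"Newton did not converge at {junction.kind} junction "
        f"({junction.parents} -> {junction.children}); max |residual| = {norm:.3e}"
    )
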