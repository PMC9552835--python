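"""Inlet and outlet boundary conditions.

The network root receives a prescribed (Dirichlet) pressure waveform.
Every terminal segment drains into a three-element Windkessel (RCR):
proximal resistance R1, compliance Ct, distal resistance R2, referenced
to an external pressure Pext(t).  For coronary outlets Pext carries the
intramyocardial squeeze (scaled off the left-ventricular waveform: RV
beds see 0.2x, septal beds 0.6x); systemic beds see a constant venous
pressure.

The RCR ODE

    P = Pext + (R1 + R2) Q + R2 Ct (dPext/dt - dP/dt + R1 dQ/dt)

is discretised with first-order backward differences and rearranged for
Q^{n+1}; the outlet closure couples that update with the vessel's
right-sided boundary relation and the tube law, solved per time step by
relaxed fixed-point iteration on the terminal pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import dyn
from .wall import area_from_pressure, pressure_from_area

__all__ = [
    "Waveform",
    "external_pressure",
    "WindkesselOutlet",
    "windkessel_flow_update",
    "inlet_apply",
    "outlet_step",
    "OutletSolveError",
]


class OutletSolveError(RuntimeError):
    """Fixed-point iteration at a Windkessel outlet failed to converge."""


@dataclass(frozen=True)
class Waveform:
    """T-periodic piecewise-linear waveform sampled on a uniform grid.

    ``values`` (dyn/cm^2) are the samples at times k*T/n for k = 0..n-1;
    evaluation wraps periodically and interpolates linearly.
    """

    period: float
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("waveform needs at least two samples")
        if self.period <= 0:
            raise ValueError("waveform period must be positive")
        object.__setattr__(self, "values", vals)

    @classmethod
    def constant(cls, value: float, period: float = 1.0, n: int = 2) -> "Waveform":
        return cls(period, np.full(n, float(value)))

    @classmethod
    def from_samples(cls, times: np.ndarray, values: np.ndarray) -> "Waveform":
        """Resample (time, value) pairs spanning [0, T) onto the uniform grid."""
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be matching 1D arrays")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        period = times[-1] + (times[-1] - times[-2])  # closing interval
        n = times.size
        grid = np.arange(n) * period / n
        tt = np.concatenate([times, [period]])
        vv = np.concatenate([values, [values[0]]])
        return cls(period, np.interp(grid, tt, vv))

    def __call__(self, t):
        tau = np.mod(t, self.period)
        n = self.values.size
        grid = np.arange(n + 1) * self.period / n
        vals = np.concatenate([self.values, self.values[:1]])
        out = np.interp(tau, grid, vals)
        return float(out) if np.isscalar(t) else out

    def scaled(self, factor: float) -> "Waveform":
        return Waveform(self.period, self.values * factor)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def min(self) -> float:
        return float(np.min(self.values))


#: external-pressure scaling per myocardial class
PEXT_SCALE = {"LV": 1.0, "RV": 0.2, "septal": 0.6}
SYSTEMIC_VENOUS = dyn(1.0)  # constant 1 mmHg venous capillary pressure


def external_pressure(klass: str, t, lv_waveform: Waveform):
    """Pext(t) for a myocardial class: LV waveform scaled by 1.0 (LV),
    0.2 (RV) or 0.6 (septal); constant venous pressure for systemic beds."""
    if klass == "systemic":
        return SYSTEMIC_VENOUS if np.isscalar(t) else np.full(np.shape(t), SYSTEMIC_VENOUS)
    try:
        scale = PEXT_SCALE[klass]
    except KeyError:
        raise ValueError(f"unknown external-pressure class {klass!r}") from None
    return lv_waveform(t) * scale


def class_waveform(klass: str, lv_waveform: Waveform) -> Waveform:
    """The full Pext waveform object for a myocardial class."""
    if klass == "systemic":
        return Waveform.constant(SYSTEMIC_VENOUS, lv_waveform.period,
                                 lv_waveform.values.size)
    scale = PEXT_SCALE.get(klass)
    if scale is None:
        raise ValueError(f"unknown external-pressure class {klass!r}")
    return lv_waveform.scaled(scale)


@dataclass
class WindkesselOutlet:
    """Terminal RCR element in CGS (resistances dyn s/cm^5, Ct cm^5/dyn)."""

    r1: float
    r2: float
    ct: float
    pext_class: str = "systemic"
    pext: Waveform = field(default=None)  # resolved against the LV waveform

    def __post_init__(self) -> None:
        if min(self.r1, self.r2, self.ct) <= 0:
            raise ValueError("R1, R2 and Ct must all be positive")


def windkessel_flow_update(p_new: float, p_old: float, q_old: float,
                           pext_new: float, pext_old: float,
                           r1: float, r2: float, ct: float, dt: float) -> float:
    """Discrete RCR update for the outlet flow Q^{n+1} given the terminal
    pressures at n and n+1 (backward-difference discretisation of the RCR
    ODE, rearranged for Q^{n+1})."""
    return (
        q_old
        + (p_new - p_old) / r1
        + dt * p_old / (r1 * r2 * ct)
        - dt * (r2 + r1) * q_old / (r1 * r2 * ct)
        - (pext_new - pext_old) / r1
        - dt * pext_old / (r1 * r2 * ct)
    )


def inlet_apply(pressure: float, a0: float, f: float, p0: float,
                pext: float, left_relation: tuple[float, float]
                ) -> tuple[float, float, float]:
    """Dirichlet inlet: area from the inverse tube law at the prescribed
    pressure, flow from the left-sided boundary relation Q = s A + b."""
    a = area_from_pressure(pressure, a0, f, p0, pext)
    s, b = left_relation
    q = s * a + b
    return a, q, pressure


def outlet_step(right_relation: tuple[float, float], outlet: WindkesselOutlet,
                p_old: float, q_old: float, pext_old: float, pext_new: float,
                a0: float, f: float, p0: float, pext_seg: float, dt: float,
                relax: float = 0.5, tol: float = 1.333e-7, max_iter: int = 100,
                ) -> tuple[float, float, float]:
    """Advance a terminal endpoint one step.

    Fixed-point iteration on the terminal pressure P_M^{n+1}: the RCR
    update gives Q from P, the right boundary relation gives A from Q,
    and the tube law maps A back to a pressure; successive substitution
    with under-relaxation (default 0.5) to a tolerance of 1e-10 mmHg.

    ``pext_seg`` is the external pressure entering the *tube law* of the
    terminal segment itself at t^{n+1} (myocardial squeeze), which for
    coronary outlets equals the Windkessel reference ``pext_new``.
    """
    s, b = right_relation
    p = p_old
    for _ in range(max_iter):
        q = windkessel_flow_update(p, p_old, q_old, pext_new, pext_old,
                                   outlet.r1, outlet.r2, outlet.ct, dt)
        a = (q - b) / s
        if a <= 0:
            raise OutletSolveError(
                f"outlet iteration produced nonpositive area ({a:.3e} cm^2)"
            )
        p_tube = pressure_from_area(a, a0, f, p0, pext_seg)
        p_next = p + relax * (p_tube - p)
        if abs(p_next - p) < tol:
            q = windkessel_flow_update(p_next, p_old, q_old, pext_new, pext_old,
                                       outlet.r1, outlet.r2, outlet.ct, dt)
            a = (q - b) / s
            return a, q, pressure_from_area(a, a0, f, p0, pext_seg)
        p = p_next
    raise OutletSolveError(
        f"outlet fixed point did not converge in {max_iter} iterations "
        f"(last pressure {p / 1333.22:.4f} mmHg)"
    )
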