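"""Windkessel calibration: assigning R1, R2, Ct at every outlet.

The proximal resistance is the characteristic impedance Z0 = rho c0 / A0
of the terminal vessel (minimising wave reflection at the 1D/0D
interface).  The distal resistance closes a mean-flow balance

    R2 = (Pbar_start - Pbar_ext) / Qbar - R1D - R1

where Qbar is the outlet's prescribed mean flow, Pbar_start the estimated
mean pressure at the terminal segment's inlet, Pbar_ext the mean external
pressure of its bed, and R1D = (2 alpha/(alpha-1)) mu L / (pi R^4) the
alpha-corrected Poiseuille resistance of the terminal segment itself.
Compliances follow from the diastolic time constant of the inlet
waveform, Ct = tau / (R1 + R2), with tau fitted from the exponential
diastolic decay (default 1.25 s).

Mean flows are prescribed: systemic outlets as a percentage of cardiac
output; coronary outlets by splitting each myocardial territory's share
of the coronary fraction across its outlets in proportion to the
unstressed area raised to the power 2.6 (Murray-type rule).  Upstream
mean pressures descend from the mean inlet pressure through the
accumulated R1D x mean-flow drops along the root-to-terminal path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetworkTopology
from .terminals import SYSTEMIC_VENOUS, PEXT_SCALE, Waveform, WindkesselOutlet
from .units import DYN_TO_MMHG, ml_min
from .wall import FluidProperties, WallLaw, wave_speed

__all__ = [
    "CalibrationError",
    "FlowPrescription",
    "CalibrationReport",
    "characteristic_impedance",
    "resistance_1d",
    "prescribe_terminal_flows",
    "segment_mean_flows",
    "estimate_upstream_mean_pressure",
    "distal_resistance",
    "fit_time_constant",
    "capacitance",
    "calibrate",
]

MURRAY_EXPONENT = 2.6


class CalibrationError(ValueError):
    """Inconsistent or infeasible outlet calibration."""


@dataclass(frozen=True)
class FlowPrescription:
    """Mean-flow targets: cardiac output (ml/min), the coronary fraction
    (% of CO to the myocardium) and the split of myocardial flow across
    the three coronary territories (% summing to 100).  Systemic outlet
    percentages live on the segments themselves (``flow_pct``)."""

    cardiac_output: float = 5000.0  # ml/min
    coronary_fraction: float = 4.5  # % of CO
    territory_pct: dict[str, float] = field(
        default_factory=lambda: {"LAD": 42.0, "CIRC": 27.0, "RCA": 31.0})

    def __post_init__(self) -> None:
        if self.cardiac_output <= 0:
            raise ValueError("cardiac output must be positive")
        total = sum(self.territory_pct.values())
        if abs(total - 100.0) > 0.01:
            raise ValueError(
                f"territory percentages must sum to 100, got {total}")


def characteristic_impedance(r0: float, law: WallLaw, rho: float) -> float:
    """R1 = rho c0 / A0 in dyn s/cm^5."""
    a0 = math.pi * r0 * r0
    return rho * wave_speed(r0, law, rho) / a0


def resistance_1d(length: float, radius: float, alpha: float, mu: float) -> float:
    """Alpha-corrected Poiseuille resistance (2 alpha/(alpha-1)) mu L/(pi R^4);
    alpha = 4/3 recovers the classic 8 mu L / (pi R^4)."""
    if min(length, radius, mu) <= 0:
        raise ValueError("length, radius and viscosity must be positive")
    return (2.0 * alpha / (alpha - 1.0)) * mu * length / (math.pi * radius**4)


def prescribe_terminal_flows(topology: NetworkTopology,
                             prescription: FlowPrescription,
                             ) -> dict[str, float]:
    """Mean flow per outlet in cm^3/s.

    Systemic outlets receive flow_pct x CO.  Each coronary territory's
    total (CO x coronary% x territory%) is split across its outlets by
    A0^2.6.  The systemic percentages plus the coronary fraction must
    sum to 100 (+-0.01).
    """
    co = prescription.cardiac_output / 60.0  # cm^3/s
    flows: dict[str, float] = {}
    systemic_total = 0.0
    by_territory: dict[str, list[str]] = {}
    for name in topology.terminals:
        seg = topology.segments[name]
        if seg.outlet_class == "systemic":
            if seg.flow_pct is None:
                raise CalibrationError(
                    f"systemic outlet {name!r} has no flow percentage")
            systemic_total += seg.flow_pct
            flows[name] = seg.flow_pct / 100.0 * co
        else:
            if seg.territory is None:
                raise CalibrationError(
                    f"coronary outlet {name!r} has no territory assignment")
            by_territory.setdefault(seg.territory, []).append(name)
    check = systemic_total + prescription.coronary_fraction
    if abs(check - 100.0) > 0.01:
        raise CalibrationError(
            f"systemic percentages ({systemic_total}) plus coronary fraction "
            f"({prescription.coronary_fraction}) must sum to 100, got {check}")
    coronary_total = prescription.coronary_fraction / 100.0 * co
    for territory, names in by_territory.items():
        if territory not in prescription.territory_pct:
            raise CalibrationError(f"no percentage for territory {territory!r}")
        q_terr = prescription.territory_pct[territory] / 100.0 * coronary_total
        weights = np.array(
            [topology.segments[n].area0 ** MURRAY_EXPONENT for n in names])
        for n, w in zip(names, weights / weights.sum()):
            flows[n] = w * q_terr
    return flows


def segment_mean_flows(topology: NetworkTopology,
                       terminal_flows: dict[str, float]) -> dict[str, float]:
    """Propagate prescribed outlet flows up the tree: each segment carries
    the sum of the terminal flows in its downstream subtree.  Requires a
    pure tree (single-parent junctions) — calibrate before grafting."""
    for j in topology.junctions:
        if len(j.parents) > 1:
            raise CalibrationError(
                "mean-flow propagation requires a tree; calibrate on the "
                f"pre-graft network (found a {j.kind} junction)")
    flows: dict[str, float] = {}

    def descend(name: str) -> float:
        if name in flows:
            return flows[name]
        j = topology.children_of(name)
        if j is None:
            q = terminal_flows[name]
        else:
            q = sum(descend(c) for c in j.children)
        flows[name] = q
        return q

    descend(topology.root)
    return flows


def estimate_upstream_mean_pressure(topology: NetworkTopology,
                                    seg_flows: dict[str, float],
                                    mean_inlet_pressure: float,
                                    fluid: FluidProperties,
                                    ) -> dict[str, float]:
    """Mean pressure at each terminal segment's start: the mean inlet
    pressure minus the accumulated R1D x mean-flow drop over the
    root-to-terminal path (terminal segment excluded)."""
    pressures: dict[str, float] = {}
    for terminal in topology.terminals:
        p = mean_inlet_pressure
        for name in topology.path_to_root(terminal):
            seg = topology.segments[name]
            r1d = resistance_1d(seg.length, seg.radius, seg.alpha, fluid.mu)
            p -= r1d * seg_flows[name]
        pressures[terminal] = p
    return pressures


def distal_resistance(p_start: float, p_ext: float, q_terminal: float,
                      r1d: float, r1: float, outlet: str = "?") -> float:
    """R2 = (Pbar_start - Pbar_ext)/Qbar - R1D - R1; must come out positive."""
    if q_terminal <= 0:
        raise CalibrationError(f"outlet {outlet!r}: prescribed flow must be positive")
    r2 = (p_start - p_ext) / q_terminal - r1d - r1
    if r2 <= 0:
        raise CalibrationError(
            f"outlet {outlet!r}: nonpositive R2 ({r2:.3e}); the prescribed flow "
            f"{ml_min(q_terminal):.2f} ml/min exceeds what the available "
            f"pressure head can drive")
    return r2


def fit_time_constant(waveform: Waveform, p_ref: float,
                      p_out: float | None = None) -> float:
    """Diastolic time constant tau = R_total C_total (s) from the
    exponential decay P - Pout = (P_ref - Pout) exp(-(t - t0)/tau).

    The decay window starts where the waveform first falls through
    ``p_ref`` after its global peak and runs to the end of the period.
    With ``p_out`` given the fit is a linear regression on
    log(P - Pout); otherwise the asymptote is fitted too
    (three-parameter least squares).
    """
    n = waveform.values.size
    t = np.arange(n) * waveform.period / n
    v = waveform.values
    peak = int(np.argmax(v))
    after = np.nonzero(v[peak:] <= p_ref)[0]
    if after.size == 0:
        raise CalibrationError(
            "no diastolic decay window: waveform never falls to the reference "
            "pressure after its peak")
    i0 = peak + int(after[0])
    tw, vw = t[i0:], v[i0:]
    if vw.size < 3 or np.any(np.diff(vw) > 0):
        raise CalibrationError("diastolic window is too short or non-monotone")
    if p_out is not None:
        y = vw - p_out
        if np.any(y <= 0):
            raise CalibrationError("Pout must lie below the diastolic decay")
        slope = np.polyfit(tw, np.log(y), 1)[0]
        return -1.0 / slope
    from scipy.optimize import curve_fit

    def model(tt, tau, pout):
        return pout + (vw[0] - pout) * np.exp(-(tt - tw[0]) / tau)

    (tau, _), _ = curve_fit(model, tw, vw, p0=[1.0, vw[-1] - 0.2 * (vw[0] - vw[-1])],
                            maxfev=10000)
    return float(tau)


def capacitance(r1: float, r2: float, tau: float = 1.25) -> float:
    """Ct = tau / (R1 + R2) in cm^5/dyn."""
    if min(r1, r2) <= 0 or tau <= 0:
        raise ValueError("resistances and tau must be positive")
    return tau / (r1 + r2)


@dataclass
class CalibrationReport:
    """Calibrated outlets plus the per-outlet audit table."""

    outlets: dict[str, WindkesselOutlet]
    table: pd.DataFrame
    tau: float
    prescription: FlowPrescription

    def save(self, path) -> None:
        self.table.to_csv(path, index=False)


def calibrate(topology: NetworkTopology, prescription: FlowPrescription,
              inlet_waveform: Waveform, lv_waveform: Waveform,
              fluid: FluidProperties | None = None,
              tau: float | None = None) -> CalibrationReport:
    """Assign R1, R2, Ct at every outlet of a (pre-graft) network.

    Deterministic: identical topology and prescription give identical
    parameters.  ``tau`` defaults to 1.25 s; pass None to keep the default
    or a value refitted from the inlet waveform via ``fit_time_constant``.
    """
    fluid = fluid or FluidProperties()
    tau = 1.25 if tau is None else tau
    terminal_flows = prescribe_terminal_flows(topology, prescription)
    seg_flows = segment_mean_flows(topology, terminal_flows)
    p_in_mean = inlet_waveform.mean
    p_starts = estimate_upstream_mean_pressure(
        topology, seg_flows, p_in_mean, fluid)

    mean_lv = lv_waveform.mean
    rows = []
    outlets: dict[str, WindkesselOutlet] = {}
    for name in topology.terminals:
        seg = topology.segments[name]
        klass = seg.outlet_class
        p_ext = (SYSTEMIC_VENOUS if klass == "systemic"
                 else PEXT_SCALE[klass] * mean_lv)
        q = terminal_flows[name]
        r1 = characteristic_impedance(seg.radius, seg.law, fluid.rho)
        r1d = resistance_1d(seg.length, seg.radius, seg.alpha, fluid.mu)
        r2 = distal_resistance(p_starts[name], p_ext, q, r1d, r1, outlet=name)
        ct = capacitance(r1, r2, tau)
        outlets[name] = WindkesselOutlet(r1=r1, r2=r2, ct=ct, pext_class=klass)
        rows.append({
            "outlet": name, "class": klass, "territory": seg.territory or "",
            "Qbar_ml_min": ml_min(q),
            "Pbar_start_mmHg": p_starts[name] * DYN_TO_MMHG,
            "Pbar_ext_mmHg": p_ext * DYN_TO_MMHG,
            "R1": r1, "R1D": r1d, "R2": r2, "Ct": ct,
        })
    table = pd.DataFrame(rows)
    return CalibrationReport(outlets=outlets, table=table, tau=tau,
                             prescription=prescription)
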