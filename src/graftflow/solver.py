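"""Time integration of the 1D network: Richtmyer two-step Lax-Wendroff.

Each vessel segment advances its interior gridpoints with the two-step
(predictor at staggered midpoints, corrector) Lax-Wendroff scheme on the
conservative system

    d/dt [A, Q] + d/dx [Q, alpha Q^2/A + (f/rho) sqrt(A0 A)] = [0, S2]

where the pressure-gradient term has been folded into a conservative
flux using the tube law with f and A0 constant along the segment
(exact under step-wise taper), and the viscous source is
S2 = -2 pi nu (alpha/(alpha-1)) Q/A.

Endpoints are closed afterwards each step: Dirichlet pressure at the
network root, Newton junction systems at internal couplings, Windkessel
fixed points at terminals.  The run covers a fixed number of cardiac
cycles from rest (A = A0, Q = 0) and stores the final cycle at 100
equally spaced times; convergence to the periodic (dynamic steady)
state is measured as the relative L2 drift between the last two cycles.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import junctions as jn
from . import terminals as tm
from .network import NetworkTopology
from .units import DYN_TO_MMHG
from .wall import DEFAULT_P0, FluidProperties, pressure_from_area, stiffness_f, wave_speed

__all__ = [
    "SimulationConfig",
    "SolverError",
    "SegmentSolution",
    "SolutionStore",
    "cfl_max_dt",
    "lax_wendroff_interior",
    "run_simulation",
]

log = logging.getLogger(__name__)


class SolverError(RuntimeError):
    """Numerical failure (instability, divergence, CFL violation)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings for a network run.

    dx is the target grid spacing in cm (each segment uses M =
    max(2, round(L/dx)) cells so every segment keeps at least 3
    gridpoints); the time step is the CFL bound times ``cfl_safety``,
    rounded down so each cardiac period is an exact multiple of
    ``samples_per_cycle`` steps.
    """

    period: float = 0.917
    n_cycles: int = 4
    samples_per_cycle: int = 100
    dx: float = 0.1
    cfl_safety: float = 0.9
    drift_tol: float = 0.01
    p0: float = DEFAULT_P0

    def __post_init__(self) -> None:
        if self.period <= 0 or self.dx <= 0:
            raise ValueError("period and dx must be positive")
        if not 0 < self.cfl_safety <= 1:
            raise ValueError("cfl_safety must lie in (0, 1]")
        if self.n_cycles < 2:
            raise ValueError("need at least 2 cycles to measure drift")


def _segment_cells(length: float, dx: float) -> int:
    return max(2, int(round(length / dx)))


def cfl_max_dt(topology: NetworkTopology, dx: float, fluid: FluidProperties,
               safety: float = 0.9, velocities: dict[str, float] | None = None,
               ) -> float:
    """Largest stable time step: safety * min over segments of
    dx_s / (|V| + c0), with per-segment spacing dx_s = L/M and the
    unstressed Moens-Korteweg speed (V = 0 at rest unless supplied)."""
    bound = math.inf
    for seg in topology.segments.values():
        m = _segment_cells(seg.length, dx)
        dxs = seg.length / m
        c0 = wave_speed(seg.radius, seg.law, fluid.rho)
        v = abs(velocities.get(seg.name, 0.0)) if velocities else 0.0
        bound = min(bound, dxs / (v + c0))
    return safety * bound


def lax_wendroff_interior(a: np.ndarray, q: np.ndarray, dx: float, dt: float,
                          a0: float, f: float, alpha: float, rho: float,
                          nu: float) -> tuple[np.ndarray, np.ndarray]:
    """One Richtmyer step; returns the updated interior points 1..M-1.

    The half step evaluates fluxes and the viscous source at the staggered
    midpoints using averaged states; the corrector averages the two
    midpoint source evaluations.
    """
    fric = alpha / (alpha - 1.0)
    cf = f / rho
    f2 = alpha * q * q / a + cf * np.sqrt(a0 * a)
    s2 = (-2.0 * math.pi * nu * fric) * q / a
    lam = dt / dx
    a_h = 0.5 * (a[:-1] + a[1:]) - 0.5 * lam * (q[1:] - q[:-1])
    q_h = (0.5 * (q[:-1] + q[1:]) - 0.5 * lam * (f2[1:] - f2[:-1])
           + 0.25 * dt * (s2[:-1] + s2[1:]))
    if np.any(a_h <= 0.0):
        raise SolverError("negative area at half step")
    f2_h = alpha * q_h * q_h / a_h + cf * np.sqrt(a0 * a_h)
    s2_h = (-2.0 * math.pi * nu * fric) * q_h / a_h
    a_new = a[1:-1] - lam * (q_h[1:] - q_h[:-1])
    q_new = q[1:-1] - lam * (f2_h[1:] - f2_h[:-1]) + 0.5 * dt * (s2_h[1:] + s2_h[:-1])
    return a_new, q_new


@dataclass
class _Grid:
    """Per-segment runtime state."""

    name: str
    m: int
    dx: float
    a0: float
    f: float
    alpha: float
    pext_wave: tm.Waveform | None  # tube-law external pressure (terminals)
    a: np.ndarray = field(repr=False, default=None)
    q: np.ndarray = field(repr=False, default=None)
    a_new: np.ndarray = field(repr=False, default=None)
    q_new: np.ndarray = field(repr=False, default=None)

    def pext(self, t: float) -> float:
        return 0.0 if self.pext_wave is None else float(self.pext_wave(t))


@dataclass
class SegmentSolution:
    """Final-cycle solution of one segment: fields sampled at the stored
    times (rows) x gridpoints (columns)."""

    name: str
    x: np.ndarray
    a: np.ndarray
    q: np.ndarray
    p: np.ndarray
    pext: np.ndarray  # tube-law external pressure at the stored times


@dataclass
class SolutionStore:
    """The stored final cardiac cycle for every segment plus diagnostics."""

    times: np.ndarray
    period: float
    segments: dict[str, SegmentSolution]
    drift: dict[str, float]
    dt: float
    config: SimulationConfig
    meta: dict = field(default_factory=dict)

    def max_drift(self) -> float:
        return max(self.drift.values()) if self.drift else 0.0

    # ------------------------------------------------------------------- I/O
    def save(self, directory: str | Path) -> None:
        """Serialize to a directory: one delimited table per segment plus a
        JSON metadata document."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, seg in self.segments.items():
            mp1 = seg.x.size
            header = (["t_s"] + [f"A_{i}" for i in range(mp1)]
                      + [f"Q_{i}" for i in range(mp1)]
                      + [f"P_{i}" for i in range(mp1)] + ["Pext"])
            data = np.column_stack([self.times, seg.a, seg.q, seg.p, seg.pext])
            fname = directory / (name.replace("/", "_") + ".csv")
            np.savetxt(fname, data, delimiter=",", header=",".join(header),
                       comments="")
        meta = {
            "period_s": self.period,
            "dt_s": self.dt,
            "drift": self.drift,
            "grids": {n: list(map(float, s.x)) for n, s in self.segments.items()},
            "config": {
                "period": self.config.period,
                "n_cycles": self.config.n_cycles,
                "samples_per_cycle": self.config.samples_per_cycle,
                "dx": self.config.dx,
                "cfl_safety": self.config.cfl_safety,
                "p0_mmHg": self.config.p0 * DYN_TO_MMHG,
            },
            **self.meta,
        }
        (directory / "run_meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "SolutionStore":
        directory = Path(directory)
        meta = json.loads((directory / "run_meta.json").read_text())
        cfgm = meta["config"]
        config = SimulationConfig(
            period=cfgm["period"], n_cycles=cfgm["n_cycles"],
            samples_per_cycle=cfgm["samples_per_cycle"], dx=cfgm["dx"],
            cfl_safety=cfgm["cfl_safety"],
            p0=cfgm["p0_mmHg"] / DYN_TO_MMHG,
        )
        segments = {}
        times = None
        for name, xs in meta["grids"].items():
            x = np.asarray(xs)
            mp1 = x.size
            data = np.loadtxt(directory / (name.replace("/", "_") + ".csv"),
                              delimiter=",", skiprows=1, ndmin=2)
            times = data[:, 0]
            a = data[:, 1:1 + mp1]
            q = data[:, 1 + mp1:1 + 2 * mp1]
            p = data[:, 1 + 2 * mp1:1 + 3 * mp1]
            pext = data[:, 1 + 3 * mp1]
            segments[name] = SegmentSolution(name, x, a, q, p, pext)
        return cls(times=times, period=meta["period_s"], segments=segments,
                   drift=meta["drift"], dt=meta["dt_s"], config=config)


def run_simulation(topology: NetworkTopology,
                   outlets: dict[str, tm.WindkesselOutlet],
                   inlet_waveform: tm.Waveform,
                   lv_waveform: tm.Waveform,
                   config: SimulationConfig | None = None,
                   fluid: FluidProperties | None = None,
                   check_drift: bool = False) -> SolutionStore:
    """Run the pulsatile network simulation and return the stored final cycle.

    ``outlets`` maps every terminal segment name to its calibrated RCR
    element.  The inlet waveform is applied as a Dirichlet pressure at the
    root's first gridpoint; the left-ventricular external-pressure waveform
    drives the myocardial squeeze of coronary terminal segments through
    their outlet class.  With ``check_drift`` the run raises if the
    cycle-to-cycle relative L2 drift exceeds ``config.drift_tol``.
    """
    config = config or SimulationConfig()
    fluid = fluid or FluidProperties()
    report = topology.validate()
    root = report["root"]

    lmin = min(s.length for s in topology.segments.values())
    if config.dx >= lmin / 2.0:
        raise SolverError(
            f"dx = {config.dx} cm must be < Lmin/2 = {lmin / 2.0} cm to keep "
            "at least 3 gridpoints in every segment"
        )
    missing = [t for t in topology.terminals if t not in outlets]
    if missing:
        raise SolverError(f"terminal segments without Windkessel outlets: {missing}")

    grids: dict[str, _Grid] = {}
    for name, seg in topology.segments.items():
        m = _segment_cells(seg.length, config.dx)
        # the tube law of a terminal vessel carries the myocardial squeeze;
        # systemic terminals are not compressed (their Windkessel still
        # drains against the venous/class reference below)
        pw = (tm.class_waveform(seg.outlet_class, lv_waveform)
              if seg.outlet_class in ("LV", "RV", "septal") else None)
        g = _Grid(name=name, m=m, dx=seg.length / m, a0=seg.area0,
                  f=stiffness_f(seg.radius, seg.law), alpha=seg.alpha,
                  pext_wave=pw)
        g.a = np.full(m + 1, g.a0)
        g.q = np.zeros(m + 1)
        g.a_new = g.a.copy()
        g.q_new = g.q.copy()
        grids[name] = g

    # initial CFL bound from the rest state with a 15% velocity allowance
    # on top of the unstressed wave speed; re-audited every cycle
    v_allow = {name: 0.15 * math.sqrt(g.f / (2.0 * fluid.rho))
               for name, g in grids.items()}
    dt_bound = cfl_max_dt(topology, config.dx, fluid,
                          safety=config.cfl_safety, velocities=v_allow)
    samples = config.samples_per_cycle

    def _steps_for(bound: float) -> tuple[int, float, int]:
        n = samples * math.ceil(config.period / (samples * bound))
        return n, config.period / n, n // samples

    steps_per_cycle, dt, stride = _steps_for(dt_bound)
    log.info("dt = %.4e s (%d steps/cycle, CFL bound %.4e s)",
             dt, steps_per_cycle, dt_bound)

    # Windkessel reference pressure per outlet: an explicit override on the
    # outlet wins, otherwise the class waveform (LV-scaled or venous)
    wk_refs = {
        t: (outlets[t].pext if outlets[t].pext is not None
            else tm.class_waveform(outlets[t].pext_class, lv_waveform))
        for t in topology.terminals
    }

    # stenosis throat flow memory for the inertial backward difference
    throat_prev = {id(j): 0.0 for j in topology.junctions if j.kind == "stenosis"}

    # sample buffers for the last two cycles
    def _alloc():
        return {n: {"a": np.empty((samples, g.m + 1)),
                    "q": np.empty((samples, g.m + 1)),
                    "pext": np.empty(samples)}
                for n, g in grids.items()}

    buffers = {config.n_cycles - 2: _alloc(), config.n_cycles - 1: _alloc()}
    nu = fluid.nu
    rho = fluid.rho

    def _occupancy() -> float:
        worst = 0.0
        for g in grids.values():
            c = np.sqrt(g.f / (2.0 * rho)) * (g.a0 / g.a) ** 0.25
            v = np.abs(g.q / g.a)
            worst = max(worst, float(np.max((v + c) * dt / g.dx)))
        return worst

    for cycle in range(config.n_cycles):
        buf = buffers.get(cycle)
        occ_cycle = 0.0
        for k in range(steps_per_cycle):
            t_new = (cycle * steps_per_cycle + k + 1) * dt

            # 1. interiors
            for g in grids.values():
                try:
                    a_int, q_int = lax_wendroff_interior(
                        g.a, g.q, g.dx, dt, g.a0, g.f, g.alpha, rho, nu)
                except SolverError as exc:
                    raise SolverError(
                        f"segment {g.name!r}, cycle {cycle + 1}, step {k + 1}: {exc}"
                    ) from exc
                if not np.all(np.isfinite(q_int)) or np.any(a_int <= 0.0):
                    raise SolverError(
                        f"numerical instability in segment {g.name!r} at "
                        f"cycle {cycle + 1}, step {k + 1}"
                    )
                g.a_new[1:-1] = a_int
                g.q_new[1:-1] = q_int

            # 2. inlet (Dirichlet pressure at the root's x0)
            rg = grids[root]
            left = jn.left_boundary_relation(
                rg.a[0], rg.q[0], rg.a[1], rg.q[1], rg.a_new[1], rg.q_new[1],
                rg.dx, dt)
            a_in, q_in, _ = tm.inlet_apply(
                float(inlet_waveform(t_new)), rg.a0, rg.f, config.p0,
                rg.pext(t_new), left)
            rg.a_new[0] = a_in
            rg.q_new[0] = q_in

            # 3. junctions
            for junc in topology.junctions:
                ports: list[jn.PortState] = []
                for pname in junc.parents:
                    g = grids[pname]
                    s, b = jn.right_boundary_relation(
                        g.a[-1], g.q[-1], g.a[-2], g.q[-2],
                        g.a_new[-2], g.q_new[-2], g.dx, dt)
                    ports.append(jn.PortState(s, b, g.a0, g.f, config.p0,
                                              g.pext(t_new), g.a[-1]))
                for cname in junc.children:
                    g = grids[cname]
                    s, b = jn.left_boundary_relation(
                        g.a[0], g.q[0], g.a[1], g.q[1],
                        g.a_new[1], g.q_new[1], g.dx, dt)
                    ports.append(jn.PortState(s, b, g.a0, g.f, config.p0,
                                              g.pext(t_new), g.a[0]))
                try:
                    a_sol, q_sol, _ = jn.solve_junction(
                        junc, ports, rho, dt,
                        q_throat_prev=throat_prev.get(id(junc), 0.0))
                except jn.JunctionSolveError as exc:
                    raise SolverError(
                        f"cycle {cycle + 1}, step {k + 1}: {exc}") from exc
                if junc.kind == "stenosis":
                    throat_prev[id(junc)] = float(q_sol[0])
                idx = 0
                for pname in junc.parents:
                    g = grids[pname]
                    g.a_new[-1] = a_sol[idx]
                    g.q_new[-1] = q_sol[idx]
                    idx += 1
                for cname in junc.children:
                    g = grids[cname]
                    g.a_new[0] = a_sol[idx]
                    g.q_new[0] = q_sol[idx]
                    idx += 1

            # 4. Windkessel outlets
            t_old = t_new - dt
            for tname in topology.terminals:
                g = grids[tname]
                s, b = jn.right_boundary_relation(
                    g.a[-1], g.q[-1], g.a[-2], g.q[-2],
                    g.a_new[-2], g.q_new[-2], g.dx, dt)
                out = outlets[tname]
                wk_wave = wk_refs[tname]
                pext_old = float(wk_wave(t_old))
                pext_new = float(wk_wave(t_new))
                p_old = pressure_from_area(g.a[-1], g.a0, g.f, config.p0,
                                           g.pext(t_old))
                try:
                    a_t, q_t, _ = tm.outlet_step(
                        (s, b), out, p_old, g.q[-1], pext_old, pext_new,
                        g.a0, g.f, config.p0, g.pext(t_new), dt)
                except tm.OutletSolveError as exc:
                    raise SolverError(
                        f"outlet {tname!r}, cycle {cycle + 1}, step {k + 1}: {exc}"
                    ) from exc
                g.a_new[-1] = a_t
                g.q_new[-1] = q_t

            # 5. commit
            for g in grids.values():
                g.a, g.a_new = g.a_new, g.a
                g.q, g.q_new = g.q_new, g.q

            if (k + 1) % stride == 0:
                occ_cycle = max(occ_cycle, _occupancy())
                if buf is not None:
                    srow = (k + 1) // stride - 1
                    for n, g in grids.items():
                        buf[n]["a"][srow] = g.a
                        buf[n]["q"][srow] = g.q
                        buf[n]["pext"][srow] = g.pext(t_new)

        # per-cycle CFL audit: abort on outright violation, shrink dt for
        # the remaining cycles if the margin has eroded
        if occ_cycle > 1.02:
            raise SolverError(
                f"CFL violated during cycle {cycle + 1}: "
                f"max (|V|+c) dt/dx = {occ_cycle:.3f}"
            )
        log.info("cycle %d/%d done, CFL occupancy %.3f",
                 cycle + 1, config.n_cycles, occ_cycle)
        if occ_cycle > 0.98 and cycle + 1 < config.n_cycles:
            steps_per_cycle, dt, stride = _steps_for(
                dt * config.cfl_safety / occ_cycle)
            log.info("CFL margin eroded; dt reduced to %.4e s", dt)

    # assemble the stored (final) cycle and the cycle-to-cycle drift
    times = (np.arange(1, samples + 1)) * config.period / samples
    prev, last = buffers[config.n_cycles - 2], buffers[config.n_cycles - 1]
    segments: dict[str, SegmentSolution] = {}
    drift: dict[str, float] = {}
    for name, g in grids.items():
        a_s = last[name]["a"]
        q_s = last[name]["q"]
        pext_s = last[name]["pext"]
        p_s = np.empty_like(a_s)
        for i in range(samples):
            p_s[i] = pressure_from_area(a_s[i], g.a0, g.f, config.p0, pext_s[i])
        x = np.arange(g.m + 1) * g.dx
        segments[name] = SegmentSolution(name, x, a_s, q_s, p_s, pext_s)
        dq = np.linalg.norm(q_s - prev[name]["q"])
        dp_prev = prev[name]["a"]
        da = np.linalg.norm(a_s - dp_prev)
        qn = np.linalg.norm(prev[name]["q"])
        an = np.linalg.norm(dp_prev)
        # flow drift normalised by the cycle's flow scale (or the area scale
        # for quiescent vessels), area drift relative to the area norm
        drift[name] = max(dq / max(qn, 1e-9 * an), da / an)

    import hashlib

    topo_hash = hashlib.sha256("|".join(
        f"{n}:{s.length}:{s.radius}:{s.wall_law}"
        for n, s in sorted(topology.segments.items())).encode()).hexdigest()[:16]
    store = SolutionStore(times=times, period=config.period, segments=segments,
                          drift=drift, dt=dt, config=config,
                          meta={"root": root, "steps_per_cycle": steps_per_cycle,
                                "topology_hash": topo_hash})
    if check_drift and store.max_drift() > config.drift_tol:
        worst_seg = max(drift, key=drift.get)
        raise SolverError(
            f"no dynamic steady state: drift {drift[worst_seg]:.3%} in "
            f"segment {worst_seg!r} exceeds {config.drift_tol:.1%}"
        )
    return store
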