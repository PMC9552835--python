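"""High-level modelling interface: build once, run, inspect results.

``CoronarySimulation`` bundles a network topology (with optional stenosis
and graft edits), the inlet and LV external-pressure waveforms, a flow
prescription and the numerical settings.  ``run()`` calibrates the
Windkessel outlets on the pre-edit (disease-free) network, carries those
parameters to the edited network, integrates the requested cardiac
cycles and returns a ``SimulationResults`` object holding the stored
cycle, the calibration report, convergence diagnostics and the clinical
metrics, with a printable ``summary()``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from .calibration import CalibrationReport, FlowPrescription, calibrate
from .metrics import (CardiacPhaseMap, graft_report, ifr, mean_flow,
                      territory_perfusion)
from .network import GraftSpec, NetworkTopology, StenosisSpec, insert_graft, insert_stenosis
from .solver import SimulationConfig, SolutionStore, run_simulation
from .terminals import Waveform
from .wall import FluidProperties

__all__ = ["CoronarySimulation", "SimulationResults"]

_EDIT_SUFFIXES = ("_psten", "_dsten", "_pgraf", "_dgraf")


def _strip_edit_suffixes(name: str) -> str:
    """Original segment name behind a chain of edit renamings
    (e.g. 'OM1_dsten_dgraf' -> 'OM1'): the calibrated outlet of a split
    terminal carries over to its distal remainder."""
    changed = True
    while changed:
        changed = False
        for suffix in _EDIT_SUFFIXES:
            if name.endswith(suffix):
                name = name[: -len(suffix)]
                changed = True
    return name


@dataclass
class CoronarySimulation:
    """A 1D-0D pulsatile flow model of one circulation scenario.

    ``base`` is the disease-free network used for outlet calibration;
    stenoses and grafts listed in ``edits`` are applied on top of it (in
    order) to produce the simulated topology.  Waveforms are in CGS
    (build them with the fixtures module or load from two-column tables).
    """

    base: NetworkTopology
    inlet: Waveform
    lv_external: Waveform
    edits: list[StenosisSpec | GraftSpec] = field(default_factory=list)
    prescription: FlowPrescription = field(default_factory=FlowPrescription)
    config: SimulationConfig = field(default_factory=SimulationConfig)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    tau: float | None = None
    #: dicrotic notch time (s) for the cardiac phase map; defaults to the
    #: inlet waveform's 0.4 T convention if not given
    t_notch: float | None = None

    def build_topology(self) -> NetworkTopology:
        topo = self.base
        for edit in self.edits:
            if isinstance(edit, StenosisSpec):
                topo = insert_stenosis(topo, edit, self.fluid)
            elif isinstance(edit, GraftSpec):
                topo = insert_graft(topo, edit)
            else:
                raise TypeError(f"unknown edit {edit!r}")
        return topo

    def calibrate(self) -> CalibrationReport:
        return calibrate(self.base, self.prescription, self.inlet,
                         self.lv_external, self.fluid, tau=self.tau)

    def run(self, check_drift: bool = False) -> "SimulationResults":
        """Calibrate, integrate, and package the results."""
        report = self.calibrate()
        topo = self.build_topology()
        outlets = {}
        for t in topo.terminals:
            base = _strip_edit_suffixes(t)
            if base in report.outlets:
                outlets[t] = report.outlets[base]
        store = run_simulation(topo, outlets, self.inlet, self.lv_external,
                               self.config, self.fluid,
                               check_drift=check_drift)
        notch = self.t_notch if self.t_notch is not None else 0.4 * store.period
        phases = CardiacPhaseMap(period=store.period, t_notch=notch)
        return SimulationResults(model=self, topology=topo, store=store,
                                 calibration=report, phases=phases)


@dataclass
class SimulationResults:
    """Stored final cycle plus derived clinical outputs."""

    model: CoronarySimulation
    topology: NetworkTopology
    store: SolutionStore
    calibration: CalibrationReport
    phases: CardiacPhaseMap

    # ------------------------------------------------------------- quantities
    def cardiac_output(self) -> float:
        """Mean flow at the network root inlet, ml/min."""
        return mean_flow(self.store, self.topology.root, site=0)

    def perfusion(self) -> dict[str, float]:
        """Per-territory and total myocardial perfusion, ml/min."""
        return territory_perfusion(self.store, self.topology)

    def stenosis_ifr(self) -> dict[str, float]:
        """iFR for every stenosis junction present in the topology."""
        out = {}
        for j in self.topology.junctions:
            if j.kind == "stenosis" and j.stenosis is not None:
                out[j.stenosis.host] = ifr(
                    self.store, j.stenosis.host, self.phases,
                    proximal=j.parents[0], distal=j.children[0])
        return out

    def grafts(self, segments: dict[str, str], site: int = -1) -> pd.DataFrame:
        """TTFM metric table for the given {label: graft segment} map."""
        return graft_report(self.store, segments, self.phases, site=site)

    def drift(self) -> float:
        return self.store.max_drift()

    # ---------------------------------------------------------------- summary
    def summary(self, graft_segments: dict[str, str] | None = None) -> str:
        buf = io.StringIO()
        w = buf.write
        n_seg = len(self.topology.segments)
        n_jun = len(self.topology.junctions)
        w("1D-0D coronary network simulation\n")
        w("=" * 50 + "\n")
        w(f"segments: {n_seg}   junctions: {n_jun}   "
          f"outlets: {len(self.topology.terminals)}\n")
        w(f"period: {self.store.period:.3f} s   dt: {self.store.dt:.3e} s   "
          f"stored samples: {self.store.times.size}\n")
        w(f"cycle-to-cycle drift (max rel. L2): {self.drift():.3%}\n")
        w(f"cardiac output at root: {self.cardiac_output():.1f} ml/min\n")
        perf = self.perfusion()
        if len(perf) > 1:
            w("myocardial perfusion (ml/min): ")
            w("  ".join(f"{k}={v:.2f}" for k, v in perf.items()) + "\n")
        ifrs = self.stenosis_ifr()
        if ifrs:
            w("stenosis iFR: " + "  ".join(
                f"{k}={v:.3f}" for k, v in ifrs.items()) + "\n")
        if graft_segments:
            w("\ngraft performance (measured at the distal anastomosis):\n")
            table = self.grafts(graft_segments)
            w(table.to_string(index=False,
                              float_format=lambda x: f"{x:.2f}") + "\n")
        return buf.getvalue()
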