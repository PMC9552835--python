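"""Synthetic inputs: parametric waveforms and a reduced coronary network.

Everything the pipeline consumes can be generated here, deterministic in
a seed: an aortic-root inlet pressure waveform (systolic rise, dicrotic
notch, exponential diastolic decay with a prescribed time constant), a
synchronised left-ventricular external-pressure waveform, and a toy
network — an aortic trunk with IMA take-offs and three coronary
territories — together with a stenosis scenario and two grafting
scenarios ("separate": in-situ LIMA + in-situ RIMA + free aortic radial
graft; "composite": in-situ LIMA with a radial Y limb extended end-to-end
and sewn sequentially through the circumflex target onward to the PDA).
Across its variants the toy network exercises every junction kind.

The defaults are resting physiological conditions: period 0.917 s
(≈65 bpm), diastolic pressure 76.41 mmHg, diastolic time constant
1.25 s, cardiac output 5 l/min with 4.5% to the coronary circulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import FlowPrescription
from .network import (GraftSpec, NetworkTopology, StenosisSpec, VesselSegment,
                      Junction, insert_graft, insert_stenosis, write_network,
                      write_scenario)
from .solver import SimulationConfig
from .terminals import Waveform
from .units import dyn

__all__ = [
    "WaveformParams",
    "generate_inlet_pressure",
    "generate_lv_external_pressure",
    "ToyNetwork",
    "make_toy_network",
]


@dataclass(frozen=True)
class WaveformParams:
    """Shape parameters of the synthetic pressure waveforms (mmHg, s)."""

    period: float = 0.917
    diastolic: float = 76.41
    systolic: float = 120.0
    notch_pressure: float = 86.92  # pressure at the start of diastolic decay
    notch_fraction: float = 0.40  # dicrotic notch time as a fraction of T
    tau: float = 1.25  # diastolic decay time constant, s
    lv_peak: float = 100.0  # peak LV external pressure
    venous_offset: float = 1.0  # diastolic plateau / systemic venous pressure
    n_samples: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.notch_fraction < 1.0:
            raise ValueError("notch fraction must lie in (0, 1)")
        if self.tau <= 0 or self.period <= 0:
            raise ValueError("period and tau must be positive")

    @property
    def t_notch(self) -> float:
        return self.notch_fraction * self.period


def generate_inlet_pressure(params: WaveformParams | None = None) -> Waveform:
    """Synthetic aortic-root pressure over one period (dyn/cm^2).

    Piecewise: a half-sine systolic upstroke from the diastolic foot to
    the systolic peak, a quarter-cosine fall to the dicrotic-notch
    pressure, then an exponential diastolic decay with time constant tau
    whose asymptote is chosen so the waveform lands exactly back on the
    diastolic pressure at the end of the period.  The minimum is the
    diastolic parameter, at the foot t = 0.  Zero pulse amplitude
    (systolic == diastolic) degenerates to a constant waveform.
    """
    p = params or WaveformParams()
    n = p.n_samples
    t = np.arange(n) * p.period / n
    if p.systolic <= p.diastolic:
        return Waveform(p.period, np.full(n, dyn(p.diastolic)))
    t_n = p.t_notch
    t_p = 0.5 * t_n  # systolic peak time
    decay_len = p.period - t_n
    e = math.exp(-decay_len / p.tau)
    p_out = (p.diastolic - p.notch_pressure * e) / (1.0 - e)
    vals = np.empty(n)
    rise = t < t_p
    fall = (t >= t_p) & (t < t_n)
    decay = t >= t_n
    vals[rise] = p.diastolic + (p.systolic - p.diastolic) * np.sin(
        0.5 * math.pi * t[rise] / t_p)
    vals[fall] = p.notch_pressure + (p.systolic - p.notch_pressure) * np.cos(
        0.5 * math.pi * (t[fall] - t_p) / (t_n - t_p))
    vals[decay] = p_out + (p.notch_pressure - p_out) * np.exp(
        -(t[decay] - t_n) / p.tau)
    return Waveform(p.period, dyn(1.0) * vals)


def generate_lv_external_pressure(params: WaveformParams | None = None) -> Waveform:
    """Synthetic LV external pressure: a sin^2 systolic squeeze peaking
    mid-systole of the paired inlet waveform, on a diastolic plateau equal
    to the venous offset (dyn/cm^2)."""
    p = params or WaveformParams()
    n = p.n_samples
    t = np.arange(n) * p.period / n
    t_n = p.t_notch
    vals = np.full(n, p.venous_offset)
    sys_mask = t < t_n
    vals[sys_mask] += (p.lv_peak - p.venous_offset) * np.sin(
        math.pi * t[sys_mask] / t_n) ** 2
    return Waveform(p.period, dyn(1.0) * vals)


# --------------------------------------------------------------------- toy net

#: (name, length cm, radius cm, wall law, outlet class, territory, flow % CO)
_TOY_SEGMENTS = [
    ("AO1",   2.0, 1.47, "large_systemic", None, None, None),
    ("LMCA",  1.2, 0.25, "coronary", None, None, None),
    ("RCA",   2.6, 0.18, "coronary", None, None, None),
    ("AA",    2.0, 1.47, "large_systemic", None, None, None),
    ("ARCH",  2.0, 1.12, "large_systemic", None, None, None),
    ("LSCA",  2.0, 0.42, "large_systemic", None, None, None),
    ("DA",    3.0, 1.00, "large_systemic", "systemic", None, 64.6),
    ("INN",   2.0, 0.62, "large_systemic", None, None, None),
    ("RSCA",  2.0, 0.45, "large_systemic", "systemic", None, 16.9),
    ("RIMA", 10.0, 0.14, "coronary", "systemic", None, 2.4),
    ("LSCA2", 2.0, 0.38, "large_systemic", "systemic", None, 9.4),
    ("LIMA", 10.0, 0.13, "coronary", "systemic", None, 2.2),
    ("LAD1",  2.4, 0.18, "coronary", None, None, None),
    ("LAD2",  3.0, 0.14, "coronary", "LV", "LAD", None),
    ("D1",    1.5, 0.10, "coronary", "LV", "LAD", None),
    ("CIRC1", 2.0, 0.17, "coronary", None, None, None),
    ("OM1",   3.0, 0.12, "coronary", "LV", "CIRC", None),
    ("CIRC2", 2.0, 0.13, "coronary", "LV", "CIRC", None),
    ("PDA",   2.5, 0.12, "coronary", "septal", "RCA", None),
    ("RVB",   1.5, 0.09, "coronary", "RV", "RCA", None),
]

_TOY_JUNCTIONS = [
    ("trifurcation", ["AO1"], ["LMCA", "RCA", "AA"]),
    ("bifurcation", ["AA"], ["ARCH", "LSCA"]),
    ("bifurcation", ["ARCH"], ["DA", "INN"]),
    ("bifurcation", ["INN"], ["RSCA", "RIMA"]),
    ("bifurcation", ["LSCA"], ["LSCA2", "LIMA"]),
    ("bifurcation", ["LMCA"], ["LAD1", "CIRC1"]),
    ("bifurcation", ["LAD1"], ["LAD2", "D1"]),
    ("bifurcation", ["CIRC1"], ["OM1", "CIRC2"]),
    ("bifurcation", ["RCA"], ["PDA", "RVB"]),
]

#: stenosis scenario: (host, position cm, length cm, % diameter)
_TOY_STENOSES = [
    ("LAD1", 0.8, 0.8, 90.0),
    ("OM1", 0.8, 0.6, 95.0),
    ("RCA", 1.0, 0.6, 90.0),
]


@dataclass
class ToyNetwork:
    """The generated fixture: topologies for every disease/graft stage,
    waveforms, flow prescription and solver settings sized to the grid."""

    seed: int
    base: NetworkTopology
    stenotic: NetworkTopology
    separate: NetworkTopology
    composite: NetworkTopology
    stenoses: list[StenosisSpec]
    inlet: Waveform
    lv_external: Waveform
    waveform_params: WaveformParams
    prescription: FlowPrescription
    config: SimulationConfig
    #: display label -> graft segment to measure, per scenario
    graft_segments: dict[str, dict[str, str]] = field(default_factory=dict)
    #: scenario name -> ordered edit list (stenoses + grafts)
    edits: dict[str, list] = field(default_factory=dict)

    def topology(self, scenario: str) -> NetworkTopology:
        try:
            return {"base": self.base, "stenotic": self.stenotic,
                    "separate": self.separate, "composite": self.composite}[scenario]
        except KeyError:
            raise KeyError(f"unknown scenario {scenario!r}") from None

    def write(self, directory) -> None:
        """Emit the file formats the loaders read: segment CSV + relations
        config per scenario, waveform tables, and the prescription."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for scenario in ("base", "stenotic", "separate", "composite"):
            topo = self.topology(scenario)
            write_network(topo, directory / f"{scenario}_segments.csv",
                          directory / f"{scenario}_relations.cfg")
        for scenario, edit_list in self.edits.items():
            write_scenario(edit_list, directory / f"{scenario}_scenario.yaml")
        for label, wave in (("inlet_pressure", self.inlet),
                            ("lv_external_pressure", self.lv_external)):
            n = wave.values.size
            t = np.arange(n) * wave.period / n
            np.savetxt(directory / f"{label}.csv",
                       np.column_stack([t, wave.values / dyn(1.0)]),
                       delimiter=",", header="t_s,p_mmHg", comments="")


def make_toy_network(seed: int = 0, radius_jitter: float = 0.03) -> ToyNetwork:
    """Deterministic (seeded) reduced coronary network with scenarios.

    ``radius_jitter`` perturbs every vessel radius by up to +-3%
    (uniformly, seeded) so that different seeds give distinct but equally
    valid geometries; lengths and topology are fixed so the scenario
    edits always fit their hosts.
    """
    rng = np.random.default_rng(seed)
    segments: dict[str, VesselSegment] = {}
    for name, length, radius, law, klass, terr, pct in _TOY_SEGMENTS:
        r = radius * (1.0 + radius_jitter * rng.uniform(-1.0, 1.0))
        segments[name] = VesselSegment(
            name, length, r, law, outlet_class=klass, territory=terr,
            flow_pct=pct)
    junctions = [Junction(kind, list(ps), list(cs))
                 for kind, ps, cs in _TOY_JUNCTIONS]
    base = NetworkTopology(segments, junctions)
    base.validate()

    stenoses = [StenosisSpec(host=h, position=pos, length=ln, percent=pct)
                for h, pos, ln, pct in _TOY_STENOSES]
    stenotic = base
    for spec in stenoses:
        stenotic = insert_stenosis(stenotic, spec)

    # separate grafting: three independent inflows
    separate_grafts = [
        GraftSpec(kind="in_situ", source="LIMA", target="LAD2", position=2.0),
        GraftSpec(kind="in_situ", source="RIMA", target="OM1_dsten",
                  position=0.8),
        GraftSpec(kind="free_aortic", source="AA", source_position=1.0,
                  name="RA", radius=0.17, length=6.0, target="PDA",
                  position=1.5),
    ]
    separate = stenotic
    for g in separate_grafts:
        separate = insert_graft(separate, g)

    # composite grafting: single LIMA inflow, radial Y limb extended
    # end-to-end (connector) and sewn sequentially through the OM target
    # onward to the PDA
    composite_grafts = [
        GraftSpec(kind="in_situ", source="LIMA", target="LAD2", position=2.0),
        GraftSpec(kind="y_composite", source="LIMA", source_position=4.0,
                  name="RAy", radius=0.15, length=3.0),
        GraftSpec(kind="i_extension", source="RAy", name="RAy_ext",
                  radius=0.15, length=2.0),
        GraftSpec(kind="sequential", source="RAy_ext", target="OM1_dsten",
                  position=0.8, name="RA_PDA", radius=0.14, length=4.0),
        GraftSpec(kind="in_situ", source="RA_PDA", target="PDA", position=1.5),
    ]
    composite = stenotic
    for g in composite_grafts:
        composite = insert_graft(composite, g)

    graft_segments = {
        "separate": {
            "LIMA to LAD": "LIMA",
            "RIMA to OM": "RIMA",
            "RA to PDA": "RA",
        },
        "composite": {
            "LIMA common stem": "LIMA_Y",
            "LIMA to LAD": "LIMA_cont",
            "RA Y-limb to OM": "RAy_ext",
            "RA sequential to PDA": "RA_PDA",
        },
    }

    params = WaveformParams()
    return ToyNetwork(
        seed=seed,
        base=base, stenotic=stenotic, separate=separate, composite=composite,
        stenoses=stenoses,
        inlet=generate_inlet_pressure(params),
        lv_external=generate_lv_external_pressure(params),
        waveform_params=params,
        prescription=FlowPrescription(),
        # dx sized to the shortest post-edit piece (0.6 cm stenotic throat
        # remainders) while keeping >= 3 gridpoints everywhere
        config=SimulationConfig(dx=0.3),
        graft_segments=graft_segments,
        edits={
            "stenotic": list(stenoses),
            "separate": list(stenoses) + separate_grafts,
            "composite": list(stenoses) + composite_grafts,
        },
    )
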