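"""Clinical outputs from a stored solution cycle.

Transit-time-flowmetry style graft indices, each evaluated at a chosen
gridpoint of a graft segment (default the distal end, next to the
anastomosis, where intraoperative probes are recommended):

    MGF  mean graft flow, the plain mean of the stored samples (ml/min);
         > 15 ml/min indicates a satisfactory graft
    PI   pulsatility index (Qmax - Qmin)/Qmean; < 5 acceptable, < 3 ideal
    BF   backward-flow percentage, the negative area under the flow curve
         as a share of the total unsigned area; >= 3% suggests
         competitive flow
    DF   diastolic filling percentage, diastolic / total flow integral

Stenosis severity is graded with the instantaneous wave-free ratio
(iFR): the ratio of the mean distal to mean proximal pressure across the
stenosis during the diastolic wave-free window, the last 75% (by
duration) of diastole.  Regional myocardial perfusion sums outlet-end
mean flows per coronary territory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetworkTopology
from .solver import SolutionStore
from .units import ml_min

__all__ = [
    "CardiacPhaseMap",
    "GraftReport",
    "mean_flow",
    "pulsatility_index",
    "backflow_fraction",
    "diastolic_fraction",
    "ifr",
    "territory_perfusion",
    "graft_report",
    "MGF_THRESHOLD",
    "PI_THRESHOLD",
    "BF_THRESHOLD",
]

MGF_THRESHOLD = 15.0  # ml/min, minimum satisfactory mean graft flow
PI_THRESHOLD = 5.0  # maximum acceptable pulsatility index
BF_THRESHOLD = 3.0  # %, backward flow at/above this suggests competitive flow


@dataclass(frozen=True)
class CardiacPhaseMap:
    """Partition of the stored period into systole and diastole.

    Systole runs from the waveform foot (``t_foot``, the cycle minimum of
    the inlet pressure) to the dicrotic notch ``t_notch``; diastole covers
    the rest of the period.  The diastolic wave-free window is the last
    75% of diastole by duration.
    """

    period: float
    t_notch: float
    t_foot: float = 0.0
    wave_free_fraction: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_foot < self.t_notch < self.t_foot + self.period:
            raise ValueError("need t_foot < t_notch within one period")
        if not 0.0 < self.wave_free_fraction <= 1.0:
            raise ValueError("wave-free fraction must lie in (0, 1]")

    @property
    def diastole_duration(self) -> float:
        return self.period - (self.t_notch - self.t_foot)

    def in_systole(self, t) -> np.ndarray:
        tau = np.mod(np.asarray(t, dtype=float) - self.t_foot, self.period)
        return tau < (self.t_notch - self.t_foot)

    def in_diastole(self, t) -> np.ndarray:
        return ~self.in_systole(t)

    def in_wave_free(self, t) -> np.ndarray:
        """The diastolic wave-free window: last 75% of diastole."""
        tau = np.mod(np.asarray(t, dtype=float) - self.t_foot, self.period)
        sys_len = self.t_notch - self.t_foot
        start = sys_len + (1.0 - self.wave_free_fraction) * self.diastole_duration
        return tau >= start


def _site_samples(store: SolutionStore, segment: str, site: int) -> np.ndarray:
    try:
        seg = store.segments[segment]
    except KeyError:
        raise KeyError(f"segment {segment!r} not in solution store") from None
    n = seg.q.shape[1]
    if not -n <= site < n:
        raise IndexError(f"site {site} out of range for {segment!r} ({n} gridpoints)")
    return seg.q[:, site]


def mean_flow(store: SolutionStore, segment: str, site: int = -1) -> float:
    """Mean of the stored flow samples at a gridpoint, in ml/min."""
    return ml_min(float(np.mean(_site_samples(store, segment, site))))


def pulsatility_index(store: SolutionStore, segment: str, site: int = -1) -> float:
    """(Qmax - Qmin)/Qmean over the stored cycle; NaN (with a warning) for
    zero-mean flow."""
    q = _site_samples(store, segment, site)
    qbar = float(np.mean(q))
    if abs(qbar) <= 1e-12 * max(float(np.max(np.abs(q))), 1e-300):
        warnings.warn(f"PI undefined for zero-mean flow in {segment!r}")
        return float("nan")
    return float((q.max() - q.min()) / qbar)


def backflow_fraction(store: SolutionStore, segment: str, site: int = -1) -> float:
    """Percentage of reverse flow: negative area under the flow curve as a
    share of total unsigned area (trapezoid on the uniform samples)."""
    q = _site_samples(store, segment, site)
    total = float(np.sum(np.abs(q)))
    if total == 0.0:
        warnings.warn(f"backflow undefined for identically zero flow in {segment!r}")
        return 0.0
    negative = float(np.sum(np.abs(np.minimum(q, 0.0))))
    return 100.0 * negative / total


def diastolic_fraction(store: SolutionStore, segment: str,
                       phases: CardiacPhaseMap, site: int = -1) -> float:
    """Diastolic flow integral as a percentage of the whole-cycle integral."""
    q = _site_samples(store, segment, site)
    mask = phases.in_diastole(store.times)
    total = float(np.sum(q))
    if total <= 0.0:
        warnings.warn(f"diastolic fraction undefined for non-positive total "
                      f"flow in {segment!r}")
        return float("nan")
    return 100.0 * float(np.sum(q[mask])) / total


def ifr(store: SolutionStore, host: str, phases: CardiacPhaseMap,
        proximal: str | None = None, distal: str | None = None) -> float:
    """Instantaneous wave-free ratio across the stenosis inserted in
    ``host``: mean P at the start of the distal segment over mean P at the
    end of the proximal segment, both averaged over the diastolic
    wave-free window.

    By default the segments are <host>_psten / <host>_dsten; pass
    ``proximal``/``distal`` explicitly when a later graft edit has
    re-split one of them (the stenosis junction's own ports are
    authoritative).
    """
    pname = proximal or f"{host}_psten"
    dname = distal or f"{host}_dsten"
    if pname not in store.segments or dname not in store.segments:
        raise KeyError(
            f"no stenosis around {host!r}: segments {pname!r}/{dname!r} missing")
    mask = phases.in_wave_free(store.times)
    p_prox = float(np.mean(store.segments[pname].p[mask, -1]))
    p_dist = float(np.mean(store.segments[dname].p[mask, 0]))
    return p_dist / p_prox


def territory_perfusion(store: SolutionStore, topology: NetworkTopology,
                        ) -> dict[str, float]:
    """Mean outlet-end flow summed per coronary territory, plus 'total'
    (ml/min)."""
    sums: dict[str, float] = {}
    for name in topology.terminals:
        seg = topology.segments[name]
        if seg.territory is None:
            if seg.outlet_class != "systemic":
                raise KeyError(
                    f"coronary outlet {name!r} has no territory assignment")
            continue
        sums[seg.territory] = sums.get(seg.territory, 0.0) + mean_flow(
            store, name, site=-1)
    sums["total"] = sum(v for k, v in sums.items() if k != "total")
    return sums


@dataclass
class GraftReport:
    """TTFM-style metrics for one graft measurement site."""

    graft: str
    site: int
    mgf: float
    pi: float
    bf: float
    df: float
    flags: dict[str, bool] = field(default_factory=dict)

    @classmethod
    def evaluate(cls, store: SolutionStore, graft: str,
                 phases: CardiacPhaseMap, site: int = -1) -> "GraftReport":
        mgf = mean_flow(store, graft, site)
        pi = pulsatility_index(store, graft, site)
        bf = backflow_fraction(store, graft, site)
        df = diastolic_fraction(store, graft, phases, site)
        flags = {
            "mgf_ok": mgf > MGF_THRESHOLD,
            "pi_ok": pi < PI_THRESHOLD,
            "bf_ok": bf < BF_THRESHOLD,
        }
        return cls(graft=graft, site=site, mgf=mgf, pi=pi, bf=bf, df=df,
                   flags=flags)


def graft_report(store: SolutionStore, grafts: dict[str, str],
                 phases: CardiacPhaseMap, site: int = -1) -> pd.DataFrame:
    """Tabulate MGF/PI/BF/DF for named grafts.

    ``grafts`` maps a display label (e.g. 'LIMA to LAD') to the graft
    segment carrying the flow at the measurement site; ``site`` defaults
    to the distal (anastomosis) end.
    """
    rows = []
    for label, segment in grafts.items():
        rep = GraftReport.evaluate(store, segment, phases, site)
        rows.append({
            "graft": label, "segment": segment,
            "MGF_ml_min": rep.mgf, "PI": rep.pi, "BF_pct": rep.bf,
            "DF_pct": rep.df,
            "MGF_ok": rep.flags["mgf_ok"], "PI_ok": rep.flags["pi_ok"],
            "BF_ok": rep.flags["bf_ok"],
        })
    return pd.DataFrame(rows)
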