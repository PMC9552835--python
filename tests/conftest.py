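"""Shared fixtures.

Full network runs are expensive, so the pulsatile solutions of the toy
scenarios are computed once per session and shared across the metric,
conservation and closure tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import graftflow as gf
from graftflow.model import CoronarySimulation


@pytest.fixture(scope="session")
def toy():
    return gf.make_toy_network(seed=0)


@pytest.fixture(scope="session")
def base_results(toy):
    """Pulsatile solution of the disease-free toy network."""
    sim = CoronarySimulation(
        base=toy.base, inlet=toy.inlet, lv_external=toy.lv_external,
        prescription=toy.prescription, config=toy.config)
    return sim.run(check_drift=True)


@pytest.fixture(scope="session")
def separate_results(toy):
    """Pulsatile solution of the stenosed + separately grafted network."""
    sim = CoronarySimulation(
        base=toy.base, inlet=toy.inlet, lv_external=toy.lv_external,
        edits=list(toy.edits["separate"]),
        prescription=toy.prescription, config=toy.config)
    return sim.run(check_drift=True)


def single_vessel_network(radius=0.15, length=4.0, law="coronary",
                          outlet_class="LV", territory="LAD"):
    """One coronary-like vessel with a Windkessel outlet."""
    seg = gf.VesselSegment("COR", length, radius, law,
                           outlet_class=outlet_class, territory=territory)
    topo = gf.NetworkTopology({"COR": seg}, [])
    topo.validate()
    return topo


@pytest.fixture(scope="session")
def fluid():
    return gf.FluidProperties()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
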