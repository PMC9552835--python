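"""Network model: loading, validation, editing operations."""

import math

import pytest

import graftflow as gf
from graftflow.network import (GeometryError, Junction, LoadError,
                               NetworkTopology, TopologyError, VesselSegment)
from graftflow.wall import FluidProperties

# Typical systemic-branch dimensions used generically (radius, length in cm)
AORTIC_BRANCH_TABLE = [
    ("AO1", 1.47, 0.5), ("AO2", 1.47, 0.5), ("AA", 1.47, 3.0),
    ("INN", 0.62, 3.0), ("ARCH1", 1.12, 2.0), ("RCC", 0.4, 3.0),
    ("RSCA1", 0.48, 3.0), ("RVA", 0.2, 13.5), ("RSCA2", 0.47, 0.75),
    ("RIMA", 0.14, 18.2), ("RSCA3", 0.45, 2.5), ("LCC", 0.37, 3.0),
    ("ARCH2", 1.07, 3.9), ("DA", 0.999, 5.2), ("LSCA1", 0.423, 3.0),
    ("LVA", 0.2, 13.5), ("LSCA2", 0.407, 0.75), ("LIMA", 0.13, 18.2),
    ("LSCA3", 0.38, 2.5),
]


def _write_chain(tmp_path, rows, connector_chain=True):
    seg_file = tmp_path / "segments.csv"
    rel_file = tmp_path / "relations.cfg"
    lines = ["name,length_cm,radius_cm,wall_law,outlet_class,territory,flow_pct"]
    for i, (name, radius, length) in enumerate(rows):
        law = "coronary" if radius < 0.3 else "large_systemic"
        # the chain's far end is its only terminal and needs an outlet class
        outlet = "systemic" if (connector_chain and i == len(rows) - 1
                                or not connector_chain) else ""
        pct = "100" if outlet else ""
        lines.append(f"{name},{length},{radius},{law},{outlet},,{pct}")
    seg_file.write_text("\n".join(lines) + "\n")
    rels = []
    if connector_chain:
        names = [r[0] for r in rows]
        rels = [f"connector: {a} -> {b}" for a, b in zip(names, names[1:])]
    rel_file.write_text("\n".join(rels) + "\n")
    return seg_file, rel_file


class TestLoad:
    def test_aortic_branch_table_linear_chain(self, tmp_path):
        """19 generic aortic-branch segments in a connector chain load and
        keep their printed dimensions (LIMA 0.13 cm radius, 18.2 cm long)."""
        seg_file, rel_file = _write_chain(tmp_path, AORTIC_BRANCH_TABLE)
        topo, report = gf.load_network(seg_file, rel_file)
        assert report["n_segments"] == 19
        assert report["n_junctions"] == 18
        lima = topo.segments["LIMA"]
        assert lima.radius == pytest.approx(0.13)
        assert lima.length == pytest.approx(18.2)
        assert topo.root == "AO1"

    def test_single_segment_degenerate_network(self, tmp_path):
        seg_file, rel_file = _write_chain(
            tmp_path, [("AO1", 1.47, 0.5)], connector_chain=False)
        topo, report = gf.load_network(seg_file, rel_file)
        assert report == {"n_segments": 1, "n_junctions": 0,
                          "junctions_by_type": {}, "root": "AO1",
                          "n_outlets": 1}

    def test_missing_segment_reference_names_it(self, tmp_path):
        seg_file, rel_file = _write_chain(tmp_path, AORTIC_BRANCH_TABLE[:3])
        rel_file.write_text("bifurcation: AO1 -> AO2, LAD9\n")
        with pytest.raises(LoadError, match="LAD9"):
            gf.load_network(seg_file, rel_file)

    def test_cycle_rejected(self, tmp_path):
        seg_file, rel_file = _write_chain(tmp_path, AORTIC_BRANCH_TABLE[:2])
        rel_file.write_text("connector: AO1 -> AO2\nconnector: AO2 -> AO1\n")
        with pytest.raises(TopologyError):
            gf.load_network(seg_file, rel_file)

    def test_unsupported_junction_arity_rejected(self, tmp_path):
        seg_file, rel_file = _write_chain(tmp_path, AORTIC_BRANCH_TABLE[:4])
        rel_file.write_text("bifurcation: AO1 -> AO2, AA, INN\n")
        with pytest.raises(TopologyError, match="bifurcation"):
            gf.load_network(seg_file, rel_file)

    def test_round_trip_preserves_geometry(self, tmp_path, toy):
        """write -> load reproduces names, lengths and radii to full
        precision, for every scenario including stenosed/grafted ones."""
        for scenario in ("base", "stenotic", "separate", "composite"):
            topo = toy.topology(scenario)
            gf.write_network(topo, tmp_path / "s.csv", tmp_path / "r.cfg")
            back, _ = gf.load_network(tmp_path / "s.csv", tmp_path / "r.cfg")
            assert set(back.segments) == set(topo.segments)
            for name, seg in topo.segments.items():
                assert back.segments[name].length == seg.length
                assert back.segments[name].radius == seg.radius
                assert back.segments[name].wall_law == seg.wall_law
            assert gf.count_elements(back) == gf.count_elements(topo)


class TestSegment:
    def test_unstressed_area_definition(self):
        seg = VesselSegment("X", 2.0, 0.3)
        assert seg.area0 == pytest.approx(math.pi * 0.09, rel=1e-15)

    def test_rejects_bad_geometry(self):
        with pytest.raises(ValueError):
            VesselSegment("X", -1.0, 0.3)
        with pytest.raises(ValueError):
            VesselSegment("X", 1.0, 0.0)


class TestStenosisEditing:
    def test_split_conserves_length_and_renames(self, toy):
        """1.6 cm stenosis 0.35 cm along a 2.3 cm vessel leaves a 0.35 cm
        proximal and a 0.35 cm distal piece around the throat."""
        seg = VesselSegment("LAD_1", 2.3, 0.15, "coronary",
                            outlet_class="LV", territory="LAD")
        topo = NetworkTopology({"LAD_1": seg}, [])
        spec = gf.StenosisSpec(host="LAD_1", position=0.35, length=1.6,
                               percent=90.0)
        edited = gf.insert_stenosis(topo, spec)
        assert edited.segments["LAD_1_psten"].length == pytest.approx(0.35)
        assert edited.segments["LAD_1_dsten"].length == pytest.approx(0.35)
        total = (edited.segments["LAD_1_psten"].length + spec.length
                 + edited.segments["LAD_1_dsten"].length)
        assert total == pytest.approx(seg.length)
        (j,) = edited.junctions
        assert j.kind == "stenosis"
        assert j.parents == ["LAD_1_psten"] and j.children == ["LAD_1_dsten"]

    def test_zero_percent_has_no_viscous_or_turbulent_coefficient(self):
        seg = VesselSegment("V", 3.0, 0.15)
        spec = gf.StenosisSpec("V", 1.0, 0.5, 0.0).derive(seg, FluidProperties())
        assert spec.kv == 0.0
        assert spec.av == 0.0
        assert spec.at == 0.0

    def test_ninety_percent_area_ratio_is_ten(self):
        seg = VesselSegment("V", 3.0, 0.15)
        spec = gf.StenosisSpec("V", 1.0, 0.5, 90.0).derive(seg, FluidProperties())
        assert spec.a0 / spec.a_s == pytest.approx(10.0, rel=1e-12)

    def test_oversized_stenosis_rejected(self):
        seg = VesselSegment("V", 2.0, 0.15)
        topo = NetworkTopology({"V": seg}, [])
        with pytest.raises(GeometryError):
            gf.insert_stenosis(topo, gf.StenosisSpec("V", 0.5, 1.6, 50.0))

    def test_double_split_at_same_site_rejected(self, toy):
        spec = toy.stenoses[0]
        with pytest.raises((GeometryError, gf.network.LoadError,
                            KeyError, ValueError)):
            gf.insert_stenosis(toy.stenotic, spec)


class TestGraftEditing:
    def test_in_situ_creates_reverse_bifurcation(self, toy):
        edited = gf.insert_graft(toy.base, gf.GraftSpec(
            kind="in_situ", source="LIMA", target="LAD2", position=2.0))
        rev = [j for j in edited.junctions if j.kind == "reverse_bifurcation"]
        assert len(rev) == 1
        assert set(rev[0].parents) == {"LAD2_pgraf", "LIMA"}
        assert rev[0].children == ["LAD2_dgraf"]
        # conduit re-routing removes its old terminal outlet
        assert edited.segments["LIMA"].outlet_class is None
        # host centreline length conserved
        assert (edited.segments["LAD2_pgraf"].length
                + edited.segments["LAD2_dgraf"].length
                ) == pytest.approx(toy.base.segments["LAD2"].length)

    def test_free_aortic_graft_splits_ascending_aorta(self, toy):
        edited = gf.insert_graft(toy.base, gf.GraftSpec(
            kind="free_aortic", source="AA", source_position=1.0,
            name="RA", radius=0.17, length=6.0, target="PDA", position=1.5))
        assert "AA1" in edited.segments and "AA2" in edited.segments
        takeoff = [j for j in edited.junctions
                   if j.kind == "bifurcation" and "RA" in j.children]
        assert takeoff and takeoff[0].parents == ["AA1"]
        assert set(takeoff[0].children) == {"AA2", "RA"}

    def test_sequential_graft_creates_cross_junction(self, toy):
        edited = gf.insert_graft(toy.base, gf.GraftSpec(
            kind="in_situ", source="RIMA", target="OM1", position=1.0))
        # re-use RIMA as the entering limb of a second, sequential target
        edited = gf.insert_graft(toy.stenotic, gf.GraftSpec(
            kind="sequential", source="RIMA", target="OM1_dsten", position=0.8,
            name="RIMA_ext", radius=0.13, length=4.0))
        cross = [j for j in edited.junctions if j.kind == "cross_junction"]
        assert len(cross) == 1
        assert set(cross[0].parents) == {"OM1_dsten_pgraf", "RIMA"}
        assert set(cross[0].children) == {"OM1_dsten_dgraf", "RIMA_ext"}

    def test_split_at_segment_end_rejected(self, toy):
        with pytest.raises(GeometryError):
            gf.insert_graft(toy.base, gf.GraftSpec(
                kind="in_situ", source="LIMA", target="LAD2", position=0.0))

    def test_editing_preserves_validity(self, toy):
        for scenario in ("stenotic", "separate", "composite"):
            report = toy.topology(scenario).validate()
            assert report["n_segments"] >= 20

    def test_all_junction_kinds_exercised_across_scenarios(self, toy):
        kinds = set()
        for scenario in ("base", "stenotic", "separate", "composite"):
            _, by_kind = gf.count_elements(toy.topology(scenario))
            kinds |= set(by_kind)
        assert kinds == set(Junction.__dataclass_fields__ and
                            gf.network.JUNCTION_ARITY)


class TestScenarioConfig:
    def test_round_trip_reproduces_topology(self, toy, tmp_path):
        """Writing the edit list and replaying it from YAML rebuilds the
        same grafted topology."""
        from graftflow.network import load_scenario, write_scenario

        for scenario in ("stenotic", "separate", "composite"):
            path = tmp_path / f"{scenario}.yaml"
            write_scenario(toy.edits[scenario], path)
            topo = toy.base
            for edit in load_scenario(path):
                if isinstance(edit, gf.StenosisSpec):
                    topo = gf.insert_stenosis(topo, edit)
                else:
                    topo = gf.insert_graft(topo, edit)
            assert gf.count_elements(topo) == gf.count_elements(
                toy.topology(scenario))
            assert set(topo.segments) == set(toy.topology(scenario).segments)

    def test_missing_key_raises_load_error(self, tmp_path):
        from graftflow.network import load_scenario

        path = tmp_path / "bad.yaml"
        path.write_text("stenoses:\n  - {segment: LAD1, percent: 90}\n")
        with pytest.raises(LoadError, match="missing key"):
            load_scenario(path)


class TestCounts:
    def test_single_segment(self):
        topo = NetworkTopology({"V": VesselSegment("V", 1.0, 0.5)}, [])
        assert gf.count_elements(topo) == (1, {})

    def test_counts_match_validation_report(self, toy):
        n, by_kind = gf.count_elements(toy.separate)
        report = toy.separate.validate()
        assert n == report["n_segments"]
        assert by_kind == report["junctions_by_type"]
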