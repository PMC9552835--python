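"""Vessel-network domain model: segments, junctions, topology and editing.

A coronary (or systemic) network is a directed, rooted collection of
constant-radius 1D vessel segments joined at typed junctions.  Taper is
expressed step-wise: every segment has a single unstressed radius and
diameter changes happen only across junctions.  Terminal segments couple
to three-element Windkessel outlets; the single root segment receives the
prescribed inlet pressure.

Two plain-text files describe a network: a comma-delimited segment table
(name, length, radius, wall-law class, outlet class, territory, systemic
flow percentage) and a relations config with one junction per line,

    bifurcation: AO1 -> LMCA, AA

Scenario edits — lumped-parameter stenoses and bypass grafts — rewrite
the topology by splitting host segments (``_psten``/``_dsten`` around a
stenosis, ``_pgraf``/``_dgraf`` around a graft anastomosis) and inserting
the junction kind the surgical construct implies: an end-to-side graft is
a reverse bifurcation, a Y take-off a normal bifurcation, a sequential
(side-to-side) graft a cross-junction and an I-extension a connector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from .wall import WALL_LAWS, WallLaw

__all__ = [
    "LoadError",
    "TopologyError",
    "GeometryError",
    "VesselSegment",
    "StenosisSpec",
    "GraftSpec",
    "Junction",
    "JUNCTION_ARITY",
    "NetworkTopology",
    "load_network",
    "write_network",
    "insert_stenosis",
    "insert_graft",
    "count_elements",
    "load_scenario",
    "write_scenario",
]


class LoadError(ValueError):
    """Malformed or inconsistent network input files."""


class TopologyError(ValueError):
    """Structurally invalid network (root/reachability/arity violations)."""


class GeometryError(ValueError):
    """Scenario edit that does not fit the host geometry."""


#: (n_parents, n_children) per junction kind
JUNCTION_ARITY: dict[str, tuple[int, int]] = {
    "bifurcation": (1, 2),
    "trifurcation": (1, 3),
    "stenosis": (1, 1),
    "reverse_bifurcation": (2, 1),
    "cross_junction": (2, 2),
    "connector": (1, 1),
}

PEXT_CLASSES = ("LV", "RV", "septal", "systemic")
TERRITORIES = ("LAD", "CIRC", "RCA")


@dataclass
class VesselSegment:
    """A straight elastic tube with constant unstressed radius.

    Lengths and radii in cm.  ``outlet_class`` is set only on terminal
    segments and selects the external-pressure waveform of the attached
    Windkessel ('LV' | 'RV' | 'septal' | 'systemic'); coronary terminals
    additionally carry a ``territory`` ('LAD' | 'CIRC' | 'RCA') while
    systemic terminals carry ``flow_pct``, their prescribed share of
    cardiac output in percent.
    """

    name: str
    length: float
    radius: float
    wall_law: str = "coronary"
    outlet_class: str | None = None
    territory: str | None = None
    flow_pct: float | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment {self.name!r}: length must be positive")
        if self.radius <= 0:
            raise ValueError(f"segment {self.name!r}: radius must be positive")
        if self.wall_law not in WALL_LAWS:
            raise ValueError(
                f"segment {self.name!r}: unknown wall law {self.wall_law!r}"
            )
        if self.outlet_class is not None and self.outlet_class not in PEXT_CLASSES:
            raise ValueError(
                f"segment {self.name!r}: unknown outlet class {self.outlet_class!r}"
            )
        if self.territory is not None and self.territory not in TERRITORIES:
            raise ValueError(
                f"segment {self.name!r}: unknown territory {self.territory!r}"
            )

    @property
    def law(self) -> WallLaw:
        return WALL_LAWS[self.wall_law]

    @property
    def alpha(self) -> float:
        return self.law.alpha

    @property
    def area0(self) -> float:
        """Unstressed cross-sectional area pi R0^2, cm^2."""
        return math.pi * self.radius**2

    def split(self, position: float, proximal_name: str, distal_name: str,
              gap: float = 0.0) -> tuple["VesselSegment", "VesselSegment"]:
        """Split at ``position`` cm from the proximal end, optionally leaving
        a ``gap`` (e.g. a stenosis throat) between the two pieces.

        The distal piece inherits outlet/territory annotations; the proximal
        piece keeps none (it now ends at a junction).
        """
        if not 0.0 < position < self.length - gap:
            raise GeometryError(
                f"cannot split {self.name!r} (L={self.length} cm) at "
                f"{position} cm with a {gap} cm gap"
            )
        prox = VesselSegment(proximal_name, position, self.radius, self.wall_law)
        dist = VesselSegment(
            distal_name, self.length - position - gap, self.radius, self.wall_law,
            outlet_class=self.outlet_class, territory=self.territory,
            flow_pct=self.flow_pct,
        )
        return prox, dist


@dataclass
class StenosisSpec:
    """A lumped-parameter stenosis: a percent-diameter narrowing of
    length ``length`` starting ``position`` cm along ``host``.

    The pressure drop across the throat is

        dP = av Q + at Q|Q| + au dQ/dt

    with the viscous, turbulent and inertial coefficients derived from
    the host geometry (``derive``):

        av = mu Kv / (2 pi R0^3),   Kv = (4a/(a-1)) (La/R0) (A0/As - 1)^2
        at = rho Kt / (2 A0^2) (A0/As - 1)^2,   Kt = 1.52
        au = Ku Lu,  Ku = 1.2,  Lu = rho Ls / (pi Rs^2)

    where La = 0.83 Ls + 3.28 Rs and A0/As = 100/(100 - %stenosis).
    """

    host: str
    position: float
    length: float
    percent: float
    kt: float = 1.52
    ku: float = 1.2
    # derived (filled by derive()):
    a0: float = 0.0
    a_s: float = 0.0
    r_s: float = 0.0
    kv: float = 0.0
    la: float = 0.0
    lu: float = 0.0
    av: float = 0.0
    at: float = 0.0
    au: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent < 100.0:
            raise ValueError(f"percent stenosis must lie in [0, 100), got {self.percent}")
        if self.length <= 0 or self.position < 0:
            raise ValueError("stenosis length must be positive and position non-negative")

    def derive(self, host: VesselSegment, fluid, alpha: float = 1.1) -> "StenosisSpec":
        """Populate the derived throat geometry and dP coefficients from the
        host segment (A0-bar is the mean of the proximal/distal unstressed
        areas, which coincide for a constant-radius host)."""
        a0 = host.area0
        r0 = host.radius
        area_ratio = 100.0 / (100.0 - self.percent)  # A0 / As
        a_s = a0 / area_ratio
        r_s = math.sqrt(a_s / math.pi)
        la = 0.83 * self.length + 3.28 * r_s
        kv = (4.0 * alpha / (alpha - 1.0)) * (la / r0) * (area_ratio - 1.0) ** 2
        lu = fluid.rho * self.length / (math.pi * r_s**2)
        av = fluid.mu * kv / (2.0 * math.pi * r0**3)
        at = fluid.rho * self.kt / (2.0 * a0**2) * (area_ratio - 1.0) ** 2
        au = self.ku * lu
        return replace(self, a0=a0, a_s=a_s, r_s=r_s, kv=kv, la=la, lu=lu,
                       av=av, at=at, au=au)

    def pressure_drop(self, q: float, dq_dt: float = 0.0) -> float:
        """dP across the throat in dyn/cm^2 for throat flow q (cm^3/s)."""
        return self.av * q + self.at * q * abs(q) + self.au * dq_dt


@dataclass
class GraftSpec:
    """A bypass-graft edit.

    kinds:
      in_situ     — an existing conduit segment (e.g. LIMA) is detached
                    from its terminal outlet and anastomosed end-to-side
                    onto ``target`` (reverse bifurcation).
      free_aortic — a new conduit (``name``/``radius``/``length``) takes
                    off the ``source`` aorta segment at ``source_position``
                    (the aorta is split, creating a take-off bifurcation)
                    and lands end-to-side on ``target``.
      y_composite — a new conduit branches off an existing graft conduit
                    ``source`` at ``source_position`` (Y bifurcation) and
                    lands end-to-side on ``target``.
      sequential  — an existing conduit ``source`` passes side-to-side
                    through ``target`` (cross-junction) and continues as a
                    new exiting limb named ``name``; the limb's own distal
                    anastomosis is a separate (in_situ-style) spec or left
                    to a later edit.
      i_extension — a new conduit ``name`` is sewn end-to-end (connector)
                    onto the existing conduit ``source``.
    """

    kind: str
    target: str | None = None
    position: float | None = None  # cm along target, from its proximal end
    source: str | None = None  # existing conduit / aorta segment
    source_position: float | None = None
    name: str | None = None  # new conduit segment name
    radius: float | None = None
    length: float | None = None
    wall_law: str = "coronary"

    KINDS = ("in_situ", "free_aortic", "y_composite", "sequential", "i_extension")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown graft kind {self.kind!r}")


@dataclass
class Junction:
    """A typed coupling of parent segment ends (each at its xM) to child
    segment starts (each at its x0)."""

    kind: str
    parents: list[str]
    children: list[str]
    stenosis: StenosisSpec | None = None

    def __post_init__(self) -> None:
        if self.kind not in JUNCTION_ARITY:
            raise TopologyError(f"unsupported junction kind {self.kind!r}")
        ni, nj = JUNCTION_ARITY[self.kind]
        if (len(self.parents), len(self.children)) != (ni, nj):
            raise TopologyError(
                f"{self.kind} requires {ni} parent(s) and {nj} child(ren), got "
                f"{len(self.parents)}/{len(self.children)}"
            )
        if self.kind == "stenosis" and self.stenosis is None:
            raise TopologyError("stenosis junction requires a StenosisSpec")

    @property
    def ports(self) -> list[str]:
        return list(self.parents) + list(self.children)


@dataclass
class NetworkTopology:
    """Directed rooted network of segments and junctions."""

    segments: dict[str, VesselSegment]
    junctions: list[Junction] = field(default_factory=list)

    # ------------------------------------------------------------------ roots
    @property
    def root(self) -> str:
        roots = self.find_roots()
        if len(roots) != 1:
            raise TopologyError(f"network must have exactly one root, found {sorted(roots)}")
        return next(iter(roots))

    def find_roots(self) -> set[str]:
        children = {c for j in self.junctions for c in j.children}
        return set(self.segments) - children

    @property
    def terminals(self) -> list[str]:
        """Segments whose distal end feeds no junction (outlet candidates),
        in insertion order."""
        parents = {p for j in self.junctions for p in j.parents}
        return [s for s in self.segments if s not in parents]

    def parents_of(self, name: str) -> Junction | None:
        """The junction (if any) whose children include ``name``."""
        for j in self.junctions:
            if name in j.children:
                return j
        return None

    def children_of(self, name: str) -> Junction | None:
        """The junction (if any) whose parents include ``name``."""
        for j in self.junctions:
            if name in j.parents:
                return j
        return None

    # ------------------------------------------------------------- validation
    def validate(self, require_outlet_classes: bool = True) -> dict:
        """Check structural invariants; return a validation report.

        ``require_outlet_classes=False`` skips the terminal-annotation
        check, for mid-edit topologies whose conduits are not yet
        attached."""
        for j in self.junctions:
            for port in j.ports:
                if port not in self.segments:
                    raise LoadError(
                        f"junction {j.kind} references unknown segment {port!r}"
                    )
        roots = self.find_roots()
        if len(roots) != 1:
            raise TopologyError(
                f"network must have exactly one root segment, found {sorted(roots)}"
            )
        # each segment's distal end in at most one parent role,
        # proximal end in at most one child role
        parent_seen: set[str] = set()
        child_seen: set[str] = set()
        for j in self.junctions:
            for p in j.parents:
                if p in parent_seen:
                    raise TopologyError(f"segment {p!r} feeds more than one junction")
                parent_seen.add(p)
            for c in j.children:
                if c in child_seen:
                    raise TopologyError(f"segment {c!r} is fed by more than one junction")
                child_seen.add(c)
        # reachability: every segment must be connected to the root through
        # the undirected junction graph (graft limbs join their reverse
        # bifurcation as co-parents, so directed descent is not enough)
        root = next(iter(roots))
        undirected: dict[str, set[str]] = {s: set() for s in self.segments}
        for j in self.junctions:
            for a in j.ports:
                for b in j.ports:
                    if a != b:
                        undirected[a].add(b)
        seen = {root}
        stack = [root]
        while stack:
            s = stack.pop()
            for t in undirected[s]:
                if t not in seen:
                    seen.add(t)
                    stack.append(t)
        disconnected = set(self.segments) - seen
        if disconnected:
            raise TopologyError(
                f"segments not reachable from root {root!r}: {sorted(disconnected)}"
            )
        # cycle check: child may not be an ancestor of any of its parents
        self._check_acyclic()
        # terminal segments must carry an outlet class
        for t in self.terminals if require_outlet_classes else []:
            if self.segments[t].outlet_class is None:
                raise TopologyError(
                    f"terminal segment {t!r} has no outlet (external-pressure) class"
                )
        counts: dict[str, int] = {}
        for j in self.junctions:
            counts[j.kind] = counts.get(j.kind, 0) + 1
        return {
            "n_segments": len(self.segments),
            "n_junctions": len(self.junctions),
            "junctions_by_type": counts,
            "root": root,
            "n_outlets": len(self.terminals),
        }

    def _check_acyclic(self) -> None:
        # DAG over segments: edge parent -> child for every junction
        adjacency: dict[str, list[str]] = {s: [] for s in self.segments}
        for j in self.junctions:
            for p in j.parents:
                adjacency[p].extend(j.children)
        state: dict[str, int] = {}

        def visit(node: str, stack: list[str]) -> None:
            state[node] = 1
            for nxt in adjacency[node]:
                if state.get(nxt) == 1:
                    raise TopologyError(
                        f"cycle in connectivity involving {nxt!r} (path {stack + [node]})"
                    )
                if state.get(nxt) is None:
                    visit(nxt, stack + [node])
            state[node] = 2

        for s in self.segments:
            if state.get(s) is None:
                visit(s, [])

    # ---------------------------------------------------------------- queries
    def path_to_root(self, name: str) -> list[str]:
        """Segments from the root down to (and excluding) ``name``, following
        first-parent ancestry at multi-parent junctions."""
        path: list[str] = []
        current = name
        while True:
            j = self.parents_of(current)
            if j is None:
                break
            parent = j.parents[0]
            path.append(parent)
            current = parent
        return list(reversed(path))

    def copy(self) -> "NetworkTopology":
        return NetworkTopology(
            segments={n: replace(s) for n, s in self.segments.items()},
            junctions=[
                Junction(j.kind, list(j.parents), list(j.children),
                         stenosis=replace(j.stenosis) if j.stenosis else None)
                for j in self.junctions
            ],
        )

    def _rewire(self, old: str, prox: VesselSegment, dist: VesselSegment) -> None:
        """Replace segment ``old`` with a proximal/distal pair, transferring
        the old proximal-end connection to ``prox`` and the old distal-end
        connection to ``dist``.  The caller adds the junction joining them."""
        jin = self.parents_of(old)
        jout = self.children_of(old)
        del self.segments[old]
        self.segments[prox.name] = prox
        self.segments[dist.name] = dist
        if jin is not None:
            jin.children[jin.children.index(old)] = prox.name
        if jout is not None:
            jout.parents[jout.parents.index(old)] = dist.name


# ---------------------------------------------------------------------- I/O

SEGMENT_COLUMNS = [
    "name", "length_cm", "radius_cm", "wall_law", "outlet_class",
    "territory", "flow_pct",
]


def _parse_segment_row(row: dict[str, str], line_no: int) -> VesselSegment:
    try:
        return VesselSegment(
            name=row["name"].strip(),
            length=float(row["length_cm"]),
            radius=float(row["radius_cm"]),
            wall_law=row.get("wall_law", "coronary").strip() or "coronary",
            outlet_class=(row.get("outlet_class") or "").strip() or None,
            territory=(row.get("territory") or "").strip() or None,
            flow_pct=float(row["flow_pct"]) if (row.get("flow_pct") or "").strip() else None,
        )
    except (KeyError, ValueError) as exc:
        raise LoadError(f"segment table line {line_no}: {exc}") from exc


def load_network(segment_table: str | Path, relations_config: str | Path,
                 fluid=None) -> tuple[NetworkTopology, dict]:
    """Read a segment CSV and relations config; return the validated
    topology and its validation report."""
    import csv

    from .wall import FluidProperties

    fluid = fluid or FluidProperties()
    seg_path, rel_path = Path(segment_table), Path(relations_config)
    segments: dict[str, VesselSegment] = {}
    with open(seg_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise LoadError(f"{seg_path}: missing header row with a 'name' column")
        for i, row in enumerate(reader, start=2):
            if not (row.get("name") or "").strip():
                continue
            seg = _parse_segment_row(row, i)
            if seg.name in segments:
                raise LoadError(f"duplicate segment name {seg.name!r}")
            segments[seg.name] = seg

    junctions: list[Junction] = []
    for i, raw in enumerate(rel_path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            kind_part, rest = line.split(":", 1)
            params_part = ""
            if "|" in rest:
                rest, params_part = rest.split("|", 1)
            parents_part, children_part = rest.split("->")
        except ValueError as exc:
            raise LoadError(f"{rel_path} line {i}: cannot parse {line!r}") from exc
        kind = kind_part.strip()
        parents = [p.strip() for p in parents_part.split(",") if p.strip()]
        children = [c.strip() for c in children_part.split(",") if c.strip()]
        for port in parents + children:
            if port not in segments:
                raise LoadError(
                    f"{rel_path} line {i}: junction references segment {port!r} "
                    "absent from the segment table"
                )
        sten = None
        if kind == "stenosis":
            params = dict(
                kv.split("=") for kv in params_part.split() if "=" in kv
            )
            try:
                sten = StenosisSpec(
                    host=params.get("host", parents[0]),
                    position=float(params.get("position_cm", 0.0)),
                    length=float(params["length_cm"]),
                    percent=float(params["percent"]),
                )
            except KeyError as exc:
                raise LoadError(
                    f"{rel_path} line {i}: stenosis junction missing parameter {exc}"
                ) from exc
            host_like = segments[parents[0]]
            sten = sten.derive(host_like, fluid)
        junctions.append(Junction(kind, parents, children, stenosis=sten))

    topo = NetworkTopology(segments, junctions)
    report = topo.validate()
    return topo, report


def write_network(topology: NetworkTopology, segment_table: str | Path,
                  relations_config: str | Path) -> None:
    """Write the segment CSV and relations config (full-precision floats)."""
    seg_path, rel_path = Path(segment_table), Path(relations_config)
    lines = [",".join(SEGMENT_COLUMNS)]
    for seg in topology.segments.values():
        lines.append(",".join([
            seg.name,
            repr(seg.length),
            repr(seg.radius),
            seg.wall_law,
            seg.outlet_class or "",
            seg.territory or "",
            repr(seg.flow_pct) if seg.flow_pct is not None else "",
        ]))
    seg_path.write_text("\n".join(lines) + "\n")

    rel_lines = []
    for j in topology.junctions:
        line = f"{j.kind}: {', '.join(j.parents)} -> {', '.join(j.children)}"
        if j.stenosis is not None:
            s = j.stenosis
            line += (f" | host={s.host} position_cm={s.position!r} "
                     f"length_cm={s.length!r} percent={s.percent!r}")
        rel_lines.append(line)
    rel_path.write_text("\n".join(rel_lines) + "\n")


# ------------------------------------------------------------------- editing

def insert_stenosis(topology: NetworkTopology, spec: StenosisSpec,
                    fluid=None) -> NetworkTopology:
    """Split the host segment into ``<host>_psten``/``<host>_dsten`` coupled
    by a stenosis junction whose throat spans the stenosed length."""
    from .wall import FluidProperties

    fluid = fluid or FluidProperties()
    topo = topology.copy()
    if spec.host not in topo.segments:
        raise LoadError(f"stenosis host segment {spec.host!r} not in network")
    host = topo.segments[spec.host]
    if spec.position + spec.length >= host.length:
        raise GeometryError(
            f"stenosis ({spec.position} + {spec.length} cm) does not fit inside "
            f"host {spec.host!r} of length {host.length} cm"
        )
    pname, dname = f"{spec.host}_psten", f"{spec.host}_dsten"
    if pname in topo.segments or dname in topo.segments:
        raise GeometryError(f"host {spec.host!r} already split at this site")
    prox, dist = host.split(spec.position, pname, dname, gap=spec.length)
    derived = spec.derive(host, fluid)
    topo._rewire(spec.host, prox, dist)
    topo.junctions.append(
        Junction("stenosis", [pname], [dname], stenosis=derived)
    )
    topo.validate(require_outlet_classes=False)
    return topo


def _split_for_graft(topo: NetworkTopology, target: str, position: float,
                     suffixes: tuple[str, str] = ("_pgraf", "_dgraf"),
                     ) -> tuple[str, str]:
    if target not in topo.segments:
        raise LoadError(f"graft target segment {target!r} not in network")
    host = topo.segments[target]
    if position is None or not 0.0 < position < host.length:
        raise GeometryError(
            f"graft anastomosis position {position} must fall strictly inside "
            f"{target!r} (length {host.length} cm)"
        )
    pname, dname = target + suffixes[0], target + suffixes[1]
    if pname in topo.segments or dname in topo.segments:
        raise GeometryError(f"target {target!r} already split at this site")
    prox, dist = host.split(position, pname, dname)
    topo._rewire(target, prox, dist)
    return pname, dname


def _detach_conduit(topo: NetworkTopology, conduit: str) -> None:
    """Remove a re-routed in-situ conduit's terminal-outlet annotation."""
    seg = topo.segments[conduit]
    if topo.children_of(conduit) is not None:
        raise GeometryError(
            f"conduit {conduit!r} already feeds a junction; cannot re-route"
        )
    seg.outlet_class = None
    seg.territory = None
    seg.flow_pct = None


def insert_graft(topology: NetworkTopology, spec: GraftSpec) -> NetworkTopology:
    """Apply one graft edit; returns the re-validated topology."""
    topo = topology.copy()

    if spec.kind == "in_situ":
        if spec.source not in topo.segments:
            raise LoadError(f"in-situ conduit {spec.source!r} not in network")
        _detach_conduit(topo, spec.source)
        pname, dname = _split_for_graft(topo, spec.target, spec.position)
        topo.junctions.append(
            Junction("reverse_bifurcation", [pname, spec.source], [dname])
        )

    elif spec.kind == "free_aortic":
        if spec.source not in topo.segments:
            raise LoadError(f"aortic source segment {spec.source!r} not in network")
        if not spec.name or not spec.radius or not spec.length:
            raise LoadError("free_aortic graft requires name, radius and length")
        # split the aorta at the take-off: AA becomes AA1 + AA2
        src = topo.segments[spec.source]
        a_name, b_name = f"{spec.source}1", f"{spec.source}2"
        if spec.source_position is None or not 0.0 < spec.source_position < src.length:
            raise GeometryError(
                f"take-off position {spec.source_position} must fall strictly "
                f"inside {spec.source!r} (length {src.length} cm)"
            )
        prox, dist = src.split(spec.source_position, a_name, b_name)
        topo._rewire(spec.source, prox, dist)
        conduit = VesselSegment(spec.name, spec.length, spec.radius, spec.wall_law)
        topo.segments[spec.name] = conduit
        topo.junctions.append(Junction("bifurcation", [a_name], [b_name, spec.name]))
        pname, dname = _split_for_graft(topo, spec.target, spec.position)
        topo.junctions.append(
            Junction("reverse_bifurcation", [pname, spec.name], [dname])
        )

    elif spec.kind == "y_composite":
        # new conduit branches off an existing conduit: Y bifurcation
        if spec.source not in topo.segments:
            raise LoadError(f"Y-composite source conduit {spec.source!r} not in network")
        if not spec.name or not spec.radius or not spec.length:
            raise LoadError("y_composite graft requires name, radius and length")
        src = topo.segments[spec.source]
        stem_name, cont_name = f"{spec.source}_Y", f"{spec.source}_cont"
        if spec.source_position is None or not 0.0 < spec.source_position < src.length:
            raise GeometryError(
                f"Y take-off position {spec.source_position} must fall strictly "
                f"inside {spec.source!r} (length {src.length} cm)"
            )
        stem, cont = src.split(spec.source_position, stem_name, cont_name)
        topo._rewire(spec.source, stem, cont)
        branch = VesselSegment(spec.name, spec.length, spec.radius, spec.wall_law)
        topo.segments[spec.name] = branch
        topo.junctions.append(
            Junction("bifurcation", [stem_name], [cont_name, spec.name])
        )
        if spec.target is not None:
            pname, dname = _split_for_graft(topo, spec.target, spec.position)
            topo.junctions.append(
                Junction("reverse_bifurcation", [pname, spec.name], [dname])
            )

    elif spec.kind == "sequential":
        # conduit passes side-to-side through target and continues as `name`
        if spec.source not in topo.segments:
            raise LoadError(f"sequential conduit {spec.source!r} not in network")
        if not spec.name or not spec.radius or not spec.length:
            raise LoadError(
                "sequential graft requires an exiting limb (name, radius, length)"
            )
        if topo.segments[spec.source].outlet_class is not None:
            _detach_conduit(topo, spec.source)
        pname, dname = _split_for_graft(topo, spec.target, spec.position)
        exiting = VesselSegment(spec.name, spec.length, spec.radius, spec.wall_law)
        topo.segments[spec.name] = exiting
        topo.junctions.append(
            Junction("cross_junction", [pname, spec.source], [dname, spec.name])
        )

    elif spec.kind == "i_extension":
        # end-to-end lengthening of an existing conduit by a new piece
        if spec.source not in topo.segments:
            raise LoadError(f"I-extension base conduit {spec.source!r} not in network")
        if not spec.name or not spec.radius or not spec.length:
            raise LoadError("i_extension requires name, radius and length")
        if topo.children_of(spec.source) is not None:
            raise GeometryError(
                f"conduit {spec.source!r} already feeds a junction; cannot extend"
            )
        if topo.segments[spec.source].outlet_class is not None:
            _detach_conduit(topo, spec.source)
        ext = VesselSegment(spec.name, spec.length, spec.radius, spec.wall_law)
        topo.segments[spec.name] = ext
        topo.junctions.append(Junction("connector", [spec.source], [spec.name]))
        if spec.target is not None:
            pname, dname = _split_for_graft(topo, spec.target, spec.position)
            topo.junctions.append(
                Junction("reverse_bifurcation", [pname, spec.name], [dname])
            )

    topo.validate(require_outlet_classes=False)
    return topo


def count_elements(topology: NetworkTopology) -> tuple[int, dict[str, int]]:
    """Exact segment count and per-kind junction counts."""
    counts: dict[str, int] = {}
    for j in topology.junctions:
        counts[j.kind] = counts.get(j.kind, 0) + 1
    return len(topology.segments), counts


# ----------------------------------------------------------------- scenarios

def load_scenario(path: str | Path) -> list:
    """Read a structured scenario config (YAML) of stenosis and graft edits.

    Layout::

        stenoses:
          - {segment: LAD1, position_cm: 0.8, length_cm: 0.8, percent: 90}
        grafts:
          - {kind: in_situ, source: LIMA, target: LAD2, position_cm: 2.0}
          - {kind: free_aortic, source: AA, source_position_cm: 1.0,
             name: RA, radius_cm: 0.17, length_cm: 6.0,
             target: PDA, position_cm: 1.5}

    Returns the edits in file order (stenoses first), ready to apply with
    ``insert_stenosis`` / ``insert_graft``.
    """
    import yaml

    doc = yaml.safe_load(Path(path).read_text()) or {}
    edits: list = []
    for s in doc.get("stenoses", []):
        try:
            edits.append(StenosisSpec(
                host=s["segment"], position=float(s["position_cm"]),
                length=float(s["length_cm"]), percent=float(s["percent"])))
        except KeyError as exc:
            raise LoadError(f"scenario stenosis entry missing key {exc}") from exc
    for g in doc.get("grafts", []):
        try:
            edits.append(GraftSpec(
                kind=g["kind"], target=g.get("target"),
                position=_opt_float(g.get("position_cm")),
                source=g.get("source"),
                source_position=_opt_float(g.get("source_position_cm")),
                name=g.get("name"), radius=_opt_float(g.get("radius_cm")),
                length=_opt_float(g.get("length_cm")),
                wall_law=g.get("wall_law", "coronary")))
        except KeyError as exc:
            raise LoadError(f"scenario graft entry missing key {exc}") from exc
    return edits


def _opt_float(value):
    return None if value is None else float(value)


def write_scenario(edits: list, path: str | Path) -> None:
    """Write stenosis/graft edits as a scenario config (YAML)."""
    import yaml

    doc: dict = {"stenoses": [], "grafts": []}
    for e in edits:
        if isinstance(e, StenosisSpec):
            doc["stenoses"].append({
                "segment": e.host, "position_cm": e.position,
                "length_cm": e.length, "percent": e.percent})
        elif isinstance(e, GraftSpec):
            doc["grafts"].append({k: v for k, v in {
                "kind": e.kind, "source": e.source,
                "source_position_cm": e.source_position,
                "name": e.name, "radius_cm": e.radius,
                "length_cm": e.length, "target": e.target,
                "position_cm": e.position, "wall_law": e.wall_law,
            }.items() if v is not None})
        else:
            raise TypeError(f"unknown edit {e!r}")
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
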