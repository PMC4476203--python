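"""Vessel-network definition, loading, validation and serialization.

The venous tree is represented as a directed multigraph of resistive
segments.  Each :class:`Vessel` is one lumped Poiseuille resistance; its
orientation (``upstream_node -> downstream_node``) encodes the physiological
drainage direction, so a positive solved flow is antegrade and a negative
one retrograde.  Geometry is stored in SI units (metres) internally; the
on-disk anatomy table uses the conventional centimetres, converted only at
the I/O boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

__all__ = [
    "Vessel",
    "Node",
    "FlowInput",
    "NetworkTopology",
    "ValidationReport",
    "AnatomyError",
    "load_anatomy_table",
    "load_config",
    "validate_topology",
    "export_graph",
    "import_graph",
    "write_anatomy_table",
    "write_config",
]

CM = 1e-2
ML_PER_S = 1e-6  # m^3/s
CENTIPOISE = 1e-3  # Pa*s

SIDES = frozenset({"left", "right", "midline"})
DISTRICTS = frozenset(
    {"intracranial", "cervical", "thoracic", "lumbar", "connective"}
)

ANATOMY_COLUMNS = [
    "id",
    "name",
    "side",
    "district",
    "length_cm",
    "diameter_cm",
    "upstream_node",
    "downstream_node",
]


class AnatomyError(ValueError):
    """Raised for malformed anatomy tables, configs or topologies."""


@dataclass(frozen=True)
class Vessel:
    """One resistive vessel segment.

    ``length`` and ``diameter`` are in metres.  Orientation follows the
    physiological drainage direction.
    """

    id: str
    name: str
    side: str
    district: str
    length: float
    diameter: float
    upstream_node: str
    downstream_node: str

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise AnatomyError(
                f"vessel {self.id!r}: length and diameter must be positive "
                f"(got L={self.length}, D={self.diameter})"
            )
        if self.upstream_node == self.downstream_node:
            raise AnatomyError(
                f"vessel {self.id!r}: upstream and downstream node coincide "
                f"({self.upstream_node!r})"
            )
        if self.side not in SIDES:
            raise AnatomyError(
                f"vessel {self.id!r}: unknown side {self.side!r}"
            )
        if self.district not in DISTRICTS:
            raise AnatomyError(
                f"vessel {self.id!r}: unknown district {self.district!r}"
            )


@dataclass(frozen=True)
class Node:
    """A junction of the network.

    Reference nodes carry a fixed zero pressure (in the bundled anatomy:
    the subclavian vein and the right atrium).
    """

    id: str
    label: str = ""
    district: str = "connective"
    is_reference: bool = False
    reference_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.is_reference and self.reference_pressure != 0.0:
            raise AnatomyError(
                f"node {self.id!r}: reference pressure must be 0 Pa"
            )


@dataclass(frozen=True)
class FlowInput:
    """A steady arterial inflow injected at a node. ``rate`` in m^3/s."""

    node_id: str
    rate: float
    label: str

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise AnatomyError(
                f"flow input {self.label!r}: rate must be >= 0"
            )


@dataclass(frozen=True)
class NetworkTopology:
    """Immutable container for the vessel graph, sources and references.

    ``viscosity`` is the blood dynamic viscosity in Pa*s (default 3 cP).
    Vessel order is preserved as loaded, giving deterministic output
    ordering everywhere downstream.
    """

    vessels: tuple[Vessel, ...]
    nodes: tuple[Node, ...]
    inputs: tuple[FlowInput, ...] = ()
    viscosity: float = 3.0 * CENTIPOISE

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise AnatomyError("viscosity must be positive")
        ids = [v.id for v in self.vessels]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AnatomyError(f"duplicate vessel ids: {dup}")
        node_ids = [n.id for n in self.nodes]
        if len(set(node_ids)) != len(node_ids):
            raise AnatomyError("duplicate node ids")

    # -- lookups -----------------------------------------------------------
    @property
    def node_map(self) -> dict[str, Node]:
        return {n.id: n for n in self.nodes}

    @property
    def vessel_map(self) -> dict[str, Vessel]:
        return {v.id: v for v in self.vessels}

    @property
    def reference_nodes(self) -> tuple[str, ...]:
        return tuple(n.id for n in self.nodes if n.is_reference)

    def vessel(self, vessel_id: str) -> Vessel:
        try:
            return self.vessel_map[vessel_id]
        except KeyError:
            raise AnatomyError(f"unknown vessel id {vessel_id!r}") from None

    def vessels_named(self, prefix: str) -> list[Vessel]:
        """All vessels whose id starts with ``prefix`` (e.g. ``'AZ'``)."""
        return [v for v in self.vessels if v.id.startswith(prefix)]

    def total_inflow(self) -> float:
        return sum(q.rate for q in self.inputs)

    # -- derived views -----------------------------------------------------
    def to_graph(self) -> nx.MultiDiGraph:
        """Directed multigraph; edge key = vessel id."""
        g = nx.MultiDiGraph(viscosity=self.viscosity)
        for n in self.nodes:
            g.add_node(
                n.id,
                label=n.label,
                district=n.district,
                is_reference=n.is_reference,
            )
        for q in self.inputs:
            g.nodes[q.node_id]["inflow_label"] = q.label
            g.nodes[q.node_id]["inflow_ml_s"] = q.rate / ML_PER_S
        for v in self.vessels:
            g.add_edge(
                v.upstream_node,
                v.downstream_node,
                key=v.id,
                name=v.name,
                side=v.side,
                district=v.district,
                length_cm=v.length / CM,
                diameter_cm=v.diameter / CM,
            )
        return g

    def with_vessels(self, vessels: Iterable[Vessel]) -> "NetworkTopology":
        return replace(self, vessels=tuple(vessels))


@dataclass
class ValidationReport:
    """Report-style validation outcome: empty ``violations`` iff valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy when valid, like a check result
        return self.is_valid

    def __str__(self) -> str:
        if self.is_valid:
            return "topology valid"
        return "topology invalid:\n" + "\n".join(
            f"  - {v}" for v in self.violations
        )


# ---------------------------------------------------------------------------
# loading


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in ANATOMY_COLUMNS if c not in df.columns]
    if missing:
        raise AnatomyError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {','.join(ANATOMY_COLUMNS)}"
        )
    return df


def load_config(path: str | Path) -> dict:
    """Read the boundary/input config (YAML: reference nodes, inflows)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise AnatomyError(f"{path}: config must be a mapping")
    for key in ("reference_nodes", "flow_inputs"):
        if key not in cfg:
            raise AnatomyError(f"{path}: config missing {key!r}")
    return cfg


def load_anatomy_table(
    path: str | Path, config: str | Path | Mapping
) -> NetworkTopology:
    """Load a vessel table (CSV, cm units) plus a boundary config.

    The CSV needs the header ``id,name,side,district,length_cm,diameter_cm,
    upstream_node,downstream_node``; ``#`` lines are provenance comments.
    The config names the zero-pressure reference nodes and the arterial
    inflows (ml/s).  Row order is preserved.
    """
    df = _read_table(path)
    cfg = load_config(config) if not isinstance(config, Mapping) else dict(config)

    vessels: list[Vessel] = []
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1 of the data (comments aside)
        try:
            length = float(row["length_cm"])
            diameter = float(row["diameter_cm"])
        except (TypeError, ValueError):
            raise AnatomyError(
                f"{path} row {rownum} (id={row['id']!r}): "
                "length_cm/diameter_cm must be numeric"
            ) from None
        try:
            vessels.append(
                Vessel(
                    id=str(row["id"]),
                    name=str(row["name"]),
                    side=str(row["side"]),
                    district=str(row["district"]),
                    length=length * CM,
                    diameter=diameter * CM,
                    upstream_node=str(row["upstream_node"]),
                    downstream_node=str(row["downstream_node"]),
                )
            )
        except AnatomyError as exc:
            raise AnatomyError(f"{path} row {rownum}: {exc}") from None

    ids = [v.id for v in vessels]
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        rows = [str(i + 2) for i, v in enumerate(vessels) if v.id in dup]
        raise AnatomyError(
            f"{path}: duplicate vessel id(s) {dup} (rows {', '.join(rows)})"
        )

    reference = set(map(str, cfg["reference_nodes"]))
    node_districts: dict[str, str] = {}
    for v in vessels:
        node_districts.setdefault(v.upstream_node, v.district)
        node_districts.setdefault(v.downstream_node, v.district)
    for ref in reference:
        if ref not in node_districts:
            raise AnatomyError(
                f"config reference node {ref!r} not present in anatomy table"
            )
    nodes = tuple(
        Node(
            id=nid,
            district=district,
            is_reference=nid in reference,
        )
        for nid, district in node_districts.items()
    )

    inputs = []
    for item in cfg["flow_inputs"]:
        inputs.append(
            FlowInput(
                node_id=str(item["node"]),
                rate=float(item["ml_per_s"]) * ML_PER_S,
                label=str(item.get("label", item["node"])),
            )
        )
    viscosity = float(cfg.get("viscosity_cP", 3.0)) * CENTIPOISE

    topo = NetworkTopology(
        vessels=tuple(vessels),
        nodes=nodes,
        inputs=tuple(inputs),
        viscosity=viscosity,
    )
    report = validate_topology(topo)
    if not report.is_valid:
        raise AnatomyError(f"{path}: {report}")
    return topo


# ---------------------------------------------------------------------------
# validation


def validate_topology(t: NetworkTopology) -> ValidationReport:
    """Check all structural invariants; returns a report, never raises.

    Beyond per-vessel geometry (already enforced at construction) this
    verifies endpoint existence, that inflows sit on existing non-reference
    nodes, and that every connected component carrying a source or an edge
    contains at least one reference node (otherwise the nodal system is
    singular: no drainage path).
    """
    rep = ValidationReport()
    node_ids = {n.id for n in t.nodes}
    for v in t.vessels:
        for endpoint in (v.upstream_node, v.downstream_node):
            if endpoint not in node_ids:
                rep.violations.append(
                    f"vessel {v.id!r} references unknown node {endpoint!r}"
                )
    for q in t.inputs:
        if q.node_id not in node_ids:
            rep.violations.append(
                f"flow input {q.label!r} references unknown node "
                f"{q.node_id!r}"
            )
        elif t.node_map[q.node_id].is_reference:
            rep.violations.append(
                f"flow input {q.label!r} injected at reference node "
                f"{q.node_id!r}"
            )
    if rep.violations:
        return rep

    g = nx.Graph()
    g.add_nodes_from(node_ids)
    g.add_edges_from((v.upstream_node, v.downstream_node) for v in t.vessels)
    refs = {n.id for n in t.nodes if n.is_reference}
    sources = {q.node_id for q in t.inputs}
    for comp in nx.connected_components(g):
        has_edge = any(
            v.upstream_node in comp for v in t.vessels
        )
        if (comp & sources or has_edge) and not comp & refs:
            member = sorted(comp)[:4]
            rep.violations.append(
                "no drainage path: component containing "
                f"{member}{'...' if len(comp) > 4 else ''} has no "
                "reference node"
            )
    return rep


# ---------------------------------------------------------------------------
# serialization


def write_anatomy_table(
    t: NetworkTopology, path: str | Path, header_comment: str | None = None
) -> None:
    """Write the vessel table back to CSV (cm units), preserving order."""
    rows = [
        {
            "id": v.id,
            "name": v.name,
            "side": v.side,
            "district": v.district,
            "length_cm": repr(v.length / CM),
            "diameter_cm": repr(v.diameter / CM),
            "upstream_node": v.upstream_node,
            "downstream_node": v.downstream_node,
        }
        for v in t.vessels
    ]
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    pd.DataFrame(rows, columns=ANATOMY_COLUMNS).to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_config(t: NetworkTopology, path: str | Path) -> None:
    cfg = {
        "reference_nodes": list(t.reference_nodes),
        "viscosity_cP": t.viscosity / CENTIPOISE,
        "flow_inputs": [
            {
                "node": q.node_id,
                "label": q.label,
                "ml_per_s": q.rate / ML_PER_S,
            }
            for q in t.inputs
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def export_graph(
    t: NetworkTopology, path: str | Path, format: str = "graphml"
) -> None:
    """Export the topology as GraphML (round-trippable) or DOT.

    GraphML keeps geometry, district and boundary attributes so
    :func:`import_graph` reproduces the topology exactly.  DOT is a
    one-way rendering format.
    """
    fmt = format.lower()
    g = t.to_graph()
    if fmt == "graphml":
        nx.write_graphml(g, str(path))
    elif fmt == "dot":
        _write_dot(g, path)
    else:
        raise AnatomyError(f"unsupported export format {format!r}")


def _dot_quote(s: str) -> str:
    return '"' + s.replace('"', r"\"") + '"'


def _write_dot(g: nx.MultiDiGraph, path: str | Path) -> None:
    lines = ["digraph venonet {"]
    for nid, attrs in g.nodes(data=True):
        shape = "doublecircle" if attrs.get("is_reference") else "circle"
        lines.append(f"  {_dot_quote(nid)} [shape={shape}];")
    for u, v, key, attrs in g.edges(keys=True, data=True):
        lbl = f"{key} D={attrs['diameter_cm']:g}cm L={attrs['length_cm']:g}cm"
        lines.append(
            f"  {_dot_quote(u)} -> {_dot_quote(v)} "
            f"[label={_dot_quote(lbl)}];"
        )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def import_graph(path: str | Path) -> NetworkTopology:
    """Rebuild a topology from a GraphML file written by :func:`export_graph`."""
    g = nx.read_graphml(str(path), force_multigraph=True)
    nodes = []
    inputs = []
    for nid, attrs in g.nodes(data=True):
        nodes.append(
            Node(
                id=str(nid),
                label=attrs.get("label", ""),
                district=attrs.get("district", "connective"),
                is_reference=bool(attrs.get("is_reference", False)),
            )
        )
        if "inflow_label" in attrs:
            inputs.append(
                FlowInput(
                    node_id=str(nid),
                    rate=float(attrs["inflow_ml_s"]) * ML_PER_S,
                    label=str(attrs["inflow_label"]),
                )
            )
    vessels = []
    for u, v, key, attrs in g.edges(keys=True, data=True):
        vessels.append(
            Vessel(
                id=str(key),
                name=attrs.get("name", str(key)),
                side=attrs.get("side", "midline"),
                district=attrs.get("district", "connective"),
                length=float(attrs["length_cm"]) * CM,
                diameter=float(attrs["diameter_cm"]) * CM,
                upstream_node=str(u),
                downstream_node=str(v),
            )
        )
    viscosity = float(g.graph.get("viscosity", 3.0 * CENTIPOISE))
    return NetworkTopology(
        vessels=tuple(vessels),
        nodes=tuple(nodes),
        inputs=tuple(inputs),
        viscosity=viscosity,
    )
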