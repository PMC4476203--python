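"""Synthetic networks with known solutions, and seeded random instances.

Every toy kind ships with an analytically derived expected solution
(series/parallel reduction, never the nodal solver), so the solver can be
checked against closed forms.  Random networks are reproducible from a
seed and always pass validation; their geometry brackets realistic venous
dimensions (D 0.05-1.5 cm, L 0.5-30 cm) without copying any particular
anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import CM, ML_PER_S, FlowInput, NetworkTopology, Node, Vessel
from .core import (
    SolveResult,
    parallel_resistance,
    poiseuille_resistance,
    series_resistance,
)

__all__ = [
    "TOY_KINDS",
    "RandomNetworkSpec",
    "make_toy",
    "make_random",
]

TOY_KINDS = ("single_edge", "series_chain", "parallel_pair", "wye", "ladder")

_MU = 3e-3


def _vessel(vid, up, down, length, diameter, district="connective"):
    return Vessel(
        id=vid,
        name=vid,
        side="midline",
        district=district,
        length=length,
        diameter=diameter,
        upstream_node=up,
        downstream_node=down,
    )


def _topology(vessels, ref_nodes, inputs, viscosity=_MU):
    node_ids = []
    for v in vessels:
        for nid in (v.upstream_node, v.downstream_node):
            if nid not in node_ids:
                node_ids.append(nid)
    nodes = tuple(
        Node(id=nid, is_reference=nid in ref_nodes) for nid in node_ids
    )
    return NetworkTopology(
        vessels=tuple(vessels),
        nodes=nodes,
        inputs=tuple(inputs),
        viscosity=viscosity,
    )


def make_toy(
    kind: str,
    flow: float = 5.0 * ML_PER_S,
    n: int = 3,
    length: float = 10 * CM,
    diameter: float = 0.5 * CM,
    diameter2: float = 0.3 * CM,
) -> tuple[NetworkTopology, SolveResult]:
    """Build a toy network plus its closed-form steady-state solution.

    Kinds: ``single_edge`` (one vessel source->reference), ``series_chain``
    (n vessels in series), ``parallel_pair`` (two branches), ``wye`` (a
    stem feeding two parallel branches) and ``ladder`` (n rail segments
    with a shunt rung to the reference at every intermediate node).
    """
    if kind not in TOY_KINDS:
        raise ValueError(f"unknown toy kind {kind!r}; choose from {TOY_KINDS}")
    q = flow
    if kind == "single_edge":
        r = poiseuille_resistance(length, diameter, _MU)
        topo = _topology(
            [_vessel("e0", "src", "ref", length, diameter)],
            {"ref"},
            [FlowInput("src", q, "Q0")],
        )
        expected = SolveResult(
            node_pressures={"src": r * q, "ref": 0.0},
            edge_flows={"e0": q},
            residual=0.0,
            total_inflow=q,
        )
        return topo, expected

    if kind == "series_chain":
        vessels = []
        names = ["src"] + [f"n{i}" for i in range(1, n)] + ["ref"]
        rs = []
        for i in range(n):
            d = diameter * (1 + 0.1 * i)  # slight taper, breaks symmetry
            vessels.append(_vessel(f"e{i}", names[i], names[i + 1], length, d))
            rs.append(poiseuille_resistance(length, d, _MU))
        topo = _topology(vessels, {"ref"}, [FlowInput("src", q, "Q0")])
        pressures = {"ref": 0.0}
        acc = 0.0
        for i in range(n - 1, -1, -1):
            acc = series_resistance([acc, rs[i]]) if acc else rs[i]
            pressures[names[i]] = acc * q
        expected = SolveResult(
            node_pressures=pressures,
            edge_flows={f"e{i}": q for i in range(n)},
            residual=0.0,
            total_inflow=q,
        )
        return topo, expected

    if kind == "parallel_pair":
        r1 = poiseuille_resistance(length, diameter, _MU)
        r2 = poiseuille_resistance(length, diameter2, _MU)
        topo = _topology(
            [
                _vessel("b1", "src", "ref", length, diameter),
                _vessel("b2", "src", "ref", length, diameter2),
            ],
            {"ref"},
            [FlowInput("src", q, "Q0")],
        )
        rp = parallel_resistance([r1, r2])
        expected = SolveResult(
            node_pressures={"src": rp * q, "ref": 0.0},
            edge_flows={"b1": q * r2 / (r1 + r2), "b2": q * r1 / (r1 + r2)},
            residual=0.0,
            total_inflow=q,
        )
        return topo, expected

    if kind == "wye":
        r_stem = poiseuille_resistance(length, diameter, _MU)
        r1 = poiseuille_resistance(length, diameter2, _MU)
        r2 = poiseuille_resistance(2 * length, diameter2, _MU)
        topo = _topology(
            [
                _vessel("stem", "src", "junction", length, diameter),
                _vessel("b1", "junction", "ref", length, diameter2),
                _vessel("b2", "junction", "ref", 2 * length, diameter2),
            ],
            {"ref"},
            [FlowInput("src", q, "Q0")],
        )
        rp = parallel_resistance([r1, r2])
        expected = SolveResult(
            node_pressures={
                "src": (r_stem + rp) * q,
                "junction": rp * q,
                "ref": 0.0,
            },
            edge_flows={
                "stem": q,
                "b1": q * r2 / (r1 + r2),
                "b2": q * r1 / (r1 + r2),
            },
            residual=0.0,
            total_inflow=q,
        )
        return topo, expected

    # ladder: rails src=n0 -> n1 -> ... -> n_{n}, rung from every rail node
    # to the reference; solved by right-to-left impedance folding.
    rail_d = diameter
    rung_d = diameter2
    vessels = []
    rail_r = []
    rung_r = []
    names = ["src"] + [f"n{i}" for i in range(1, n + 1)]
    for i in range(n):
        vessels.append(
            _vessel(f"rail{i}", names[i], names[i + 1], length, rail_d)
        )
        rail_r.append(poiseuille_resistance(length, rail_d, _MU))
    for i in range(n + 1):
        vessels.append(
            _vessel(f"rung{i}", names[i], "ref", 2 * length, rung_d)
        )
        rung_r.append(poiseuille_resistance(2 * length, rung_d, _MU))
    topo = _topology(vessels, {"ref"}, [FlowInput("src", q, "Q0")])

    # fold from the far end: Z_i = resistance from node i to ref
    z = rung_r[n]
    z_right = [0.0] * (n + 1)
    z_right[n] = z
    for i in range(n - 1, -1, -1):
        z = parallel_resistance(
            [rung_r[i], series_resistance([rail_r[i], z])]
        )
        z_right[i] = z
    pressures = {"ref": 0.0, "src": z_right[0] * q}
    flows = {}
    p = pressures["src"]
    q_in = q
    for i in range(n + 1):
        flows[f"rung{i}"] = p / rung_r[i]
        if i < n:
            q_rail = q_in - flows[f"rung{i}"]
            flows[f"rail{i}"] = q_rail
            p = p - q_rail * rail_r[i]
            pressures[names[i + 1]] = p
            q_in = q_rail
    expected = SolveResult(
        node_pressures=pressures,
        edge_flows=flows,
        residual=0.0,
        total_inflow=q,
    )
    return topo, expected


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Recipe for a reproducible random resistive network."""

    node_count: int = 8
    edge_density: float = 0.3
    seed: int = 0
    source_count: int = 1
    reference_count: int = 1

    def __post_init__(self) -> None:
        if not 4 <= self.node_count <= 12:
            raise ValueError("node_count must be in [4, 12]")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must be in [0, 1]")
        if self.source_count < 1 or self.reference_count < 1:
            raise ValueError("need at least one source and one reference")
        if self.source_count + self.reference_count > self.node_count:
            raise ValueError("more sources+references than nodes")


def make_random(spec: RandomNetworkSpec) -> NetworkTopology:
    """Generate a random connected network from a seeded recipe.

    A random spanning tree guarantees connectivity (so validation always
    passes); extra edges are added between non-adjacent node pairs with
    probability ``edge_density``.  Same seed, same topology.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.node_count
    names = [f"n{i}" for i in range(n)]

    edges: list[tuple[str, str]] = []
    for i in range(1, n):
        j = int(rng.integers(0, i))  # random attachment: spanning tree
        edges.append((names[j], names[i]))
    present = {frozenset(e) for e in edges}
    for i in range(n):
        for j in range(i + 1, n):
            pair = frozenset((names[i], names[j]))
            if pair not in present and rng.random() < spec.edge_density:
                edges.append((names[i], names[j]))
                present.add(pair)

    perm = rng.permutation(n)
    refs = {names[int(k)] for k in perm[: spec.reference_count]}
    sources = [
        names[int(k)]
        for k in perm[
            spec.reference_count : spec.reference_count + spec.source_count
        ]
    ]

    vessels = []
    for k, (u, v) in enumerate(edges):
        vessels.append(
            _vessel(
                f"e{k}",
                u,
                v,
                length=float(rng.uniform(0.5, 30.0)) * CM,
                diameter=float(rng.uniform(0.05, 1.5)) * CM,
            )
        )
    inputs = [
        FlowInput(s, float(rng.uniform(0.5, 10.0)) * ML_PER_S, f"Q{i}")
        for i, s in enumerate(sources)
    ]
    return _topology(vessels, refs, inputs)
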