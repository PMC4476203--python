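"""Morphological interventions: stenoses, collaterals, parametric sweeps.

A stenosis is a fractional reduction of a vessel's equivalent diameter;
under Poiseuille's law a reduction r multiplies the resistance by
(1-r)^-4.  A reduction of exactly 1 (complete block) removes the edge
rather than approximating it with a huge finite resistance, which keeps
the conductance matrix well conditioned; the solver then reports a
singular system only if the block truly disconnects a source from every
reference.  All interventions return modified copies; topologies are
never mutated in place.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .anatomy import CM, ML_PER_S, AnatomyError, NetworkTopology, Vessel
from .core import SolveResult, SolverError, solve_network

__all__ = [
    "InterventionSpec",
    "CollateralSpec",
    "SweepAxis",
    "SweepSpec",
    "SweepRecord",
    "SweepResult",
    "apply_stenosis",
    "apply_diameter_overrides",
    "add_collaterals",
    "run_sweep",
]


@dataclass(frozen=True)
class InterventionSpec:
    """Reduce the diameter of a set of vessels by a common fraction."""

    targets: tuple[str, ...]
    diameter_reduction: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.diameter_reduction <= 1.0:
            raise ValueError(
                "diameter_reduction must lie in [0, 1], got "
                f"{self.diameter_reduction}"
            )
        if not self.targets:
            raise ValueError("intervention needs at least one target vessel")


@dataclass(frozen=True)
class CollateralSpec:
    """Add parallel collateral conduits alongside an existing vessel.

    ``diameter`` in metres; ``length`` defaults to the paralleled vessel's
    own length.  New vessel ids derive deterministically from the target id
    (``<target>__coll1`` ...).
    """

    parallel_to: str
    diameter: float
    length: float | None = None
    count: int = 1

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("collateral diameter must be positive")
        if self.length is not None and self.length <= 0:
            raise ValueError("collateral length must be positive")
        if self.count < 1:
            raise ValueError("collateral count must be >= 1")


@dataclass(frozen=True)
class SweepAxis:
    """One sweep axis: a vessel set reduced together over a grid."""

    targets: tuple[str, ...]
    grid: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError("sweep grid must be non-empty")
        if any(not 0.0 <= g <= 1.0 for g in self.grid):
            raise ValueError("grid values must lie in [0, 1]")
        if list(self.grid) != sorted(self.grid):
            raise ValueError("grid must be sorted ascending")


@dataclass(frozen=True)
class SweepSpec:
    """A grid of interventions: Cartesian product or zipped axes."""

    axes: tuple[SweepAxis, ...]
    cartesian: bool = True
    collaterals: tuple[CollateralSpec, ...] = ()
    diameter_overrides: tuple[tuple[str, float], ...] = ()  # (vessel, m)

    def grid_points(self) -> list[tuple[float, ...]]:
        """Deterministic row-major enumeration of the reduction grid."""
        grids = [ax.grid for ax in self.axes]
        if self.cartesian:
            return list(itertools.product(*grids))
        if len({len(g) for g in grids}) != 1:
            raise ValueError("zipped sweep requires equal-length grids")
        return list(zip(*grids))

    def n_points(self) -> int:
        return len(self.grid_points())


@dataclass(frozen=True)
class SweepRecord:
    """One grid point: the reductions applied and the solve (or failure)."""

    reductions: tuple[float, ...]
    result: SolveResult | None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.result is None


@dataclass(frozen=True)
class SweepResult:
    spec: SweepSpec
    baseline_topology: NetworkTopology  # after overrides and collaterals
    baseline: SolveResult
    records: tuple[SweepRecord, ...]

    def record_at(self, reductions: Sequence[float]) -> SweepRecord:
        key = tuple(reductions)
        for rec in self.records:
            if rec.reductions == key:
                return rec
        raise KeyError(f"no sweep record at grid point {key}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: axis reductions, quantity, entity, value."""
        axis_names = [
            ax.label or f"axis{i}" for i, ax in enumerate(self.spec.axes)
        ]
        rows = []
        for rec in self.records:
            base = dict(zip(axis_names, rec.reductions))
            if rec.failed:
                rows.append({**base, "quantity": "error", "entity": "",
                             "value": np.nan})
                continue
            for nid, p in rec.result.node_pressures.items():
                rows.append({**base, "quantity": "pressure_Pa",
                             "entity": nid, "value": p})
            for vid, q in rec.result.edge_flows.items():
                rows.append({**base, "quantity": "flow_ml_s",
                             "entity": vid, "value": q / ML_PER_S})
        return pd.DataFrame(
            rows, columns=axis_names + ["quantity", "entity", "value"]
        )


def apply_stenosis(
    t: NetworkTopology, spec: InterventionSpec
) -> NetworkTopology:
    """Return a copy with each target diameter scaled by (1 - reduction).

    A reduction of 1 removes the target edges entirely (complete block).
    The input topology is left unchanged.
    """
    unknown = [vid for vid in spec.targets if vid not in t.vessel_map]
    if unknown:
        raise AnatomyError(f"unknown vessel id(s) in intervention: {unknown}")
    r = spec.diameter_reduction
    targets = set(spec.targets)
    if r == 1.0:
        vessels = [v for v in t.vessels if v.id not in targets]
    else:
        vessels = [
            replace(v, diameter=v.diameter * (1.0 - r))
            if v.id in targets
            else v
            for v in t.vessels
        ]
    return t.with_vessels(vessels)


def apply_diameter_overrides(
    t: NetworkTopology, overrides: Iterable[tuple[str, float]]
) -> NetworkTopology:
    """Set absolute baseline diameters (metres) for selected vessels.

    Used for sensitivity runs with alternative published vessel calibres
    before a sweep (e.g. jugular diameters of 1 cm or 0.7 cm).
    """
    over = dict(overrides)
    unknown = [vid for vid in over if vid not in t.vessel_map]
    if unknown:
        raise AnatomyError(f"unknown vessel id(s) in overrides: {unknown}")
    if any(d <= 0 for d in over.values()):
        raise ValueError("override diameters must be positive")
    vessels = [
        replace(v, diameter=over[v.id]) if v.id in over else v
        for v in t.vessels
    ]
    return t.with_vessels(vessels)


def add_collaterals(
    t: NetworkTopology, spec: CollateralSpec
) -> NetworkTopology:
    """Add parallel collateral edges sharing the target's endpoints."""
    target = t.vessel(spec.parallel_to)
    length = spec.length if spec.length is not None else target.length
    new = [
        Vessel(
            id=f"{target.id}__coll{i + 1}",
            name=f"collateral {i + 1} of {target.name}",
            side=target.side,
            district="connective",
            length=length,
            diameter=spec.diameter,
            upstream_node=target.upstream_node,
            downstream_node=target.downstream_node,
        )
        for i in range(spec.count)
    ]
    return t.with_vessels(list(t.vessels) + new)


def run_sweep(t: NetworkTopology, sweep: SweepSpec) -> SweepResult:
    """Solve every grid point of a sweep.

    Overrides and collaterals are applied once to form the sweep baseline;
    each grid point then applies its per-axis diameter reductions to that
    baseline.  Singular grid points (a block that severs all drainage) are
    recorded as flagged failures instead of aborting the sweep.  Iteration
    is row-major over the axes, so record order and count are a pure
    function of the spec.
    """
    base = apply_diameter_overrides(t, sweep.diameter_overrides)
    for coll in sweep.collaterals:
        base = add_collaterals(base, coll)
    # fail fast on bad targets before any solving
    for ax in sweep.axes:
        missing = [vid for vid in ax.targets if vid not in base.vessel_map]
        if missing:
            raise AnatomyError(f"unknown sweep target(s): {missing}")

    baseline = solve_network(base)
    records = []
    for point in sweep.grid_points():
        topo = base
        for ax, r in zip(sweep.axes, point):
            topo = apply_stenosis(
                topo, InterventionSpec(targets=ax.targets,
                                       diameter_reduction=r)
            )
        try:
            res = solve_network(topo)
            records.append(SweepRecord(reductions=point, result=res))
        except SolverError as exc:
            records.append(
                SweepRecord(reductions=point, result=None, error=str(exc))
            )
    return SweepResult(
        spec=sweep,
        baseline_topology=base,
        baseline=baseline,
        records=tuple(records),
    )
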