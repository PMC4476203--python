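"""Poiseuille resistances and the steady-state nodal solve.

Each vessel is a hydraulic resistance R = 128 mu L / (pi D^4); pressure
drop and flow obey dP = R Q.  Flow conservation at every junction yields a
linear system in the unknown node pressures (the hydraulic analogue of
nodal circuit analysis): the conductance matrix has the sum of incident
conductances on the diagonal and minus the connecting conductance off it,
the right-hand side is the injected arterial inflow, and reference nodes
(fixed at 0 Pa) are eliminated.  The system is small (order 10^2), so it is
solved directly and deterministically with a sparse LU factorization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .anatomy import ML_PER_S, NetworkTopology, validate_topology

__all__ = [
    "poiseuille_resistance",
    "series_resistance",
    "parallel_resistance",
    "vessel_resistances",
    "solve_network",
    "SolveResult",
    "SolverError",
    "NoDrainagePathError",
    "PA_PER_MMHG",
]

PA_PER_MMHG = 133.322

#: warn when the post-hoc mass-balance residual exceeds this fraction of
#: the total injected flow (near-singular systems after severe occlusions)
RESIDUAL_WARN_REL = 1e-8


class SolverError(RuntimeError):
    """Numerical failure of the nodal solve."""


class NoDrainagePathError(SolverError):
    """A component with sources has no reference node: singular system."""


def poiseuille_resistance(
    length: float, diameter: float, viscosity: float
) -> float:
    """Hydraulic resistance of a cylindrical conduit, Pa*s/m^3.

    R = 128 mu L / (pi D^4) for fully developed laminar flow.  All
    arguments in SI (m, m, Pa*s) and strictly positive.
    """
    if length <= 0 or diameter <= 0 or viscosity <= 0:
        raise ValueError(
            "length, diameter and viscosity must all be positive "
            f"(got L={length}, D={diameter}, mu={viscosity})"
        )
    return 128.0 * viscosity * length / (math.pi * diameter**4)


def series_resistance(values) -> float:
    """Total resistance of elements in series: the plain sum."""
    values = list(values)
    if not values:
        raise ValueError("series_resistance needs at least one element")
    return float(sum(values))


def parallel_resistance(values) -> float:
    """Total resistance of elements in parallel: (sum 1/R_i)^-1."""
    values = list(values)
    if not values:
        raise ValueError("parallel_resistance needs at least one element")
    if any(r <= 0 for r in values):
        raise ValueError("parallel_resistance requires positive resistances")
    return 1.0 / sum(1.0 / r for r in values)


def vessel_resistances(t: NetworkTopology) -> dict[str, float]:
    """Per-vessel Poiseuille resistance for a topology, Pa*s/m^3."""
    return {
        v.id: poiseuille_resistance(v.length, v.diameter, t.viscosity)
        for v in t.vessels
    }


@dataclass(frozen=True)
class SolveResult:
    """Pressures, signed flows and the mass-balance residual of one solve.

    ``node_pressures`` in Pa (reference nodes at exactly 0); ``edge_flows``
    in m^3/s, signed by the vessel's drainage orientation (positive =
    antegrade).  ``residual`` is the maximum absolute node flow-balance
    error in m^3/s.
    """

    node_pressures: dict[str, float]
    edge_flows: dict[str, float]
    residual: float
    total_inflow: float

    def pressure_mmHg(self, node_id: str) -> float:
        return self.node_pressures[node_id] / PA_PER_MMHG

    def flow_ml_s(self, vessel_id: str) -> float:
        return self.edge_flows[vessel_id] / ML_PER_S

    def delta_p(self, t: NetworkTopology, vessel_id: str) -> float:
        """Pressure drop upstream minus downstream across one vessel, Pa."""
        v = t.vessel(vessel_id)
        return (
            self.node_pressures[v.upstream_node]
            - self.node_pressures[v.downstream_node]
        )

    # -- tabular views -----------------------------------------------------
    def node_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": list(self.node_pressures),
                "pressure_Pa": list(self.node_pressures.values()),
            }
        )

    def edge_frame(self, t: NetworkTopology) -> pd.DataFrame:
        rows = []
        for vid, q in self.edge_flows.items():
            rows.append(
                {
                    "vessel_id": vid,
                    "flow_ml_s": q / ML_PER_S,
                    "delta_p_Pa": self.delta_p(t, vid),
                    "antegrade": q >= 0,
                }
            )
        return pd.DataFrame(
            rows, columns=["vessel_id", "flow_ml_s", "delta_p_Pa", "antegrade"]
        )


def _direct_solve(mat: sp.csc_matrix, rhs: np.ndarray) -> np.ndarray:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", spla.MatrixRankWarning)
            return spla.spsolve(mat, rhs)
    except (spla.MatrixRankWarning, RuntimeError) as exc:
        raise SolverError(
            f"singular or ill-conditioned nodal system: {exc}"
        ) from exc


def solve_network(t: NetworkTopology, check: bool = True) -> SolveResult:
    """Solve the steady-state nodal system of a topology.

    Assembles the symmetric conductance matrix over non-reference nodes,
    eliminates every reference node at 0 Pa (multiple references therefore
    stay decoupled rather than being tied together), solves directly, and
    recovers per-vessel flows Q = g (P_up - P_down).  The mass-balance
    residual is always recomputed from the returned quantities; a residual
    above ``RESIDUAL_WARN_REL`` of the total inflow triggers a warning.
    """
    if check:
        report = validate_topology(t)
        if not report.is_valid:
            if any("no drainage path" in v for v in report.violations):
                raise NoDrainagePathError(str(report))
            raise SolverError(str(report))

    node_ids = [n.id for n in t.nodes]
    refs = set(t.reference_nodes)
    unknown = [nid for nid in node_ids if nid not in refs]
    index = {nid: i for i, nid in enumerate(unknown)}
    n = len(unknown)

    resistances = vessel_resistances(t)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for v in t.vessels:
        g = 1.0 / resistances[v.id]
        iu = index.get(v.upstream_node)
        idn = index.get(v.downstream_node)
        if iu is not None:
            rows.append(iu)
            cols.append(iu)
            vals.append(g)
        if idn is not None:
            rows.append(idn)
            cols.append(idn)
            vals.append(g)
        if iu is not None and idn is not None:
            rows.extend((iu, idn))
            cols.extend((idn, iu))
            vals.extend((-g, -g))

    rhs = np.zeros(n)
    for q in t.inputs:
        rhs[index[q.node_id]] += q.rate

    pressures = {nid: 0.0 for nid in node_ids if nid in refs}
    if n:
        mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
        # isolated unknown nodes (no incident vessel) leave zero rows:
        # fatal if they carry inflow, otherwise pinned to reference level
        zero_diag = np.flatnonzero(mat.diagonal() == 0)
        if zero_diag.size:
            bad = [unknown[i] for i in zero_diag if rhs[i] != 0]
            if bad:
                raise NoDrainagePathError(
                    f"no drainage path: inflow node(s) {bad} have no "
                    "incident vessels"
                )
            keep = np.setdiff1d(np.arange(n), zero_diag)
            sub = mat[np.ix_(keep, keep)]
            p = np.zeros(n)
            p[keep] = _direct_solve(sub.tocsc(), rhs[keep])
        else:
            p = _direct_solve(mat, rhs)
        if not np.all(np.isfinite(p)):
            raise SolverError(
                "nodal solve produced non-finite pressures "
                "(singular system; check drainage paths)"
            )
        pressures.update(zip(unknown, p.tolist()))

    flows = {}
    for v in t.vessels:
        g = 1.0 / resistances[v.id]
        flows[v.id] = g * (
            pressures[v.upstream_node] - pressures[v.downstream_node]
        )

    # post-hoc mass balance at every non-reference node
    balance = dict.fromkeys(unknown, 0.0)
    for v in t.vessels:
        if v.upstream_node in balance:
            balance[v.upstream_node] -= flows[v.id]
        if v.downstream_node in balance:
            balance[v.downstream_node] += flows[v.id]
    for q in t.inputs:
        balance[q.node_id] += q.rate
    residual = max((abs(b) for b in balance.values()), default=0.0)

    total = t.total_inflow()
    if total > 0 and residual > RESIDUAL_WARN_REL * total:
        warnings.warn(
            f"flow-balance residual {residual:.3e} m^3/s exceeds "
            f"{RESIDUAL_WARN_REL:.0e} of total inflow {total:.3e}",
            RuntimeWarning,
            stacklevel=2,
        )

    return SolveResult(
        node_pressures=pressures,
        edge_flows=flows,
        residual=residual,
        total_inflow=total,
    )
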