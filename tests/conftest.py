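"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's solver paths: the
relaxation oracle iterates node-pressure fixed points, and the signed-rank
oracle enumerates all sign patterns explicitly.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from venonet import reference_topology
from venonet.anatomy import NetworkTopology
from venonet.core import vessel_resistances


@pytest.fixture(scope="session")
def reference():
    return reference_topology()


@pytest.fixture(scope="session")
def reference_solved(reference):
    from venonet import solve_network

    return solve_network(reference)


def relaxation_solve(
    t: NetworkTopology, tol: float = 1e-12, max_iter: int = 500_000
) -> dict[str, float]:
    """Independent oracle: Gauss-Seidel fixed-point iteration on pressures.

    At every non-reference node the pressure is repeatedly replaced by the
    conductance-weighted mean of its neighbours plus the injected flow
    term, until the update falls below ``tol`` of the pressure scale.
    Never calls the direct solver.
    """
    resist = vessel_resistances(t)
    refs = set(t.reference_nodes)
    neighbours: dict[str, list[tuple[str, float]]] = {
        n.id: [] for n in t.nodes
    }
    for v in t.vessels:
        g = 1.0 / resist[v.id]
        neighbours[v.upstream_node].append((v.downstream_node, g))
        neighbours[v.downstream_node].append((v.upstream_node, g))
    injection = {n.id: 0.0 for n in t.nodes}
    for q in t.inputs:
        injection[q.node_id] += q.rate

    p = {n.id: 0.0 for n in t.nodes}
    unknown = [n.id for n in t.nodes if n.id not in refs and neighbours[n.id]]
    for _ in range(max_iter):
        delta = 0.0
        scale = 0.0
        for nid in unknown:
            gsum = sum(g for _, g in neighbours[nid])
            new = (
                sum(g * p[other] for other, g in neighbours[nid])
                + injection[nid]
            ) / gsum
            delta = max(delta, abs(new - p[nid]))
            scale = max(scale, abs(new))
            p[nid] = new
        if delta <= tol * max(scale, 1e-300):
            break
    return p


def brute_force_signed_rank_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns.

    Average ranks for tied |differences|; zeros must be removed by the
    caller.  Two-sided p doubles the smaller tail (capped at 1).
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    assert n >= 1 and np.all(diffs != 0)
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    ws = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product((False, True), repeat=n)
        ]
    )
    eps = 1e-9
    p_low = np.mean(ws <= w_obs + eps)
    p_high = np.mean(ws >= w_obs - eps)
    return float(min(1.0, 2.0 * min(p_low, p_high)))
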