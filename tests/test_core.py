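"""Resistance formulae and the nodal steady-state solver."""

from __future__ import annotations

import math

import numpy as np
import pytest

from venonet import (
    NoDrainagePathError,
    parallel_resistance,
    poiseuille_resistance,
    series_resistance,
    solve_network,
    vessel_resistances,
)
from venonet.fixtures import RandomNetworkSpec, make_random, make_toy
from venonet.intervention import InterventionSpec, apply_stenosis

from conftest import relaxation_solve


class TestPoiseuille:
    def test_hand_evaluated_value(self):
        # 128 * 0.003 * 0.1 / (pi * 0.01^4) = 0.0384 / (pi * 1e-8)
        r = poiseuille_resistance(0.1, 0.01, 0.003)
        assert r == pytest.approx(1.2223e6, rel=1e-4)
        assert r == pytest.approx(0.0384 / (math.pi * 1e-8), rel=1e-15)

    def test_fourth_power_diameter_scaling(self):
        r = poiseuille_resistance(0.2, 0.008, 0.003)
        assert poiseuille_resistance(0.2, 0.004, 0.003) == pytest.approx(
            16 * r, rel=1e-12
        )

    def test_linear_in_length_and_viscosity(self):
        r = poiseuille_resistance(0.1, 0.01, 0.003)
        assert poiseuille_resistance(0.2, 0.01, 0.003) == pytest.approx(
            2 * r
        )
        assert poiseuille_resistance(0.1, 0.01, 0.006) == pytest.approx(
            2 * r
        )

    @pytest.mark.parametrize(
        "args", [(0, 0.01, 0.003), (0.1, -1, 0.003), (0.1, 0.01, 0)]
    )
    def test_non_positive_arguments_rejected(self, args):
        with pytest.raises(ValueError):
            poiseuille_resistance(*args)


class TestSeriesParallel:
    def test_series_is_the_sum(self):
        assert series_resistance([1, 2, 3]) == 6
        assert series_resistance([7.5]) == 7.5

    def test_parallel_reciprocal_rule(self):
        assert parallel_resistance([4.0, 4.0]) == pytest.approx(2.0)
        assert parallel_resistance([2, 2, 2]) == pytest.approx(2 / 3)

    @pytest.mark.parametrize("fn", [series_resistance, parallel_resistance])
    def test_empty_rejected(self, fn):
        with pytest.raises(ValueError):
            fn([])

    def test_parallel_rejects_non_positive(self):
        with pytest.raises(ValueError):
            parallel_resistance([1.0, 0.0])

    def test_azygos_chain_series_equals_sum_oracle(self, reference):
        resist = vessel_resistances(reference)
        azygos = [resist[f"AZ{i}"] for i in range(1, 13)]
        total = 0.0
        for r in azygos:  # independent plain accumulation
            total += r
        assert series_resistance(azygos) == pytest.approx(
            total, rel=1e-15
        )

    def test_parallel_of_series_matches_full_nodal_solve(self):
        """Equivalent source impedance of a 3-edge network: the reduction
        rules must agree with the complete nodal solution."""
        t, _ = make_toy("wye")
        resist = vessel_resistances(t)
        r_eq = series_resistance(
            [
                resist["stem"],
                parallel_resistance([resist["b1"], resist["b2"]]),
            ]
        )
        res = solve_network(t)
        q = t.inputs[0].rate
        assert res.node_pressures["src"] / q == pytest.approx(
            r_eq, rel=1e-12
        )


class TestSolve:
    def test_single_vessel_ohm_analogue(self):
        t, expected = make_toy("single_edge")
        res = solve_network(t)
        assert res.node_pressures["src"] == pytest.approx(
            expected.node_pressures["src"], rel=1e-12
        )
        assert res.edge_flows["e0"] == pytest.approx(
            t.inputs[0].rate, rel=1e-12
        )

    def test_parallel_branch_split_inverse_to_resistance(self):
        t, expected = make_toy("parallel_pair")
        res = solve_network(t)
        for vid in ("b1", "b2"):
            assert res.edge_flows[vid] == pytest.approx(
                expected.edge_flows[vid], rel=1e-12
            )

    def test_conservation_and_global_balance(self, reference):
        res = solve_network(reference)
        total = reference.total_inflow()
        assert res.residual <= 1e-10 * total
        # everything injected leaves through the reference nodes
        out = 0.0
        for v in reference.vessels:
            if v.downstream_node in reference.reference_nodes:
                out += res.edge_flows[v.id]
            if v.upstream_node in reference.reference_nodes:
                out -= res.edge_flows[v.id]
        assert out == pytest.approx(total, rel=1e-12)

    def test_superposition_of_sources(self, reference):
        """The nodal system is linear: the all-sources solution is the sum
        of the single-source solutions."""
        full = solve_network(reference)
        summed = {nid: 0.0 for nid in full.node_pressures}
        for q in reference.inputs:
            single = reference.__class__(
                vessels=reference.vessels,
                nodes=reference.nodes,
                inputs=(q,),
                viscosity=reference.viscosity,
            )
            res = solve_network(single)
            for nid, p in res.node_pressures.items():
                summed[nid] += p
        scale = max(abs(p) for p in full.node_pressures.values())
        for nid, p in full.node_pressures.items():
            assert abs(summed[nid] - p) <= 1e-9 * scale

    def test_homogeneity_in_the_inputs(self, reference):
        k = 3.7
        scaled_inputs = tuple(
            q.__class__(q.node_id, q.rate * k, q.label)
            for q in reference.inputs
        )
        scaled = reference.__class__(
            vessels=reference.vessels,
            nodes=reference.nodes,
            inputs=scaled_inputs,
            viscosity=reference.viscosity,
        )
        a = solve_network(reference)
        b = solve_network(scaled)
        for nid in a.node_pressures:
            assert b.node_pressures[nid] == pytest.approx(
                k * a.node_pressures[nid], rel=1e-12, abs=1e-18
            )
        for vid in a.edge_flows:
            assert b.edge_flows[vid] == pytest.approx(
                k * a.edge_flows[vid], rel=1e-12, abs=1e-24
            )

    @pytest.mark.parametrize("seed", range(12))
    def test_direct_solve_matches_relaxation_oracle(self, seed):
        spec = RandomNetworkSpec(
            node_count=4 + seed % 9,
            edge_density=0.2 + 0.05 * (seed % 5),
            seed=seed,
            source_count=1 + seed % 2,
        )
        t = make_random(spec)
        direct = solve_network(t)
        oracle = relaxation_solve(t, tol=1e-14)
        scale = max(abs(p) for p in oracle.values())
        for nid, p in direct.node_pressures.items():
            assert abs(p - oracle[nid]) <= 1e-8 * scale

    @pytest.mark.parametrize("seed", range(20))
    def test_rayleigh_monotonicity_of_source_pressure(self, seed):
        """Increasing any single edge resistance can never lower the
        source pressure of a single-source network."""
        t = make_random(
            RandomNetworkSpec(node_count=4 + seed % 9, seed=100 + seed)
        )
        src = t.inputs[0].node_id
        p0 = solve_network(t).node_pressures[src]
        rng = np.random.default_rng(seed)
        vid = t.vessels[rng.integers(len(t.vessels))].id
        bumped = apply_stenosis(
            t, InterventionSpec((vid,), 0.3)
        )  # diameter down, resistance up
        p1 = solve_network(bumped).node_pressures[src]
        assert p1 >= p0 - 1e-12 * abs(p0)

    def test_isolated_inflow_raises_no_drainage_path(self):
        t, _ = make_toy("single_edge")
        blocked = apply_stenosis(t, InterventionSpec(("e0",), 1.0))
        with pytest.raises(NoDrainagePathError):
            solve_network(blocked)

    def test_residual_warning_not_raised_on_healthy_solves(self, reference):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            solve_network(reference)


class TestDecoupling:
    """Zero right-atrial pressure decouples the upper and lower systems:
    perturbations on one side leave the other side bit-identical."""

    def _split(self, reference):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(n.id for n in reference.nodes)
        g.add_edges_from(
            (v.upstream_node, v.downstream_node) for v in reference.vessels
        )
        g.remove_node("right_atrium")
        comps = list(nx.connected_components(g))
        upper = next(c for c in comps if "cerebral_inlet" in c)
        lower = next(c for c in comps if c is not upper)
        return upper, lower

    def test_upper_perturbation_leaves_lower_untouched(self, reference):
        upper, lower = self._split(reference)
        base = solve_network(reference)
        pert = solve_network(
            apply_stenosis(reference, InterventionSpec(("IJV_l",), 0.6))
        )
        for nid in lower:
            assert pert.node_pressures[nid] == base.node_pressures[nid]
        for v in reference.vessels:
            if v.upstream_node in lower or v.downstream_node in lower:
                assert pert.edge_flows[v.id] == base.edge_flows[v.id]

    def test_lower_perturbation_leaves_upper_untouched(self, reference):
        upper, lower = self._split(reference)
        base = solve_network(reference)
        pert = solve_network(
            apply_stenosis(reference, InterventionSpec(("AZ3",), 0.6))
        )
        for nid in upper:
            assert pert.node_pressures[nid] == base.node_pressures[nid]

    def test_mmHg_rendering(self, reference_solved):
        p = reference_solved.node_pressures["cerebral_inlet"]
        assert reference_solved.pressure_mmHg(
            "cerebral_inlet"
        ) == pytest.approx(p / 133.322)
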