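"""The built-in stenosis experiments on the reference anatomy.

Each named experiment encodes one obstruction protocol:

* ``ijv-bilateral`` -- both internal jugular diameters reduced
  independently from 0 % to 100 % in 10 % steps (11 x 11 = 121 solves).
* ``ijv-collaterals`` -- the same grid after adding one collateral vessel
  (diameter 0.4 cm, length equal to the jugular's) in parallel with each
  IJV.
* ``vv-bilateral`` -- all vertebral-vein segments reduced together,
  0-100 % in 10 % steps (11 solves).
* ``azygos-proximal`` -- the four proximal azygos segments reduced
  together, 0-100 % in 10 % steps (11 solves).

Alternative baseline jugular calibres (for sensitivity runs) are applied
as diameter overrides before the sweep.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .anatomy import CM, NetworkTopology
from .analysis import detect_reflux, find_threshold
from .intervention import (
    CollateralSpec,
    SweepAxis,
    SweepSpec,
    SweepResult,
    run_sweep,
)

__all__ = [
    "EXPERIMENTS",
    "experiment_spec",
    "run_experiment",
    "reduction_grid",
    "reflux_onset_table",
    "pressure_ratio_grid",
    "first_doubling_on_grid",
]

#: 0 %, 10 %, ... 100 % diameter reductions
DEFAULT_GRID = tuple(round(0.1 * i, 10) for i in range(11))

#: collateral calibre used alongside each jugular, cm
COLLATERAL_DIAMETER_CM = 0.4


def reduction_grid(step: float = 0.1) -> tuple[float, ...]:
    """Reduction grid 0..1 with the given step (default the 10 % grid)."""
    n = int(round(1.0 / step))
    return tuple(round(i * step, 10) for i in range(n + 1))


def experiment_spec(
    name: str,
    grid: tuple[float, ...] = DEFAULT_GRID,
    ijv_diameter_cm: float | None = None,
) -> SweepSpec:
    """Build the sweep spec for a named experiment.

    ``ijv_diameter_cm`` overrides the baseline jugular calibre before the
    sweep (sensitivity analysis with alternative published diameters).
    """
    from .reference import IJV_IDS, PROXIMAL_AZYGOS_IDS, VV_IDS

    overrides: tuple[tuple[str, float], ...] = ()
    if ijv_diameter_cm is not None:
        overrides = tuple(
            (vid, ijv_diameter_cm * CM) for vid in IJV_IDS
        )
    if name == "ijv-bilateral":
        return SweepSpec(
            axes=(
                SweepAxis(("IJV_l",), grid, label="IJV_l_reduction"),
                SweepAxis(("IJV_r",), grid, label="IJV_r_reduction"),
            ),
            cartesian=True,
            diameter_overrides=overrides,
        )
    if name == "ijv-collaterals":
        return SweepSpec(
            axes=(
                SweepAxis(("IJV_l",), grid, label="IJV_l_reduction"),
                SweepAxis(("IJV_r",), grid, label="IJV_r_reduction"),
            ),
            cartesian=True,
            collaterals=tuple(
                CollateralSpec(vid, COLLATERAL_DIAMETER_CM * CM)
                for vid in IJV_IDS
            ),
            diameter_overrides=overrides,
        )
    if name == "vv-bilateral":
        return SweepSpec(
            axes=(SweepAxis(VV_IDS, grid, label="VV_reduction"),),
            diameter_overrides=overrides,
        )
    if name == "azygos-proximal":
        return SweepSpec(
            axes=(
                SweepAxis(
                    PROXIMAL_AZYGOS_IDS, grid, label="AZ_proximal_reduction"
                ),
            ),
            diameter_overrides=overrides,
        )
    raise ValueError(
        f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}"
    )


EXPERIMENTS = (
    "ijv-bilateral",
    "ijv-collaterals",
    "vv-bilateral",
    "azygos-proximal",
)


def run_experiment(
    t: NetworkTopology,
    name: str,
    grid: tuple[float, ...] = DEFAULT_GRID,
    ijv_diameter_cm: float | None = None,
) -> SweepResult:
    return run_sweep(t, experiment_spec(name, grid, ijv_diameter_cm))


# ---------------------------------------------------------------------------
# sweep summaries


def reflux_onset_table(
    sweep: SweepResult, t: NetworkTopology, tolerance: float = 1e-12
) -> pd.DataFrame:
    """Per grid point: which vessels are refluent (long format)."""
    rows = []
    axis_names = [ax.label or f"axis{i}"
                  for i, ax in enumerate(sweep.spec.axes)]
    for rec in sweep.records:
        base = dict(zip(axis_names, rec.reductions))
        if rec.failed:
            rows.append({**base, "refluent": "<solve failed>"})
            continue
        rep = detect_reflux(rec.result, t, tolerance)
        rows.append({**base, "refluent": ";".join(rep.refluent_vessels)})
    return pd.DataFrame(rows, columns=axis_names + ["refluent"])


def pressure_ratio_grid(sweep: SweepResult, node: str) -> np.ndarray:
    """Node pressure relative to baseline over a 2-axis Cartesian sweep."""
    if len(sweep.spec.axes) != 2 or not sweep.spec.cartesian:
        raise ValueError("pressure_ratio_grid needs a 2-axis Cartesian sweep")
    n0 = len(sweep.spec.axes[0].grid)
    n1 = len(sweep.spec.axes[1].grid)
    base = sweep.baseline.node_pressures[node]
    out = np.full((n0, n1), np.nan)
    for k, rec in enumerate(sweep.records):
        if not rec.failed:
            out[k // n1, k % n1] = rec.result.node_pressures[node] / base
    return out


def first_doubling_on_grid(
    sweep: SweepResult, node: str
) -> tuple[float, float] | None:
    """Smallest (symmetric-ordered) grid point where a node pressure has at
    least doubled its baseline value, scanning the 2-axis grid in row-major
    order; ``None`` when never reached."""
    ratios = pressure_ratio_grid(sweep, node)
    g0 = sweep.spec.axes[0].grid
    g1 = sweep.spec.axes[1].grid
    hits = [
        (max(g0[i], g1[j]), min(g0[i], g1[j]))
        for i in range(len(g0))
        for j in range(len(g1))
        if np.isfinite(ratios[i, j]) and ratios[i, j] >= 2.0
    ]
    return min(hits) if hits else None
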