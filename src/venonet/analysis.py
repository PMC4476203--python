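"""Endpoints derived from solves and sweeps.

Covers reflux (retrograde-flow) detection, baseline-relative changes,
grid-threshold search, Reynolds numbers, and the one-sample Wilcoxon
signed-rank comparison of modelled against measured flow rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .anatomy import ML_PER_S, NetworkTopology
from .core import SolveResult
from .intervention import SweepRecord, SweepResult

__all__ = [
    "RefluxReport",
    "ThresholdResult",
    "FlowComparison",
    "RelativeChange",
    "detect_reflux",
    "relative_change",
    "find_threshold",
    "reynolds_number",
    "signed_rank_compare",
    "BLOOD_DENSITY",
    "DEFAULT_REFLUX_TOL",
]

#: default reflux tolerance, m^3/s -- far below any physiological flow,
#: guards only against float noise in the exact solve
DEFAULT_REFLUX_TOL = 1e-12

#: blood density for Reynolds numbers, kg/m^3 (standard literature value;
#: configurable wherever it is used)
BLOOD_DENSITY = 1060.0


@dataclass(frozen=True)
class RefluxReport:
    """Which vessels invert their flow in one steady-state solve.

    A vessel is refluent iff its signed flow is below ``-tolerance``;
    vessels with |flow| <= tolerance are classed stagnant, never refluent.
    """

    refluent_vessels: tuple[str, ...]
    stagnant_vessels: tuple[str, ...]
    flows: dict[str, float]
    tolerance: float
    by_district: dict[str, tuple[str, ...]]

    @property
    def any_reflux(self) -> bool:
        return bool(self.refluent_vessels)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "vessel_id": vid,
                "flow_ml_s": self.flows[vid] / ML_PER_S,
                "class": (
                    "refluent"
                    if vid in self.refluent_vessels
                    else "stagnant"
                    if vid in self.stagnant_vessels
                    else "antegrade"
                ),
            }
            for vid in self.flows
        ]
        return pd.DataFrame(rows, columns=["vessel_id", "flow_ml_s", "class"])


@dataclass(frozen=True)
class ThresholdResult:
    """Where along a discrete sweep grid a predicate first holds.

    Values are grid levels (reduction fractions), never interpolated.
    ``transitions`` lists every False->True or True->False switch for
    non-monotone predicates.
    """

    axis: str
    predicate: str
    reached: bool
    first_true: float | None
    last_false: float | None
    transitions: tuple[tuple[float, float], ...] = ()

    def __str__(self) -> str:
        if not self.reached:
            return f"{self.predicate}: not reached along {self.axis}"
        return (
            f"{self.predicate}: first true at {self.first_true:g} "
            f"(last false {self.last_false:g}) along {self.axis}"
        )


@dataclass(frozen=True)
class RelativeChange:
    """(perturbed - baseline)/baseline per node pressure and edge flow."""

    pressure: dict[str, float]
    flow: dict[str, float]
    undefined_pressure: tuple[str, ...]
    undefined_flow: tuple[str, ...]


@dataclass(frozen=True)
class FlowComparison:
    """One-sample signed-rank comparison of measured flows vs the model."""

    vessel: str
    measured_ml_s: tuple[float, ...]
    model_ml_s: float
    statistic: float
    p_value: float
    n_used: int

    @property
    def significance(self) -> str:
        if self.p_value < 0.05:
            return "significant"
        if self.p_value < 0.1:
            return "trend"
        return "ns"


def detect_reflux(
    result: SolveResult,
    topology: NetworkTopology | None = None,
    tolerance: float = DEFAULT_REFLUX_TOL,
) -> RefluxReport:
    """Classify every vessel of a solved network by flow sign.

    Retrograde flow means the pressure difference across the vessel has
    reverted relative to its physiological drainage direction.  Passing
    the topology enables the per-district grouping.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    refluent = tuple(
        vid for vid, q in result.edge_flows.items() if q < -tolerance
    )
    stagnant = tuple(
        vid
        for vid, q in result.edge_flows.items()
        if -tolerance <= q <= tolerance
    )
    by_district: dict[str, tuple[str, ...]] = {}
    if topology is not None:
        vm = topology.vessel_map
        for vid in refluent:
            district = vm[vid].district if vid in vm else "connective"
            by_district[district] = by_district.get(district, ()) + (vid,)
    return RefluxReport(
        refluent_vessels=refluent,
        stagnant_vessels=stagnant,
        flows=dict(result.edge_flows),
        tolerance=tolerance,
        by_district=by_district,
    )


def relative_change(
    baseline: SolveResult, perturbed: SolveResult, zero_tol: float = 0.0
) -> RelativeChange:
    """Baseline-relative change of every node pressure and edge flow.

    Entries whose baseline magnitude is <= ``zero_tol`` are flagged
    undefined instead of divided.  The two results must cover identical
    node and vessel sets.
    """
    if set(baseline.node_pressures) != set(perturbed.node_pressures) or set(
        baseline.edge_flows
    ) != set(perturbed.edge_flows):
        raise ValueError(
            "relative_change requires solves over the same topology"
        )

    def _rel(base: Mapping[str, float], pert: Mapping[str, float]):
        out, undef = {}, []
        for key, b in base.items():
            if abs(b) <= zero_tol:
                undef.append(key)
            else:
                out[key] = (pert[key] - b) / b
        return out, tuple(undef)

    dp, up = _rel(baseline.node_pressures, perturbed.node_pressures)
    dq, uq = _rel(baseline.edge_flows, perturbed.edge_flows)
    return RelativeChange(
        pressure=dp, flow=dq, undefined_pressure=up, undefined_flow=uq
    )


def find_threshold(
    sweep: SweepResult,
    predicate: Callable[[SweepRecord], bool],
    label: str = "predicate",
    axis: int = 0,
) -> ThresholdResult:
    """First grid level of a (single-axis) sweep where a predicate holds.

    Works on the discrete grid only.  Failed (singular) records count as
    satisfying nothing.  For non-monotone predicates every transition pair
    is reported alongside the first-true/last-false summary.
    """
    if len(sweep.spec.axes) <= axis:
        raise ValueError(f"sweep has no axis {axis}")
    values = [rec.reductions[axis] for rec in sweep.records]
    truth = [
        (not rec.failed) and bool(predicate(rec)) for rec in sweep.records
    ]
    first_true = next(
        (v for v, t in zip(values, truth) if t), None
    )
    last_false = None
    for v, t in zip(values, truth):
        if not t:
            last_false = v
    transitions = tuple(
        (values[i], values[i + 1])
        for i in range(len(truth) - 1)
        if truth[i] != truth[i + 1]
    )
    axis_label = sweep.spec.axes[axis].label or f"axis{axis}"
    return ThresholdResult(
        axis=axis_label,
        predicate=label,
        reached=first_true is not None,
        first_true=first_true,
        last_false=last_false,
        transitions=transitions,
    )


def reynolds_number(
    flow: float,
    diameter: float,
    density: float = BLOOD_DENSITY,
    viscosity: float = 3e-3,
) -> float:
    """Re = 4 rho |Q| / (pi mu D) for a cylindrical conduit.

    ``flow`` in m^3/s, ``diameter`` in m.  Low values (well under ~2000)
    support the laminar Poiseuille description.
    """
    if diameter <= 0 or density <= 0 or viscosity <= 0:
        raise ValueError(
            "diameter, density and viscosity must be positive"
        )
    return 4.0 * density * abs(flow) / (math.pi * viscosity * diameter)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic by rank-sum DP.

    Enumerates the null distribution of W+ over all 2^n sign assignments
    via dynamic programming on doubled ranks (average ranks with ties are
    half-integers).  Two-sided p = 2 * min(P(W<=w), P(W>=w)), capped at 1;
    the null distribution is symmetric, so this equals the symmetric-range
    probability.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_low = counts[: w2 + 1].sum()
    p_high = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def signed_rank_compare(
    measured_ml_s: Sequence[float],
    model_ml_s: float,
    vessel: str = "",
) -> FlowComparison:
    """One-sample Wilcoxon signed-rank test of measurements vs the model.

    Zero differences are dropped (n counts non-zero differences only);
    ties in |difference| get average ranks.  The two-sided p-value is
    exact (full enumeration of sign assignments) for n <= 25 and uses the
    normal approximation with tie correction beyond that.  If every
    difference is zero the comparison is vacuous: p = 1 with n = 0.
    """
    measured = np.asarray(list(measured_ml_s), dtype=float)
    if measured.size == 0:
        raise ValueError("signed_rank_compare needs at least one measurement")
    diffs = measured - model_ml_s
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        return FlowComparison(
            vessel=vessel,
            measured_ml_s=tuple(measured),
            model_ml_s=float(model_ml_s),
            statistic=0.0,
            p_value=1.0,
            n_used=0,
        )
    ranks = rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    if n <= 25:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        from scipy.stats import norm

        z = (w_plus - mean) / math.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return FlowComparison(
        vessel=vessel,
        measured_ml_s=tuple(measured),
        model_ml_s=float(model_ml_s),
        statistic=w_plus,
        p_value=p,
        n_used=int(n),
    )
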