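# venonet

A lumped-parameter (resistive-network) simulator of cerebrospinal venous
circulation.

Clinical imaging keeps raising the question of whether an *extracranial*
venous obstacle — a stenosed internal jugular vein (IJV), vertebral vein
(VV) or azygos vein (AZY) — can measurably alter *intracranial* venous
pressures and flow directions.  `venonet` addresses that question with the
classic electrical analogy for steady, laminar flow: every vein is a
hydraulic resistor

    R = 128 μ L / (π D⁴)          (Poiseuille)
    ΔP = R · Q                    (linear pressure–flow relation)

with blood viscosity μ = 3 cP and each vessel's length L and equivalent
diameter D.  Flow conservation at every junction gives a sparse linear
nodal system in the unknown node pressures; arterial inflows
(Q_c cerebral, Q_v1…Q_v21 per-vertebra, Q_f femoral) are the sources, and
two nodes are held at 0 Pa — the subclavian vein (negligible resistance)
and the right atrium (negligible atrial pressure).  The zero right-atrial
pressure decouples the network into an upper (cerebral + upper spinal)
and a lower (cardiac + lower spinal) system.  Compliance and inertance
are deliberately absent: the model is steady-state, valid for a supine
subject.

The package bundles a **synthetic reference anatomy**: 105 vessel
segments whose connectivity follows the standard description of the
cerebrospinal venous tree (dural sinuses and deep Galenic system; jugular,
vertebral and vertebral-plexus routes; azygos, thoracic/lumbar plexus and
caval axis) with literature-range dimensions, calibrated once against
supine venous physiology.  Because a vessel's orientation encodes its
physiological drainage direction, *retrograde flow (reflux) is simply a
negative signed flow* — no extra machinery.

Intended users: researchers in computational physiology / cerebral
hemodynamics who want a transparent, fully scriptable 0-D venous model
for occlusion what-if studies, and methodologists who need a small,
exactly solvable resistive-network testbed.

## Worked example

Solve the bundled reference anatomy and write the result tables:

```bash
venonet simulate --out out/baseline
# solved 105 vessels / 67 nodes; residual 1.31e-20 m^3/s; 105 antegrade
```

All 105 vessels drain antegrade — the physiological flow map emerges from
the pressure field alone, it is nowhere imposed.  A few lines of the
outputs (`out/baseline/vessel_flows.csv`, `node_pressures.csv`):

```
vessel_id  flow_ml_s  delta_p_Pa  antegrade        node_id             pressure_Pa
SSS         6.80      486.5       True             cerebral_inlet      546.4
SRS         2.97       70.8       True             galenic_confluence  145.5
IJV_l       5.77        3.7       True             torcular             59.9
VV_l2       0.32        3.5       True             jugular_bulb_l        3.7
```

Reading: the superior sagittal sinus carries 6.8 ml/s of the 12 ml/s
cerebral inflow; each jugular drains ≈ 5.8 ml/s to the subclavian vein
across only ≈ 3.7 Pa (0.03 mmHg) — in the supine position the IJVs are a
very low-resistance route, which is exactly why it takes a *severe*
stenosis to disturb the intracranial circulation.

Now obstruct both jugulars over the full 11 × 11 grid of diameter
reductions (0–100 % in 10 % steps, 121 steady-state solves):

```bash
venonet sweep --experiment ijv-bilateral --out out/ijv
# 121 grid points solved (0 singular/flagged)
```

`out/ijv/reflux_onset.csv` shows an empty reflux column until both
reductions are severe; with both jugulars reduced ≥ 80 % the cavernous
and petrosal sinuses (CS, IPS, SPS, both sides) invert — blood escapes
through the basilar plexus into the anterior cervical plexus instead —
while the deep Galenic vessels (basal veins of Rosenthal, internal
cerebral veins) never invert.  Other built-in protocols:
`ijv-collaterals` (a 0.4 cm collateral beside each IJV),
`vv-bilateral` (all vertebral-vein segments; the occipital sinuses invert
beyond ~50 % reduction) and `azygos-proximal` (the four proximal azygos
segments; the mid-azygos AZ5 inverts beyond ~70 % and drains to the right
atrium via the inferior vena cava).

Compare model flows with per-subject measurements (one-sample Wilcoxon
signed-rank test, exact p-values):

```bash
venonet compare --measured measured_flows.csv --out out/cmp
```

Everything is also available as a library:

```python
from venonet import reference_topology, solve_network, detect_reflux
from venonet.intervention import InterventionSpec, apply_stenosis

t = reference_topology()
narrowed = apply_stenosis(t, InterventionSpec(("IJV_l", "IJV_r"), 0.9))
print(detect_reflux(solve_network(narrowed), t).refluent_vessels)
# ('CS_l', 'SPS_l', 'IPS_l', 'CS_r', 'SPS_r', 'IPS_r')
```

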