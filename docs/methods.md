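# Methods

## Model

`venonet` treats the cerebrospinal venous system as a steady-state
resistive network — the hydraulic analogue of a DC circuit.  Each vessel
segment is a lumped Poiseuille resistance

    R = 128 μ L / (π D⁴),    ΔP = R · Q

with dynamic viscosity μ = 3 cP (0.003 Pa·s) and the segment's length L
and equivalent diameter D.  Flow conservation at every junction turns the
network into a symmetric positive-definite linear system in the unknown
node pressures: the conductance matrix carries the sum of incident
conductances on its diagonal and minus the connecting conductance off it;
the right-hand side holds the injected arterial inflows.  Per-vessel
flows are recovered as Q = g·(P_up − P_down).

Assumptions, stated as what is *absent*:

* **No compliance, no inertance, no valves.** The model is strictly
  steady-state; cardiac and respiratory pulsatility, postural collapse of
  the jugulars and valve dynamics are outside its scope.  It describes a
  supine subject.
* **No non-Newtonian rheology.** A single constant viscosity is used; at
  the shear rates of large veins this is the standard approximation.
* **No intra-vessel flow structure.** A vessel is refluent only if its
  *net* flow reverts.  Partial or separated recirculation inside a lumen
  cannot be represented by a lumped element.  The Reynolds numbers the
  model produces (peak ≈ 680 in the superior sagittal sinus, far below
  the ~2000 laminar–turbulent transition) justify the Poiseuille closure.

Boundary conditions: arterial inflows Q_c (cerebral), Q_v1…Q_v21 (one per
vertebral level) and Q_f (femoral) enter as flow sources; the subclavian
vein and the right atrium are fixed at exactly 0 Pa.  All reference nodes
are *eliminated* from the system rather than merged, so several grounded
nodes never create an artificial conducting path between them.  A direct
sparse LU solve is used: the systems are tiny (≲ 10² unknowns), a direct
solve is deterministic, and no preconditioning or iteration tolerance
enters the results.  The mass-balance residual is recomputed after every
solve from the returned pressures and flows and stored on the result; a
residual above 10⁻⁸ of the total inflow raises a warning (the typical
value is ~10⁻¹⁶).

Edge orientation is data: `upstream_node → downstream_node` in the
anatomy table encodes the physiological drainage direction, so a negative
signed flow *is* retrograde flow.  Reflux detection therefore reduces to
a sign test with a guard tolerance of 10⁻¹² m³/s — many orders of
magnitude below any physiological flow, present only to absorb float
noise; the classification is verified to be identical across tolerances
from 10⁻¹² to 10⁻⁹ m³/s in all obstruction scenarios.

## Units

Anatomy tables and configs use the conventional units of the field
(centimetres, ml/s, cP); everything internal is strict SI (m, m³/s, Pa,
Pa·s), converted only at the I/O boundary.  Because R depends on D⁴, a
mixed-unit bug would be silent and catastrophic; confining conversions to
the loader/writer pair removes that failure mode.  Pressures are reported
in Pa with an optional mmHg rendering (1 mmHg = 133.322 Pa).

## The synthetic reference anatomy

The packaged table `anatomy_synthetic_reference.csv` is a **synthetic
reconstruction**, not a measured data set.  Its connectivity follows the
standard anatomical description of the cerebrospinal venous tree:

* **Intracranial (25 elements).** A single cerebral-inlet node receives
  Q_c and feeds the superior sagittal sinus, the inferior sagittal sinus,
  the paired internal cerebral and basal (Rosenthal) veins — which meet
  at the confluence into the great vein of Galen, the model's
  intracranial pressure probe — and the paired ophthalmic veins into the
  cavernous sinuses.  The deep system drains through the straight sinus
  to the torcular, then through transverse and sigmoid sinuses to the
  jugular bulbs.  Each cavernous sinus drains three ways: superior
  petrosal sinus (to the transverse–sigmoid junction), inferior petrosal
  sinus (to the jugular bulb), and basilar plexus (to the anterior
  cervical plexus).  Occipital sinuses run from the torcular to the
  posterior cervical plexus.
* **Cervical (45 elements).** Two internal jugular veins (bulb →
  subclavian), a seven-segment cervical vertebral-plexus chain with
  anterior/posterior feeder segments, six vertebral-vein segments per
  side, and six plexus-to-vertebral connectives per side.  Q_v1…Q_v7
  enter at the plexus levels.
* **Thoracic/lumbar (35 elements).** A twelve-segment azygos chain
  (numbered from the cavoatrial end), a twelve-segment thoracic plexus
  chain with one plexus-to-azygos connective per level (Q_v8…Q_v19), a
  two-level lumbar plexus (Q_v20, Q_v21) with connectives to lumbar veins
  draining into a three-segment inferior vena cava (Q_f at the femoral
  end, terminating at the right atrium).

Under the strict reading of that enumeration — bilateral only where
anatomy is bilateral, midline chains otherwise — the network has 105
resistive elements and 67 nodes.  Dimensions were drawn once from
plausible literature ranges for each structure (e.g. jugular ≈ 1.3 cm,
sinuses 0.45–0.8 cm, plexus channels 0.15–0.45 cm, cava ≈ 2 cm) and
calibrated once, before the test suite was frozen, against supine venous
physiology: an all-antegrade baseline flow map, jugular-dominant cerebral
outflow (≈ 5.8 ml/s per side of the 12 ml/s cerebral inflow), a dominant
superior sagittal sinus (≈ 6.8 ml/s), and laminar Reynolds numbers.  The
inflow magnitudes (Q_c = 12 ml/s; Q_v 0.2–0.8 ml/s per level;
Q_f = 10 ml/s) live in the config file, not in code.

What the synthetic anatomy does **not** emulate: real left–right
asymmetry (the bundled table is symmetric, though the code accepts
asymmetric tables — asymmetry is data, not code), facial and external
jugular drainage, venules, inter-subject variability, and the exact
per-segment dimensions of any published table.  Consequently the *grid
thresholds* of the obstruction experiments (at which reduction level a
given sinus inverts or a pressure doubles) are properties of this
particular reconstruction; the *qualitative* findings — which vessels
invert, in which order, and through which escape routes — are the
robust content, and those are what the test suite asserts.  Passing
tests show the mechanism is reproduced, not that any individual's
thresholds are predicted.

## Interventions and sweeps

A stenosis multiplies the target diameter by (1 − r); under Poiseuille's
law resistance grows by (1 − r)⁻⁴.  Reductions act on the *diameter*,
not the cross-sectional area.  r = 1 (complete block) removes the edge
outright instead of approximating it with a huge finite resistance —
this keeps the matrix well-conditioned and makes a genuinely severed
drainage path detectable as a structural singularity ("no drainage
path"), which sweeps record as flagged points rather than aborting.
Zero-resistance edges are disallowed outright; coincident nodes should
be merged in the anatomy instead.

Collaterals are new parallel edges sharing the target's endpoints
(default length = the target's own length; ids derived deterministically
from the target id).  Alternative baseline calibres (e.g. jugular
diameters of 1.0 or 0.7 cm) are absolute diameter overrides applied
before a sweep, not separate anatomy files.  Sweep grids are enumerated
row-major over the axes (Cartesian product by default, zipped on
request), so record order and count are pure functions of the spec; the
all-zeros grid point reproduces the baseline solve exactly.

The built-in protocols: `ijv-bilateral` (11 × 11 grid, 0–100 % in 10 %
steps), `ijv-collaterals` (same grid with one 0.4 cm collateral per
jugular), `vv-bilateral` (all twelve vertebral-vein segments together;
the plexus-to-vertebral connectives are deliberately left patent),
`azygos-proximal` (the four proximal azygos segments together).  Finer
grids (e.g. 1 % steps) are ordinary custom grids.

## Analysis conventions

* "Pressure doubled" compares the absolute node pressure (relative to
  the 0 Pa references) against twice the baseline pressure at the same
  node.
* "Jugular upstream pressure" is the pressure at the cranial end of the
  jugular element (the jugular bulb node); the posterior end of the
  superior sagittal sinus is its downstream node (the torcular).
* Thresholds are reported on the discrete grid only — first grid value
  where the predicate holds, last where it fails — never interpolated.
  Non-monotone predicates report every transition pair.
* Reynolds numbers use Re = 4ρ|Q|/(πμD) with blood density
  ρ = 1060 kg/m³ (a standard literature value, configurable).
* The model-vs-measurement comparison is a one-sample Wilcoxon
  signed-rank test: zero differences dropped, average ranks for tied
  |differences|, exact two-sided p by full enumeration of the sign-flip
  null (dynamic programming over doubled ranks) for n ≤ 25, normal
  approximation with tie correction beyond.  p < 0.05 is classed
  significant, p < 0.1 a trend.  The implementation is cross-checked in
  the tests against brute-force 2ⁿ enumeration (n ≤ 10) and against
  scipy's exact method on tie-free samples; it is deliberately not a
  wrapper around either.

## Numerical choices and degenerate inputs

* Direct sparse LU, no iterative fallback; singular systems raise with a
  diagnostic naming the disconnected component.
* Isolated nodes created by edge removal are fatal if they carry inflow
  ("no drainage path"), otherwise pinned to the reference pressure as
  dead stubs.
* The independent test oracle is a Gauss–Seidel pressure relaxation run
  to 10⁻¹⁴, implemented separately in the test suite; direct and relaxed
  solutions agree to ≲ 10⁻¹² relative on random networks.
* The random-network generator (4–12 nodes) builds a random spanning
  tree first, so connectivity — and hence solvability — is guaranteed by
  construction; geometry is drawn from D ∈ [0.05, 1.5] cm,
  L ∈ [0.5, 30] cm, bracketing venous dimensions without copying any
  anatomy.  All generation is seeded and reproducible.

## Known limitations

* Grid thresholds depend on the chosen "normal" dimensions and should
  not be read as clinical cut-offs; the sensitivity runs (jugular 1.0
  and 0.7 cm) show them shifting to milder reductions for narrower
  baseline calibres.
* A collateral of fixed calibre placed beside a severely stenosed
  jugular is a genuine alternative outflow in this network; with the
  thin basilar/cervical escape routes of this reconstruction its effect
  on peak intracranial pressure at near-total occlusion is large
  (tens of percent, reported by the acceptance script), and at complete
  bilateral occlusion it can prevent intracranial reflux entirely.  How
  much relief a collateral provides is controlled by the calibre ratio
  between collateral and escape routes, which this synthetic anatomy
  fixes only loosely.
* The steady-state, supine, valveless idealisation excludes exactly the
  phenomena (postural change, pulsatility, intermittent reflux) that
  dominate some clinical presentations.
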