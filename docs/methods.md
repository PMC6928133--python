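# Methods

## Scope and model

`vablate` simulates electrical wave propagation in the left atrium (LA) as a
monodomain reaction–diffusion system on a triangulated surface carrying a
constant-thickness (1.89 mm) monolayer of atrial myocardium:

    dVm/dt = D_eff · L(Vm) − (I_ion + I_s)

with `Vm` the membrane potential (mV), `I_ion` the total ionic current
density of the cell model (pA/pF), `I_s` the stimulus, `L` a node-area-lumped
surface Laplacian and `D_eff` a single effective diffusivity (mm²/ms).  The
membrane surface-to-volume ratio and specific capacitance of the continuous
monodomain formulation are folded into `D_eff` because the only tissue-scale
quantity the model constrains is the emergent conduction velocity (CV),
fixed by calibration at 0.4 m/s — the mean value measured in human atria.
The model is deliberately homogeneous: no fibrosis, fiber orientation or
wall-thickness variation (the anatomy is the only per-atrium input).

On this substrate the package reproduces the per-patient virtual-ablation
experiment: induce fibrillatory reentry, wait 4 s, clamp one of five
clinical lesion sets to −80.6 mV (permanent conduction block), observe for
25 s, and declare termination when every node of the chamber is ≥90%
repolarized with no further activation.  The lesion set with the fastest
termination is reported.

## Ionic model and AF remodeling

Cellular kinetics follow the Courtemanche–Ramirez–Nattel (1998) human atrial
action-potential model in full: 21 state variables (Vm, 15 gates, 5
concentrations), 12 membrane currents, and the two-compartment SR calcium
subsystem.  Persistent-AF electrical remodeling is applied as exactly four
conductance scalings — I_to ×0.2, I_CaL ×0.6, I_Kur ×0.5, I_K1 ×1.5 — with
every other parameter untouched.

Validation of the implementation against the published baseline model:
resting Vm −81.19 mV (published −81.18 mV), APD90 ≈ 295 ms at 1 Hz
(published ≈ 300 ms).  With the four remodeling scalings the package
measures a resting Vm of −83.1 mV and an APD90 of 202.6 ms at steady 1 Hz
pacing.  Reference values of −80.6 mV and 213 ± 2 ms have been reported for
a *modified* variant of this model whose additional modifications are not
published; the ~2.5 mV / ~10 ms residual is therefore a documented model
difference, not a tunable.  The ablation clamp stays at −80.6 mV: it is a
defined clamp level, independent of the cell model's own rest.

### Integration

Rush–Larsen exponential updates for the 15 gates, forward Euler for Vm and
concentrations, fixed dt = 0.02 ms (configurable; peak Vm converges at
~0.6 mV per dt-halving, APD90 at ~0.4 ms — first order, as expected).  Two
numba kernels share one physics core: an analytic path evaluating every rate
expression (single-cell work), and a tissue path that linearly interpolates
the 30 voltage-dependent rate quantities from a 0.05 mV-spaced lookup table
rebuilt per dt (≈10× faster; agrees with the analytic path to <0.1 mV over
an AP, covered by a test).

Single-cell protocols: the resting state is the unstimulated fixed point
(drift < 0.01 mV/s); stimulus amplitude is auto-calibrated by bisection to
2× diastolic threshold (2 ms pulse); APD90 is measured on the last complete
beat, from the maximum-upstroke instant to 90% recovery of the
peak-to-diastolic excursion.

## Discretization and CV calibration

The diffusion operator is the cotangent-weighted graph Laplacian of the
surface with barycentric (one-third) node-area lumping.  Negative cotangent
weights from obtuse triangles are clamped to zero to keep the operator
monotone and all edge weights non-negative.  Rows and columns of
non-conductive nodes (the mitral annulus) and ablated nodes are zeroed — no
flux in or out.  Time stepping is first-order operator splitting (diffusion,
then reaction); the simulator refuses dt above the explicit stability bound
`1 / (D · max_i(deg_i / a_i))`.

`D_eff` is found by bracketing plus log-secant iteration until the planar CV
on a 40 × 8 mm reference strip, measured from mean activation times at 25%
and 75% of strip length, is within 2% of the 0.4 m/s target.  Two numerical
facts matter here:

* **Resolution dependence.**  The depolarization front is ~0.3 mm wide, so
  at practical node spacings the front is under-resolved and the numerical
  CV for a fixed D depends on the mesh spacing (0.5 mm strip: 0.39 m/s;
  0.25 mm: 0.49; a D calibrated at 0.5 mm blocks outright on a 2.4 mm
  mesh).  Consequently `calibrate_for_mesh` always calibrates on a strip
  whose spacing matches the tissue mesh's mean edge length, which transfers
  the target CV to the atrium within a few percent.  CV convergence under
  edge-halving (<5%) holds once the front is resolved relative to the
  spacing (verified at D = 2 mm²/ms); at the calibrated default D it is
  recovered by the per-resolution calibration instead.
* **√D scaling.**  The continuum prediction CV ∝ √D is verified over a 16×
  diffusivity sweep on the 0.25 mm strip with CFL-limited dt (measured
  log–log slope 0.538).

## Synthetic left atrium

The generator produces a golden-spiral (Fibonacci) sphere triangulated by
its convex hull, scaled to ellipsoidal semi-axes (default 33 × 28 × 26 mm —
a mildly dilated adult LA, ≈105 cm² surface, consistent with persistent-AF
chamber dimensions), with smooth outward protrusions for the four pulmonary
veins (tube radius 5.5 mm, length 9 mm) and the appendage, and openings cut
at the PV tube tips and the mitral annulus.  The result is a
manifold-with-boundary of Euler characteristic −3 (sphere minus five disks).
The seed perturbs the lattice phase, semi-axes (±5%) and PV directions (±3°)
to emulate anatomical variability; meshes are bitwise-deterministic per
seed.  Landmarks (4 PV antra, annulus rim, appendage ostium, Bachmann's
bundle insertion, roof apex) are labelled geometrically; on imported meshes
they come from a JSON/YAML spec of node lists or snapped seed points grown
to 2 mm geodesic disks.

What the generator does *not* emulate: real PV ostial geometry and antral
folds, wall-thickness variation, fibrotic substrate, a true appendage with
pectinate muscles.  Passing tests on these atria therefore demonstrate the
engine's mechanics (induction, block, mapping, ranking) — not clinical
predictive value on patient anatomies.

## Lesion sets

Lesions are node sets clamped to −80.6 mV.  Default full width 4 mm
(widened to 1.05× the longest mesh edge if coarser, so block is guaranteed).

* **CPVI** — per ipsilateral PV pair, the geodesic distance band
  [3 mm, 3 mm + width) around the union of the pair's PV node sets.  A
  distance band wider than the longest edge is a closed separating curve by
  construction; closure is re-verified by graph separation of veins from
  body.
* **Roof line** — geodesic between the roof-facing points of the two
  superior-PV rings, widened to width/2 on each side.
* **POBI** — roof line plus an inferior posterior line between the
  annulus-facing points of the inferior-PV rings; the box closes against the
  CPVI rings (verified by separating a posterior-wall node from the anterior
  body).
* **AL** — anterior annulus (node nearest Bachmann's insertion) to the
  RSPV-ring/roof junction.
* **LLI** — LIPV ring to the lateral annulus.
* **CFAE** — nodes with mapped cycle length < 120 ms, taken greedily in
  ascending CL (ties by node index), stopping before the cumulative area
  reaches 5% of the conductive atrial area (strict "less than").

## CFAE mapping

Cycle length per node = mean interval between activations (upward −40 mV
crossings with a 50 ms refractory) of the simulated transmembrane voltage,
sampled at 1 ms over the final 4 s of the pre-ablation fibrillation segment.
Nodes with fewer than two activations are undefined (CL = +∞, never
ablated).  This is a voltage surrogate for clinical bipolar-electrogram
fractionation mapping; no electrogram synthesis is attempted.

## Induction of fibrillatory activity

Three routes, tried in configurable order, each ending in a sustained-
activity check (≥1 depolarized node at every 100 ms checkpoint of a 1 s
observation window):

1. **Rapid pacing** (the clinical protocol): 24 stimuli at Bachmann's bundle
   — 8 beats each at cycle lengths 200, 190, 180 ms.
2. **Cross-field S1–S2**: planar S1 from one pole, delayed orthogonal
   half-field S2 scanned over the vulnerable window.
3. **Phase-distributed perimitral seed**: every node is set to the state of
   a steadily paced cell (cycle 230 ms) at a phase proportional to its angle
   around the mitral-annulus axis, which launches a rotating wave around the
   annulus; the polar cap opposite the annulus, where phases would collide,
   is set to a single mid-plateau phase.

On homogeneous synthetic atria, routes 1 and 2 essentially never yield
sustained reentry — without electrophysiological heterogeneity there is no
wavebreak substrate, and the ~50–60 mm wavelength (0.4 m/s × ~140 ms
refractoriness) barely fits the chamber.  Route 3 reliably produces 1.5–4 s
of fibrillatory activity dominated by the perimitral circuit (the ~75 mm
path around the non-conductive annulus exceeds the wavelength).  Results
record which route induced.

## Termination detection and ranking

A run terminates at the earliest sample from which the per-sample maximum
voltage over all conductive non-ablated nodes stays below
rest + 10% of (recording peak − rest) through the end of the observation —
i.e. total wavelet extinction at 90% repolarization.  Because the tissue is
deterministic and has no automaticity, a branch is cut short once no node
has been depolarized for 100 ms.  Protocols are ranked: terminated runs by
ascending time from ablation onset, non-terminated last; ties by fewer
ablated nodes, then canonical protocol order.  All five protocols branch
from the *same* saved fibrillating state at ablation onset, so the ranking
isolates the lesion-set effect.

## Desk-scale study conditions

The clinical configuration (4 s pre-ablation wait, 25 s horizon,
10⁵–10⁶-node meshes) is the `RunConfig` default.  The test suite's cohort
runs use the package's desk-scale conditions: ~2,400-node atria (mean edge
≈ 2.4 mm, diffusivity re-calibrated for that spacing), phase-seed induction,
0.5 s sustained-activity window, 1.5 s pre-ablation wait, 2.5 s post-ablation
horizon, three atrium seeds.  These sizes were chosen so a full five-protocol
study runs in minutes on one CPU while preserving the mechanism under test;
on them the engine reproduces the expected qualitative ordering — lesion
sets containing an anterior line or lateral isthmus line (which transect the
perimitral circuit) terminate within ~0.3–0.4 s, while CPVI alone, CPVI+POBI
and CPVI+CFAE usually do not terminate within the horizon.

## Known limitations

* Homogeneous monolayer: no fibrosis, fibers, or thickness variation, so
  absolute termination rates and times are not comparable to patient-cohort
  statistics; only the qualitative protocol ordering is meaningful here.
* The remodeled cell's resting Vm (−83.1 mV) and APD90 (202.6 ms) differ by
  ~3% and ~5% from the reference values reported for the unpublished
  modified model variant (see above).
* Graph geodesics (not exact polyhedral geodesics) define lesion lines;
  sub-millimetre path optimality is immaterial once lines are widened to
  4 mm.
* Under-resolved fronts at desk-scale spacings make the numerical CV
  resolution-dependent; always use `calibrate_for_mesh` for a new mesh.
* Phase-seeded fibrillation on synthetic atria self-terminates within a few
  seconds, so the 4 s wait / 25 s horizon of the clinical protocol is only
  exercised end-to-end on cell- and strip-scale checks, not in the cohort
  smoke runs.
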