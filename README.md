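# vablate — virtual atrial-fibrillation ablation on monodomain atrial models

Catheter ablation of persistent atrial fibrillation (AF) has no agreed-on
optimal lesion set beyond pulmonary-vein isolation.  One clinically tested
answer is to *simulate* the candidate lesion sets on a model of the
patient's own atrium before the procedure and hand the operator the one
that terminates the simulated AF fastest.  `vablate` implements that
engine end to end for computational electrophysiologists: a monodomain
reaction–diffusion solver on a triangulated left-atrial (LA) surface, an
AF-remodeled human atrial myocyte model, the five clinical ablation
protocols, electrogram-surrogate (CFAE) mapping, and termination-time
ranking — all exercisable on built-in synthetic atria, no patient data
required.

## The model

Membrane potential on the atrial wall (a 1.89 mm constant-thickness
monolayer) follows the monodomain equation

```
∂Vm/∂t = D ∇²Vm − (I_ion + I_s)
```

discretized as a cotangent-weighted, area-lumped surface Laplacian.  The
effective diffusivity `D` is not a free parameter: it is calibrated so a
planar wavefront on a reference tissue strip travels at 0.4 m/s, the human
atrial conduction velocity.  `I_ion` is the Courtemanche–Ramirez–Nattel
(1998) human atrial action-potential model (21 state variables), with
persistent-AF electrical remodeling as four conductance scalings:
I_to −80%, I_CaL −40%, I_Kur −50%, I_K1 +50%.

The virtual experiment per atrium: induce fibrillatory reentry, wait 4 s,
clamp one lesion set permanently to −80.6 mV (conduction block), observe up
to 25 s, and call termination when the whole chamber is ≥90% repolarized
with no further activation.  Five lesion sets are compared: CPVI
(circumferential PV isolation), CPVI+POBI (posterior box), CPVI+POBI+AL
(anterior line), CPVI+RL+LLI (roof + lateral isthmus lines), and CPVI+CFAE
(shortest-cycle-length regions, <120 ms, capped at 5% of atrial area).

## Worked example

`examples/virtual_ablation_study.py` runs the whole pipeline on a synthetic
atrium (seed 2, ~2,400 nodes, desk-scale timeline):

```
calibrating diffusivity for this mesh resolution ...
  D = 0.483 mm^2/ms, planar CV = 0.399 m/s
reentry induced: True (route: phase_seed)
CFAE map: median CL 282 ms over 2314 nodes

ranked lesion sets (fastest AF termination first):
  CPVI+POBI+AL      378 ms   ablated  2140 mm^2
  CPVI+RL+LLI       443 ms   ablated  1636 mm^2
  CPVI              not terminated   ablated  1386 mm^2
  CPVI+CFAE         not terminated   ablated  1386 mm^2
  CPVI+POBI         not terminated   ablated  1792 mm^2
```

Reading the numbers: the diffusivity calibration hit the 0.4 m/s target on
a strip matching this mesh's resolution; a perimitral reentrant wave was
seeded and was still fibrillating at ablation onset; the CFAE map's cycle
lengths (~282 ms median) sit far above the 120 ms ablation threshold, so
the CFAE protocol adds nothing here.  The two lesion sets that transect the
perimitral corridor — the anterior line (AL) and the lateral isthmus line
(LLI) — extinguish the reentry within half a second, the anterior-line set
fastest; vein isolation alone leaves the circuit intact through the
horizon.  That is the qualitative protocol ordering reported for this class
of models on patient anatomies.

Other examples (each runs standalone and prints what it computes):
`single_cell_remodeling.py` (resting Vm −81.2 → −83.1 mV, APD90 295 →
203 ms under remodeling), `cv_calibration.py`, `synthetic_atrium.py`,
`lesion_sets.py`.

A thin CLI wraps the same pipeline:

```bash
vablate run --mesh synthetic --seed 2 --protocol all --out out/
vablate make-mesh --seed 7 --nodes 2500 --out la.ply
```

writing `results.json`, `results.csv` and a run log; patient meshes load
from STL/PLY/OBJ/legacy-VTK with a JSON/YAML landmark spec.

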