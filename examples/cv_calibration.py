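"""Conduction-velocity calibration of the monodomain diffusivity.

The only tissue-scale constraint of the model is the planar conduction
velocity (0.4 m/s, human atrial value).  This script calibrates the
effective diffusivity on the reference strip, then shows the continuum
sqrt(D) scaling by re-measuring at 4x the calibrated diffusivity.
"""

from vablate import CellParams, apply_af_remodeling, calibrate_diffusion, find_resting_state
from vablate import measure_planar_cv, rectangular_strip

cell = apply_af_remodeling(CellParams())
strip = rectangular_strip()  # 40 x 8 mm, 0.5 mm spacing

d, cv = calibrate_diffusion(0.4, cell, strip)
print(f"calibrated diffusivity D = {d:.4f} mm^2/ms  ->  CV = {cv:.3f} m/s")

resting = find_resting_state(cell)
cv4 = measure_planar_cv(4.0 * d, cell, resting, strip)
print(f"at 4x the diffusivity      ->  CV = {cv4:.3f} m/s  (sqrt scaling predicts {2*cv:.3f})")
print()
print("A wavefront's speed grows with the square root of tissue coupling, so")
print("quadrupling D roughly doubles CV.  The excess over the prediction is a")
print("resolution effect: at the calibrated D the ~0.3 mm depolarization front")
print("is under-resolved on the 0.5 mm strip, which depresses the baseline CV.")
print("This is why diffusivity must be re-calibrated per mesh resolution")
print("(see calibrate_for_mesh and docs/methods.md).")
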