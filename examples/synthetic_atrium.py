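"""Generate a synthetic landmarked left atrium and export it.

The generator builds an ellipsoidal shell with four pulmonary-vein tubes,
a mitral-annulus opening and an appendage bulge, and labels the eight
anatomical landmark node sets every lesion protocol needs.  Writes the
surface as PLY (+ JSON landmark sidecar) and as a VTU file with the node
areas as a scalar field.
"""

from vablate import SyntheticLAParams, extrude_monolayer, generate_synthetic_la
from vablate import io as vio

params = SyntheticLAParams(random_seed=1, target_node_count=2500)
surface = generate_synthetic_la(params)
mono = extrude_monolayer(surface)  # 1.89 mm constant-thickness monolayer

print(f"vertices   : {surface.n_vertices}")
print(f"triangles  : {surface.n_triangles}")
print(f"Euler char : {surface.euler_characteristic()}  (sphere with 5 openings = -3)")
print(f"area       : {mono.total_area():.0f} mm^2")
print(f"volume     : {mono.shell_volume() / 1000:.1f} mL of wall tissue")
for name, nodes in surface.landmark_sets.items():
    print(f"  landmark {name:15s} {len(nodes):4d} nodes")

vio.save_surface_mesh(surface, "synthetic_la.ply")
vio.write_vtu("synthetic_la.vtu", surface, {"node_area": mono.node_area})
print("\nwrote synthetic_la.ply (+ landmark sidecar) and synthetic_la.vtu")
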