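"""Export QC surface meshes: scala tube and membrane patch.

Fits the canonical scala model to a phantom's landmarks, exports its
tube surface, and exports the triangle mesh of the membrane patch the
interface classifier identified, both as PLY files for inspection in
any mesh viewer (e.g. MeshLab, 3D Slicer).
"""

from pathlib import Path

import numpy as np
import trimesh

from rwniche import (
    build_frame,
    clip_to_cylinder,
    cylinder_radius,
    extract_rwm_interface,
    fit_scala,
    generate_phantom,
    st_entrance_direction,
)

outdir = Path("example_output")
outdir.mkdir(exist_ok=True)

volume, mask, landmarks, _ = generate_phantom(seed=2)
frame = build_frame(landmarks)
scala = fit_scala(landmarks)
radius = cylinder_radius(frame, landmarks.overhang_tip)
clipped = clip_to_cylinder(mask, frame, radius)
surface = extract_rwm_interface(
    clipped, volume, st_entrance_direction(scala), frame=frame, clip_radius=radius
)

scala.export_mesh(outdir / "scala_tube.ply")
membrane = trimesh.Trimesh(
    vertices=surface.mesh_vertices, faces=surface.mesh_faces, process=False
)
membrane.export(outdir / "membrane.ply")

counts = surface.class_counts()
print(f"wrote {outdir/'scala_tube.ply'} and {outdir/'membrane.ply'}")
print(f"boundary faces: {counts['bone_contact']} bone-contact, "
      f"{counts['soft']} soft, {counts['mouth']} mouth")
print(f"membrane component: {int(surface.is_rwm.sum())} faces, "
      f"{surface.rwm_corrected_area():.3f} mm^2 (normal-corrected), "
      f"{surface.rwm_mesh_area:.3f} mm^2 (mesh triangles)")
print("The membrane is the largest soft component whose mean outward normal")
print("faces the scala-tympani entrance direction", np.round(st_entrance_direction(scala), 3))
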