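"""Isosurface a mask, repair the mesh, and re-surface it by shrink-wrap.

clean_mesh removes defective facets (duplicates, dangling triangles) and
guarantees watertightness; shrinkwrap replaces a surface by projecting an
enclosing sphere onto it, yielding a clean genus-0 equivalent surface.
"""

import numpy as np

import bolusforge as bf
from bolusforge.core import TriMesh, Volume3D

# digitised sphere, r = 20 mm
n = 48
x = np.arange(n) - n / 2 + 0.5
X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
mask = Volume3D(((X**2 + Y**2 + Z**2) <= 20.0**2).astype(float), (1, 1, 1))

mesh = bf.extract_isosurface(mask)
analytic = 4 / 3 * np.pi * 20**3
print(f"isosurface: {mesh.n_faces} facets, volume {mesh.volume_mm3():.0f} mm^3 "
      f"(analytic {analytic:.0f}, {100 * (mesh.volume_mm3() / analytic - 1):+.2f}%)")

# inject a defect: an isolated dangling triangle far from the surface
nv = mesh.n_vertices
broken = TriMesh(
    np.vstack([mesh.vertices, [[60, 60, 60], [62, 60, 60], [60, 62, 60]]]),
    np.vstack([mesh.faces, [[nv, nv + 1, nv + 2]]]),
)
repaired = bf.clean_mesh(broken)
print(f"clean_mesh removed {broken.n_faces - repaired.n_faces} defective facet(s); "
      f"watertight={bf.is_watertight(repaired)}")

wrapped = bf.shrinkwrap(repaired, iterations=10)
center = repaired.vertices.mean(axis=0)
r = np.linalg.norm(wrapped.vertices - center, axis=1)
print(f"shrink-wrap: {wrapped.n_faces} facets, mean radial error "
      f"{np.abs(r - 20).mean():.3f} mm (new surface reproduces the target)")
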