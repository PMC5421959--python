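"""Mask -> surface conversion and mesh repair.

Three stages mirror the virtual-bolus workflow: extract a triangulated
isosurface from a binary mask, eliminate defective facets, and (optionally)
re-surface the object by shrink-wrapping a sphere onto it — an enclosing
sphere mesh is iteratively relaxed and projected onto the target until it
reproduces the target surface with clean, genus-0 topology.

Watertightness is defined strictly: every edge incident to exactly two
faces. That is the printability contract every emitted bolus mesh must
satisfy.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .core import TriMesh, Volume3D

__all__ = [
    "extract_isosurface",
    "clean_mesh",
    "shrinkwrap",
    "is_watertight",
    "MeshRepairError",
]


class MeshRepairError(RuntimeError):
    """Raised when a mesh cannot be repaired to a watertight state."""


def _edge_counts(faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return uniq, counts


def is_watertight(mesh: TriMesh) -> bool:
    """True iff every edge is shared by exactly two faces."""
    if mesh.n_faces == 0:
        return False
    _, counts = _edge_counts(mesh.faces)
    return bool(np.all(counts == 2))


def extract_isosurface(
    mask: Volume3D, iso: float = 0.5, smooth_sigma_vox: float = 0.5
) -> TriMesh:
    """Marching-cubes surface of a binary mask, in world (mm) coordinates.

    The mask is pre-smoothed with a Gaussian of ``smooth_sigma_vox``
    voxels (default half a voxel) before contouring at ``iso`` so the
    printed part does not inherit staircase normals from the voxel grid.
    The enclosed volume approximates the mask's voxel volume.
    """
    values = np.asarray(mask.values, dtype=np.float64)
    if not np.any(values > 0):
        raise ValueError("cannot extract a surface from an empty mask")
    if not (0.0 < iso < 1.0):
        raise ValueError(f"iso level must be in (0, 1), got {iso}")
    binary = (values > 0).astype(np.float64)
    # pad so surfaces touching the grid boundary still close
    binary = np.pad(binary, 1, mode="constant")
    if smooth_sigma_vox > 0:
        smoothed = ndimage.gaussian_filter(binary, smooth_sigma_vox)
        # smoothing can erase structures only a voxel or two wide; fall
        # back to the raw mask rather than losing the surface
        if smoothed.max() > iso:
            binary = smoothed
    verts, faces, _, _ = measure.marching_cubes(binary, level=iso)
    verts = (verts - 1.0) * np.asarray(mask.spacing_mm) + np.asarray(mask.origin_mm)
    out = TriMesh(verts, faces, provenance="extract_isosurface")
    tm = out.to_trimesh()
    if tm.volume < 0:
        out.faces = out.faces[:, ::-1].copy()
    return out


def clean_mesh(mesh: TriMesh) -> TriMesh:
    """Eliminate defective facets and return a watertight mesh.

    Removes duplicate and degenerate faces, drops open face-connected
    components (e.g. isolated dangling triangles) when a closed component
    exists, discards unreferenced vertices and enforces consistent
    winding. Raises :class:`MeshRepairError` if no watertight result can
    be reached — never fails silently. Idempotent on clean input.
    """
    if mesh.n_faces == 0:
        raise MeshRepairError("empty mesh")
    tm = mesh.to_trimesh()
    tm.update_faces(tm.nondegenerate_faces())
    tm.update_faces(tm.unique_faces())
    # drop open components if any closed component exists
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        closed = [p for p in parts if p.is_watertight]
        if closed:
            tm = trimesh.util.concatenate(closed)
    tm.remove_unreferenced_vertices()
    tm.fix_normals()
    if tm.volume < 0:
        tm.invert()
    out = TriMesh.from_trimesh(tm, provenance=f"clean({mesh.provenance})")
    if not is_watertight(out):
        raise MeshRepairError(
            "mesh is unrecoverably non-manifold after repair "
            f"(faces={out.n_faces})"
        )
    return out


def _closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on triangle ``tri[i]`` to ``points[i]`` (paired),
    via barycentric clamping."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    v = np.where(np.abs(denom) > 1e-30, vb / np.where(denom == 0, 1, denom), 0.0)
    w = np.where(np.abs(denom) > 1e-30, vc / np.where(denom == 0, 1, denom), 0.0)
    out = a + v[:, None] * ab + w[:, None] * ac  # interior candidate
    # vertex regions
    out = np.where(((d1 <= 0) & (d2 <= 0))[:, None], a, out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[:, None], b, out)
    out = np.where(((d6 >= 0) & (d5 <= d6))[:, None], c, out)
    # edge AB
    on_ab = (d1 * d4 - d3 * d2 <= 0) & (d1 >= 0) & (d3 <= 0)
    t_ab = np.clip(d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0, 1)
    out = np.where(on_ab[:, None], a + t_ab[:, None] * ab, out)
    # edge AC
    on_ac = (d5 * d2 - d1 * d6 <= 0) & (d2 >= 0) & (d6 <= 0)
    t_ac = np.clip(d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0, 1)
    out = np.where(on_ac[:, None], a + t_ac[:, None] * ac, out)
    # edge BC
    on_bc = (d3 * d6 - d5 * d4 <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    t_bc = np.clip(
        (d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, 1, (d4 - d3) + (d5 - d6)),
        0,
        1,
    )
    out = np.where(on_bc[:, None], b + t_bc[:, None] * (c - b), out)
    return out


class _SurfaceProjector:
    """Approximate nearest-point-on-surface queries: a KD-tree over
    per-face sample points proposes candidate faces, then the exact
    point-triangle projection is taken over the candidates."""

    def __init__(self, mesh: TriMesh, k: int = 6):
        from scipy.spatial import cKDTree

        tri = mesh.vertices[mesh.faces]
        centroids = tri.mean(axis=1)
        mids = 0.5 * (tri + np.roll(tri, 1, axis=1))  # edge midpoints
        samples = np.concatenate([centroids[:, None], tri, mids], axis=1)
        self._face_of = np.repeat(np.arange(len(tri)), samples.shape[1])
        self._tree = cKDTree(samples.reshape(-1, 3))
        self._tri = tri
        self._k = min(k, len(self._face_of))

    def project(self, points: np.ndarray) -> np.ndarray:
        _, idx = self._tree.query(points, k=self._k)
        idx = np.atleast_2d(idx)
        cand_faces = self._face_of[idx]  # (n, k)
        n, k = cand_faces.shape
        flat_pts = np.repeat(points, k, axis=0)
        flat_tri = self._tri[cand_faces.reshape(-1)]
        closest = _closest_point_on_triangles(flat_pts, flat_tri).reshape(n, k, 3)
        d2 = ((closest - points[:, None, :]) ** 2).sum(axis=2)
        best = np.argmin(d2, axis=1)
        return closest[np.arange(n), best]


def _icosphere(center: np.ndarray, radius: float, subdivisions: int) -> TriMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(np.asarray(tm.vertices) + center, np.asarray(tm.faces), "icosphere")


def _vertex_neighbors(n_vertices: int, faces: np.ndarray):
    nbr: list[set[int]] = [set() for _ in range(n_vertices)]
    for a, b, c in faces:
        nbr[a].update((b, c))
        nbr[b].update((a, c))
        nbr[c].update((a, b))
    idx = np.concatenate([np.fromiter(s, dtype=np.int64) for s in nbr])
    counts = np.array([len(s) for s in nbr])
    offsets = np.concatenate([[0], np.cumsum(counts)])
    return idx, offsets, counts


def shrinkwrap(
    target: TriMesh,
    iterations: int = 10,
    step: float = 1.0,
    relax: float = 0.3,
    subdivisions: int = 4,
) -> TriMesh:
    """Re-surface ``target`` by wrapping a sphere onto it.

    Starts from an icosphere enclosing the target and alternates Laplacian
    relaxation (blend ``relax``) with projection of each vertex toward its
    nearest point on the target surface (fraction ``step``). The result
    keeps the sphere's clean genus-0 topology while conforming to the
    target; with ``iterations=0`` the initial bounding sphere is returned
    unchanged. The distance to the target is non-increasing over
    iterations because each iteration ends with the projection step.
    """
    if not is_watertight(target):
        raise ValueError("shrinkwrap requires a watertight target mesh")
    center = target.vertices.mean(axis=0)
    radius = float(np.linalg.norm(target.vertices - center, axis=1).max()) * 1.05
    wrap = _icosphere(center, radius, subdivisions)
    if iterations == 0:
        return wrap

    projector = _SurfaceProjector(target)
    verts = wrap.vertices.copy()
    idx, offsets, counts = _vertex_neighbors(len(verts), wrap.faces)
    for _ in range(int(iterations)):
        if relax > 0:
            sums = np.add.reduceat(verts[idx], offsets[:-1], axis=0)
            means = sums / counts[:, None]
            verts = (1.0 - relax) * verts + relax * means
        closest = projector.project(verts)
        verts = verts + step * (closest - verts)
    return TriMesh(verts, wrap.faces.copy(), provenance=f"shrinkwrap({target.provenance})")
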