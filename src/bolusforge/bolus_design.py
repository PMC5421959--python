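"""Conformal and step bolus design.

The design goal: the bolus's lower surface conforms to the skin and its
upper (beam-entry) surface conforms to an offset of the lung-sided
chest-wall surface, so that chest wall + bolus has uniform depth along
the beam. Concretely, for each en-face ray the chest-wall depth ``d(x)``
is measured from the first body-surface crossing to the first
lung-surface crossing, and the conformal thickness is

    t(x) = clamp(target_depth - d(x), t_min, t_max)

With ``target='auto'`` the target is the maximum depth over the field —
the thinnest bolus achieving uniformity. The conventional step bolus
quantises the same ideal thickness to the nearest available layer sum
(default sheets of 5 mm: {0, 5, 10}), ties broken toward the thicker
layer, which is what produces its characteristic hot/cold spots.

Rays are parallel (infinite-SSD simplification) along the +y axis by
default; the en-face grid is the (x, z) voxel grid of the CT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    BODY,
    BOLUS,
    LUNG_IPSI,
    MaterialSpec,
    PLA,
    StructureSet,
    TriMesh,
    Volume3D,
)
from .surfaces import clean_mesh, extract_isosurface

__all__ = [
    "BeamGeometry",
    "ThicknessMap",
    "BolusDesignParams",
    "chest_wall_depth_map",
    "design_conformal_bolus",
    "design_step_bolus",
    "bolus_mesh",
    "apply_bolus",
]


@dataclass(frozen=True)
class BeamGeometry:
    """A single broad beam: unit axis direction and an en-face aperture.

    ``field_rect`` is (x_min, x_max, z_min, z_max) in mm in the en-face
    plane. Only the +y axis is supported for ray casting (the package's
    declared beam convention); other axes would require resampling.
    """

    axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    field_rect: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("beam axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(a / n))
        if not np.allclose(self.axis, (0.0, 1.0, 0.0)):
            raise ValueError("only the +y beam axis is supported")
        if self.field_rect is not None:
            x0, x1, z0, z1 = self.field_rect
            if x1 <= x0 or z1 <= z0:
                raise ValueError("field_rect must have positive area")


@dataclass
class ThicknessMap:
    """2-D en-face grid of lengths (mm) along the beam axis.

    ``values[ix, iz]`` is the depth/thickness for the ray through voxel
    column (ix, iz); NaN marks rays outside the field or rays whose
    defining surfaces were not crossed.
    """

    values: np.ndarray  # (nx, nz), NaN where undefined
    spacing_mm: tuple[float, float]  # (dx, dz)
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ThicknessMap requires a 2-D array")
        defined = self.values[np.isfinite(self.values)]
        if defined.size and defined.min() < -1e-9:
            raise ValueError("thickness/depth values must be >= 0 where defined")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def like(self, values: np.ndarray) -> "ThicknessMap":
        return ThicknessMap(values, self.spacing_mm, self.origin_mm)


@dataclass
class BolusDesignParams:
    """Knobs of the bolus designer.

    ``target_depth_mm`` is the uniform chest-wall+bolus depth to aim for,
    or ``"auto"`` for the maximum field depth (minimal material);
    ``t_min_mm`` is the minimum printable thickness (2 mm default — the
    thinnest region observed on a printed bolus), ``t_max_mm`` a safety
    cap; ``step_layers_mm`` the attainable conventional-sheet stacks.
    """

    target_depth_mm: float | str = "auto"
    t_min_mm: float = 2.0
    t_max_mm: float = 40.0
    step_layers_mm: tuple[float, ...] = (0.0, 5.0, 10.0)
    constraint_map: np.ndarray | None = None  # optional per-ray thickness cap

    def __post_init__(self) -> None:
        if not (0 <= self.t_min_mm <= self.t_max_mm):
            raise ValueError("need 0 <= t_min_mm <= t_max_mm")
        layers = tuple(sorted(float(v) for v in self.step_layers_mm))
        if not layers:
            raise ValueError("step_layers_mm must not be empty")
        if layers[0] < 0:
            raise ValueError("step layers must be non-negative")
        self.step_layers_mm = layers


def _first_crossing_y(mask: np.ndarray) -> np.ndarray:
    """Per-(x,z) column index of the first True voxel along y; -1 if none."""
    any_hit = mask.any(axis=1)
    first = mask.argmax(axis=1)
    return np.where(any_hit, first, -1)


def _field_mask(tm_shape, spacing, origin, beam: BeamGeometry) -> np.ndarray:
    nx, nz = tm_shape
    x = origin[0] + np.arange(nx) * spacing[0]
    z = origin[1] + np.arange(nz) * spacing[1]
    if beam.field_rect is None:
        return np.ones((nx, nz), dtype=bool)
    x0, x1, z0, z1 = beam.field_rect
    return ((x >= x0) & (x <= x1))[:, None] & ((z >= z0) & (z <= z1))[None, :]


def chest_wall_depth_map(structs: StructureSet, beam: BeamGeometry) -> ThicknessMap:
    """Chest-wall depth along each beam ray.

    Depth = distance from the first BODY-surface crossing (skin) to the
    first LUNG_IPSI-surface crossing, per (x, z) column. Rays that miss
    the lung (or the field) are NaN.
    """
    for role in (BODY, LUNG_IPSI):
        if role not in structs:
            raise KeyError(f"structure {role} required for depth mapping")
    grid = structs.grid
    dy = grid.spacing_mm[1]
    body_y = _first_crossing_y(structs[BODY])
    lung_y = _first_crossing_y(structs[LUNG_IPSI])
    if (body_y < 0).all():
        raise ValueError("beam misses the body entirely")
    spacing2d = (grid.spacing_mm[0], grid.spacing_mm[2])
    origin2d = (grid.origin_mm[0], grid.origin_mm[2])
    infield = _field_mask(body_y.shape, spacing2d, origin2d, beam)
    if not (infield & (body_y >= 0)).any():
        raise ValueError("beam field does not intersect the body")
    depth = (lung_y - body_y).astype(np.float64) * dy
    depth[(body_y < 0) | (lung_y < 0) | (lung_y <= body_y) | ~infield] = np.nan
    return ThicknessMap(depth, spacing2d, origin2d)


def _resolve_target(depth: ThicknessMap, params: BolusDesignParams) -> float:
    if params.target_depth_mm == "auto":
        return float(np.nanmax(depth.values))
    return float(params.target_depth_mm)


def design_conformal_bolus(
    depth: ThicknessMap, params: BolusDesignParams | None = None
) -> ThicknessMap:
    """Per-ray conformal thickness ``clamp(target - depth, t_min, t_max)``.

    Wherever the clamp is inactive, depth + thickness equals the target
    exactly — the uniform-depth design goal. If the target is below the
    maximum field depth while ``t_min`` is 0, uniformity is unattainable
    on the clamped rays; a warning is recorded on the returned map's
    ``values`` (NaN-safe arithmetic, no exception).
    """
    params = params or BolusDesignParams()
    if not depth.defined.any():
        raise ValueError("depth map has no defined rays")
    target = _resolve_target(depth, params)
    with np.errstate(invalid="ignore"):
        t = np.clip(target - depth.values, params.t_min_mm, params.t_max_mm)
    if params.constraint_map is not None:
        t = np.minimum(t, params.constraint_map)
    t[~depth.defined] = np.nan
    return depth.like(t)


def design_step_bolus(
    depth: ThicknessMap, params: BolusDesignParams | None = None
) -> ThicknessMap:
    """Conventional step bolus: ideal thickness quantised to sheet stacks.

    Each ray's ideal thickness (target - depth, floored at 0) is replaced
    by the nearest value in ``step_layers_mm``; ties go to the thicker
    layer (conservative target coverage). The result is piecewise
    constant, with the step edges that cause hot/cold spots.
    """
    params = params or BolusDesignParams()
    if not depth.defined.any():
        raise ValueError("depth map has no defined rays")
    target = _resolve_target(depth, params)
    layers = np.asarray(params.step_layers_mm)
    with np.errstate(invalid="ignore"):
        ideal = np.maximum(target - depth.values, 0.0)
    flat = ideal[depth.defined]
    dist = np.abs(flat[:, None] - layers[None, :])
    # ties -> thicker: among equal distances pick the largest layer
    order = np.argsort(-layers)  # descending layers
    choice = order[np.argmin(dist[:, order], axis=1)]
    out = np.full_like(ideal, np.nan)
    out[depth.defined] = layers[choice]
    return depth.like(out)


def _voxelize_bolus(
    structs: StructureSet, thickness: ThicknessMap
) -> np.ndarray:
    """Binary bolus mask: each ray's thickness swept anteriorly (against
    the beam) from the skin surface."""
    grid = structs.grid
    dy = grid.spacing_mm[1]
    body_y = _first_crossing_y(structs[BODY])
    n_vox = np.zeros_like(body_y)
    t = thickness.values
    ok = np.isfinite(t) & (body_y >= 0)
    n_vox[ok] = np.rint(t[ok] / dy).astype(int)
    mask = np.zeros(grid.shape, dtype=bool)
    ny = grid.shape[1]
    ys = np.arange(ny)[None, :, None]
    start = (body_y - n_vox)[:, None, :]
    stop = body_y[:, None, :]
    mask = (ys >= np.maximum(start, 0)) & (ys < stop) & ok[:, None, :]
    return mask


def bolus_mesh(
    structs: StructureSet,
    beam: BeamGeometry,
    thickness: ThicknessMap,
) -> TriMesh:
    """Printable bolus surface from a thickness map.

    The bolus solid is the difference of two skin-registered objects:
    each ray's thickness is swept from the skin surface outward against
    the beam (lower surface on the skin, upper surface the offset
    lung-conforming surface), voxelised on the CT grid, isosurfaced and
    cleaned to a watertight mesh.
    """
    if BODY not in structs:
        raise KeyError("BODY mask required to seat the bolus on the skin")
    mask = _voxelize_bolus(structs, thickness)
    if not mask.any():
        raise ValueError("bolus has zero volume (all thickness zero or undefined)")
    grid = structs.grid
    vol = Volume3D(mask.astype(np.float64), grid.spacing_mm, grid.origin_mm)
    mesh = extract_isosurface(vol)
    mesh = clean_mesh(mesh)
    mesh.provenance = "bolus_mesh"
    return mesh


def apply_bolus(
    ct: Volume3D,
    structs: StructureSet,
    thickness: ThicknessMap,
    material: MaterialSpec = PLA,
    gel: MaterialSpec | None = None,
) -> tuple[Volume3D, StructureSet]:
    """Place the bolus in the CT: override its voxels with the material HU.

    Returns a new CT whose bolus voxels carry the material's HU (PLA,
    density 1.19 g/cm^3, by default) plus a structure set with a BOLUS
    mask added. If ``gel`` is given, the single sub-voxel layer between
    bolus and skin is set to the coupling-gel HU, emulating the gel used
    to eliminate air gaps at the skin interface.
    """
    if material.density <= 0:
        raise ValueError("material density must be > 0")
    mask = _voxelize_bolus(structs, thickness)
    new_vals = np.asarray(ct.values, dtype=np.float64).copy()
    new_vals[mask] = material.hu
    if gel is not None:
        body_y = _first_crossing_y(structs[BODY])
        shifted = np.zeros_like(mask)
        shifted[:, 1:, :] = mask[:, :-1, :]
        gap = shifted & ~mask & ~structs[BODY]
        new_vals[gap] = gel.hu
    out_structs = structs.copy()
    out_structs.add(BOLUS, mask)
    return ct.copy(values=new_vals), out_structs
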