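"""Shared containers for the bolus pipeline.

Conventions, fixed once for the whole package:

* world coordinates are millimetres;
* voxel indices are 0-based, ``world = origin + index * spacing``;
* axes are (x: right->left, y: anterior->posterior, z: inferior->superior);
* the treatment beam travels along +y unless a :class:`BeamGeometry`
  says otherwise (see :mod:`bolusforge.bolus_design`).

CT intensities are Hounsfield units; relative mass density is recovered
with the single-slope calibration ``rho = max(0, 1 + HU/1000)`` (air -1000
-> 0, water 0 -> 1, lung -700 -> 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping

import numpy as np

__all__ = [
    "AXIS_CONVENTION",
    "Volume3D",
    "StructureSet",
    "MaterialSpec",
    "TriMesh",
    "PLA",
    "COUPLING_GEL",
    "WATER",
    "hu_to_density",
    "BODY",
    "CHEST_WALL",
    "LUNG_IPSI",
    "HEART",
    "BOLUS",
]

AXIS_CONVENTION = "x:R->L, y:A->P, z:I->S (mm)"

# canonical structure roles
BODY = "BODY"
CHEST_WALL = "CHEST_WALL"
LUNG_IPSI = "LUNG_IPSI"
HEART = "HEART"
BOLUS = "BOLUS"


def hu_to_density(hu: np.ndarray | float) -> np.ndarray | float:
    """Relative mass density from Hounsfield units (single-slope CT calibration)."""
    return np.maximum(0.0, 1.0 + np.asarray(hu, dtype=float) / 1000.0)


@dataclass
class Volume3D:
    """A scalar voxel grid (HU or Gy) with physical spacing and origin."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: str = AXIS_CONVENTION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("Volume3D requires a 3-D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def same_grid(self, other: "Volume3D") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def world_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre world coordinates along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + np.arange(n) * self.spacing_mm[axis]

    def copy(self, values: np.ndarray | None = None) -> "Volume3D":
        return replace(self, values=self.values.copy() if values is None else values)


@dataclass
class StructureSet:
    """Named binary masks sharing one :class:`Volume3D` grid.

    Required roles for the design pipeline are BODY, CHEST_WALL, LUNG_IPSI
    and HEART; BOLUS is added by :func:`bolusforge.bolus_design.apply_bolus`.
    """

    grid: Volume3D
    masks: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            self.masks[name] = self._check(name, m)

    def _check(self, name: str, mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != self.grid.shape:
            raise ValueError(
                f"mask {name!r} shape {mask.shape} != grid shape {self.grid.shape}"
            )
        return mask

    def add(self, name: str, mask: np.ndarray) -> None:
        self.masks[name] = self._check(name, mask)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def roles(self) -> list[str]:
        return sorted(self.masks)

    def volume_mm3(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.grid.voxel_volume_mm3

    def copy(self) -> "StructureSet":
        return StructureSet(self.grid, {k: v.copy() for k, v in self.masks.items()})


@dataclass(frozen=True)
class MaterialSpec:
    """A bolus/interface material: mass density (g/cm^3) and representative HU."""

    name: str
    density: float
    hu: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")


# Built-in materials. HU chosen to be consistent with the single-slope
# calibration so that density overrides and HU overrides agree.
PLA = MaterialSpec("PLA", density=1.19, hu=190.0)
COUPLING_GEL = MaterialSpec("coupling_gel", density=1.02, hu=20.0)
WATER = MaterialSpec("water", density=1.00, hu=0.0)


@dataclass
class TriMesh:
    """Triangulated surface in millimetre world coordinates."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int
    provenance: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, tm, provenance: str = "") -> "TriMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), provenance)

    def volume_mm3(self) -> float:
        """Signed enclosed volume via the divergence theorem (positive for
        outward-wound watertight meshes)."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)
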