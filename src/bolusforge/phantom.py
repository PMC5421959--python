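"""Synthetic hemithorax CT phantoms.

The phantom emulates the geometry the conformal-bolus pipeline assumes: a
smooth anterior chest (skin) surface, a chest wall whose thickness along
the beam axis (+y) varies smoothly in the lateral plane — the "missing
tissue" a bolus compensates — an ipsilateral lung immediately behind the
wall, and a spherical heart embedded in the lung. HU values come from a
material table plus seeded Gaussian noise, so identical spec + seed gives
a bit-identical phantom.

Thickness variation is a band-limited random field: a sum of
low-frequency sinusoids with seeded random orientations and phases,
rescaled so the peak-to-peak amplitude equals ``chest_wall_variation_mm``
exactly. This mimics anatomical undulation without sharp artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import (
    BODY,
    CHEST_WALL,
    HEART,
    LUNG_IPSI,
    StructureSet,
    Volume3D,
)

__all__ = ["PhantomSpec", "generate_chest_phantom", "edit_structures"]

DEFAULT_HU = {
    "air": -1000.0,
    "lung": -700.0,
    "soft_tissue": 40.0,
    "chest_wall": 40.0,
    "heart": 40.0,
}

MIN_AXIS_VOXELS = 8


@dataclass
class PhantomSpec:
    """Parameters of a synthetic hemithorax phantom.

    Lengths in mm. ``spacing_mm`` may be anisotropic, e.g. ``(1, 1, 3)``
    for 1 mm in-plane pixels with 3 mm slices.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    chest_wall_base_mm: float = 15.0
    chest_wall_variation_mm: float = 10.0
    variation_wavelength_mm: float = 60.0
    skin_y_mm: float = 30.0
    skin_curvature_mm: float = 4.0
    body_margin_mm: float = 4.0
    lung_margin_mm: float = 12.0
    heart_center_mm: tuple[float, float, float] = (28.0, 64.0, 30.0)
    heart_radius_mm: float = 12.0
    hu_table: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    noise_sd_hu: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(n < MIN_AXIS_VOXELS for n in self.grid_shape):
            raise ValueError(
                f"grid too small: every axis needs >= {MIN_AXIS_VOXELS} voxels, "
                f"got {self.grid_shape}"
            )
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be strictly positive")
        for name in (
            "chest_wall_base_mm",
            "variation_wavelength_mm",
            "heart_radius_mm",
            "lung_margin_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.chest_wall_variation_mm < 0:
            raise ValueError("chest_wall_variation_mm must be >= 0")
        if self.chest_wall_base_mm <= self.chest_wall_variation_mm / 2.0:
            raise ValueError(
                "chest wall would vanish: need base > variation/2 "
                f"({self.chest_wall_base_mm} <= {self.chest_wall_variation_mm / 2})"
            )

    # round-trip through a JSON config file
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        d = json.loads(Path(path).read_text())
        for key in ("grid_shape", "spacing_mm", "heart_center_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _variation_field(
    x_mm: np.ndarray, z_mm: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited random undulation, rescaled to exactly [-1/2, +1/2] *
    variation (peak-to-peak = chest_wall_variation_mm on the grid)."""
    if spec.chest_wall_variation_mm == 0:
        return np.zeros((x_mm.size, z_mm.size))
    xx, zz = np.meshgrid(x_mm, z_mm, indexing="ij")
    f = np.zeros_like(xx)
    k0 = 2.0 * np.pi / spec.variation_wavelength_mm
    for _ in range(3):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        k = k0 * rng.uniform(0.7, 1.3)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        f += amp * np.sin(k * (xx * np.cos(theta) + zz * np.sin(theta)) + phase)
    lo, hi = f.min(), f.max()
    f = (f - lo) / (hi - lo) - 0.5  # in [-0.5, 0.5], extremes attained
    return f * spec.chest_wall_variation_mm


def generate_chest_phantom(spec: PhantomSpec) -> tuple[Volume3D, StructureSet]:
    """Build the HU volume and structure masks for a hemithorax phantom.

    Returns a :class:`Volume3D` of Hounsfield units and a
    :class:`StructureSet` with BODY, CHEST_WALL, LUNG_IPSI and HEART.
    Deterministic: identical spec (including seed) gives bit-identical
    output.
    """
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.spacing_mm
    rng = np.random.default_rng(spec.seed)

    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    z = np.arange(nz) * dz

    # anterior skin surface: gently curved in x, flat in z
    cx = x.mean()
    half_w = max(x.max() - cx, 1.0)
    y_skin = spec.skin_y_mm + spec.skin_curvature_mm * ((x - cx) / half_w) ** 2

    wall = spec.chest_wall_base_mm + _variation_field(x, z, spec, rng)

    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]

    m = spec.body_margin_mm
    lateral = (X >= m) & (X <= x.max() - m) & (Z >= m) & (Z <= z.max() - m)
    body = lateral & (Y >= y_skin[:, None, None]) & (Y <= y.max() - m)

    lm = spec.lung_margin_mm
    footprint = (X >= lm) & (X <= x.max() - lm) & (Z >= lm) & (Z <= z.max() - lm)
    y_wall_back = (y_skin[:, None] + wall)[:, None, :]  # (nx, 1, nz)
    lung = body & footprint & (Y >= y_wall_back) & (Y <= y.max() - 2 * m)

    chest_wall = body & footprint & (Y < y_wall_back)

    hx, hy, hz = spec.heart_center_mm
    heart = ((X - hx) ** 2 + (Y - hy) ** 2 + (Z - hz) ** 2) <= spec.heart_radius_mm**2
    heart &= body & ~chest_wall
    lung &= ~heart

    hu = np.full(spec.grid_shape, spec.hu_table["air"], dtype=np.float64)
    hu[body] = spec.hu_table["soft_tissue"]
    hu[chest_wall] = spec.hu_table["chest_wall"]
    hu[lung] = spec.hu_table["lung"]
    hu[heart] = spec.hu_table["heart"]
    if spec.noise_sd_hu > 0:
        hu += rng.normal(0.0, spec.noise_sd_hu, size=spec.grid_shape)

    vol = Volume3D(hu, spec.spacing_mm)
    structs = StructureSet(
        vol,
        {BODY: body, CHEST_WALL: chest_wall, LUNG_IPSI: lung, HEART: heart},
    )
    return vol, structs


def edit_structures(structs: StructureSet, remove: list[str]) -> StructureSet:
    """Return a copy of the structure set with the listed masks removed.

    This is how "erasing" an adjacent organ from the images is realised:
    the organ's mask is dropped so it no longer participates in surface
    extraction. Removing BODY is refused — the pipeline cannot run
    without the external contour.
    """
    for role in remove:
        if role not in structs:
            raise KeyError(f"structure {role!r} not present")
        if role == BODY:
            raise ValueError("refusing to remove BODY: pipeline requires it")
    out = structs.copy()
    for role in remove:
        del out.masks[role]
    return out
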