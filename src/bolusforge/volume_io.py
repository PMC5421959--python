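"""Readers/writers for the formats the pipeline touches.

Volumes: NIfTI (.nii/.nii.gz via nibabel) and NRRD (.nrrd, a minimal
raw-encoding codec written here). Meshes: binary and ASCII STL.

STL stores no units; this toolkit declares millimetres everywhere. The
binary dialect is the classic fixed layout — an 80-byte header, a
little-endian uint32 triangle count, then 50 bytes per facet (normal,
three vertices as float32, and a 2-byte attribute count) — so a mesh of
``m`` facets occupies exactly ``80 + 4 + 50*m`` bytes. Binary writes
round-trip vertex coordinates bit-exactly at float32 precision; vertex
deduplication on read uses exact coordinate match (no epsilon), favouring
reproducibility over convenience.
"""

from __future__ import annotations

import struct
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import TriMesh, Volume3D

__all__ = ["read_volume", "write_volume", "read_stl", "write_stl"]

_STL_HEADER = b"bolusforge STL (units: mm)"


class VolumeFormatError(ValueError):
    """Unrecognised or corrupt volume file."""


class MeshFormatError(ValueError):
    """Unrecognised or corrupt mesh file."""


# --------------------------------------------------------------------- NIfTI


def _volume_suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    raise VolumeFormatError(f"unrecognised volume format: {path.name}")


def write_volume(vol: Volume3D, path: str | Path) -> None:
    path = Path(path)
    kind = _volume_suffix(path)
    if kind == "nifti":
        affine = np.diag(list(vol.spacing_mm) + [1.0])
        affine[:3, 3] = vol.origin_mm
        img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), affine)
        nib.save(img, str(path))
    else:
        _write_nrrd(vol, path)


def read_volume(path: str | Path) -> Volume3D:
    path = Path(path)
    kind = _volume_suffix(path)
    if kind == "nifti":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(affine[i, i]) for i in range(3))
        if any(s <= 0 for s in spacing):
            raise VolumeFormatError(f"non-positive spacing in header: {spacing}")
        origin = tuple(float(affine[i, 3]) for i in range(3))
        return Volume3D(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)
    return _read_nrrd(path)


# ---------------------------------------------------------------------- NRRD
# Minimal NRRD0004 codec: raw little-endian encoding, 3-D, axis 0 fastest
# (the format's native layout, i.e. Fortran order relative to `sizes`).

_NRRD_DTYPES = {"double": "<f8", "float": "<f4", "uint8": "|u1", "int16": "<i2"}


def _write_nrrd(vol: Volume3D, path: Path) -> None:
    a = np.asarray(vol.values, dtype=np.float64)
    dirs = " ".join(
        "({},{},{})".format(*(vol.spacing_mm[i] if j == i else 0.0 for j in range(3)))
        for i in range(3)
    )
    header = (
        "NRRD0004\n"
        "# bolusforge volume (units: mm)\n"
        "type: double\n"
        "dimension: 3\n"
        "sizes: {} {} {}\n"
        "space dimension: 3\n"
        "space directions: {}\n"
        "space origin: ({},{},{})\n"
        "endian: little\n"
        "encoding: raw\n\n"
    ).format(*a.shape, dirs, *vol.origin_mm)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.asfortranarray(a).tobytes(order="F"))


def _read_nrrd(path: Path) -> Volume3D:
    raw = Path(path).read_bytes()
    sep = raw.find(b"\n\n")
    if not raw.startswith(b"NRRD") or sep < 0:
        raise VolumeFormatError(f"not a NRRD file: {path.name}")
    fields: dict[str, str] = {}
    for line in raw[:sep].decode("ascii", "replace").splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, val = line.split(":", 1)
        fields[key.strip()] = val.strip()
    try:
        sizes = tuple(int(s) for s in fields["sizes"].split())
        dtype = _NRRD_DTYPES[fields["type"]]
        if fields.get("encoding", "raw") != "raw":
            raise VolumeFormatError("only raw encoding supported")
        spacing = []
        for vec in fields["space directions"].replace(") (", ")|(").split("|"):
            comps = [float(c) for c in vec.strip("() ").split(",")]
            spacing.append(comps[len(spacing)])
        origin = tuple(
            float(c) for c in fields["space origin"].strip("() ").split(",")
        )
    except (KeyError, ValueError, IndexError) as exc:
        raise VolumeFormatError(f"corrupt NRRD header in {path.name}: {exc}") from exc
    if any(s <= 0 for s in spacing):
        raise VolumeFormatError(f"non-positive spacing in header: {spacing}")
    data = np.frombuffer(raw[sep + 2 :], dtype=dtype)
    if data.size != int(np.prod(sizes)):
        raise VolumeFormatError("NRRD payload size does not match sizes field")
    values = data.reshape(sizes, order="F").astype(np.float64)
    return Volume3D(values, tuple(spacing), origin)


# ----------------------------------------------------------------------- STL

_FACET_DTYPE = np.dtype(
    [("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")]
)


def write_stl(mesh: TriMesh, path: str | Path, dialect: str = "stl_binary") -> None:
    """Write a mesh as STL. ``dialect`` is ``stl_binary`` or ``stl_ascii``."""
    if mesh.n_faces == 0:
        raise MeshFormatError("refusing to write an empty mesh")
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, norms, out=np.zeros_like(normals), where=norms > 0)
    path = Path(path)
    if dialect == "stl_binary":
        rec = np.zeros(mesh.n_faces, dtype=_FACET_DTYPE)
        rec["normal"] = normals.astype(np.float32)
        rec["verts"] = tri.astype(np.float32)
        with open(path, "wb") as fh:
            fh.write(_STL_HEADER.ljust(80, b"\0"))
            fh.write(struct.pack("<I", mesh.n_faces))
            fh.write(rec.tobytes())
    elif dialect == "stl_ascii":
        lines = ["solid bolusforge"]
        for n, t in zip(normals, tri):
            lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid bolusforge\n")
        path.write_text("\n".join(lines))
    else:
        raise MeshFormatError(f"unknown STL dialect: {dialect}")


def _dedupe(tri: np.ndarray, provenance: str) -> TriMesh:
    """Rebuild an indexed mesh from facet soup by exact coordinate match."""
    flat = tri.reshape(-1, 3)
    verts, inverse = np.unique(flat, axis=0, return_inverse=True)
    return TriMesh(verts.astype(np.float64), inverse.reshape(-1, 3), provenance)


def read_stl(path: str | Path) -> TriMesh:
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 15:
        raise MeshFormatError(f"truncated STL file: {path.name}")
    if raw.lstrip()[:5] == b"solid" and b"facet" in raw[:1024]:
        return _read_stl_ascii(raw, path.name)
    if len(raw) < 84:
        raise MeshFormatError(f"truncated STL file: {path.name}")
    (count,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * count
    if len(raw) != expected:
        raise MeshFormatError(
            f"binary STL size mismatch: header promises {count} facets "
            f"({expected} bytes) but file has {len(raw)} bytes"
        )
    rec = np.frombuffer(raw, dtype=_FACET_DTYPE, count=count, offset=84)
    return _dedupe(rec["verts"], provenance=f"read_stl:{path.name}")


def _read_stl_ascii(raw: bytes, name: str) -> TriMesh:
    verts = []
    for line in raw.decode("ascii", "replace").splitlines():
        parts = line.split()
        if parts and parts[0] == "vertex":
            verts.append([float(p) for p in parts[1:4]])
    if not verts or len(verts) % 3:
        raise MeshFormatError(f"corrupt ASCII STL: {name}")
    tri = np.asarray(verts, dtype=np.float32).reshape(-1, 3, 3)
    return _dedupe(tri, provenance=f"read_stl:{name}")
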