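"""Volumes, meshes, and the on-disk formats that carry them.

Every geometric quantity in this package is expressed in physical units
(nanometres for tomograms, micrometres for tissue blocks), never in voxel
indices. A voxel with index ``i`` along an axis with spacing ``s`` is centred
at the world coordinate ``origin + (i + 0.5) * s``. Volumes are indexed
``[x, y, z]``; anisotropic spacing (e.g. 80 nm in XY, 70 nm in Z for
serial block-face SEM stacks) is carried explicitly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
import trimesh as _trimesh
from skimage import measure as _measure

__all__ = [
    "VoxelVolume",
    "TriMesh",
    "read_volume",
    "write_volume",
    "extract_mesh",
    "read_mesh",
    "write_mesh",
    "MissingSpacingError",
    "EmptyMaskError",
]

_UNIT_TO_ANGSTROM = {"nm": 10.0, "um": 1.0e4}


class MissingSpacingError(ValueError):
    """Raised when a file carries no voxel-size metadata and none is supplied."""


class EmptyMaskError(ValueError):
    """Raised when an isosurface is requested for a label absent from the volume."""


@dataclass
class VoxelVolume:
    """A 3D scalar field with anisotropic physical voxel spacing.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
    spacing : ndarray, shape (3,)
        Physical size of one voxel along (x, y, z), in ``unit``.
    origin : ndarray, shape (3,)
        World coordinate of the corner of voxel (0, 0, 0).
    unit : {"nm", "um"}
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None
    unit: str = "um"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.unit not in _UNIT_TO_ANGSTROM:
            raise ValueError(f"unit must be one of {sorted(_UNIT_TO_ANGSTROM)}, got {self.unit!r}")

    @property
    def shape(self):
        return self.data.shape

    @property
    def physical_size(self) -> np.ndarray:
        """Extent of the volume along (x, y, z) in ``unit``."""
        return self.spacing * np.asarray(self.data.shape)

    def voxel_centers_world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates of voxel centres for integer index triples."""
        return self.origin + (np.asarray(indices, dtype=float) + 0.5) * self.spacing

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel index containing each world point (no bounds check)."""
        return np.floor((np.asarray(points, dtype=float) - self.origin) / self.spacing).astype(int)

    def to_unit(self, unit: str) -> "VoxelVolume":
        if unit == self.unit:
            return self
        f = _UNIT_TO_ANGSTROM[self.unit] / _UNIT_TO_ANGSTROM[unit]
        return replace(self, spacing=self.spacing * f, origin=self.origin * f, unit=unit)


@dataclass
class TriMesh:
    """A triangulated surface in physical coordinates.

    Degenerate (zero-area) faces are dropped at construction; face indices
    are validated against the vertex array.
    """

    vertices: np.ndarray
    faces: np.ndarray
    unit: str = "um"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        if self.faces.size:
            tri = self.vertices[self.faces]
            areas = 0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
            )
            self.faces = self.faces[areas > 0]

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape (n_faces, 3, 3)."""
        return self.vertices[self.faces]

    def area(self) -> float:
        tri = self.triangles
        return float(
            0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum()
        )

    def transformed(self, rotation: np.ndarray = None, translation=(0.0, 0.0, 0.0)) -> "TriMesh":
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        return TriMesh(v + np.asarray(translation, dtype=float), self.faces.copy(), self.unit)

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: _trimesh.Trimesh, unit: str = "um") -> "TriMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), unit)


# ---------------------------------------------------------------------------
# volume I/O


def write_volume(vol: VoxelVolume, path) -> None:
    """Write a volume as MRC2014 (.mrc) or multi-page TIFF (.tif/.tiff).

    MRC carries the voxel size in the header (in angstroms, the format's
    convention); TIFF carries XY resolution tags plus ImageJ-style Z spacing.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".mrc":
        from . import mrc

        f = _UNIT_TO_ANGSTROM[vol.unit]
        mrc.write_mrc(path, vol.data, vol.spacing * f, vol.origin * f)
    elif ext in (".tif", ".tiff"):
        sx, sy, sz = vol.spacing
        # pages along z, rows y, cols x
        pages = np.ascontiguousarray(vol.data.T).astype(np.float32)
        unit_code = {"um": "micron", "nm": "nm"}[vol.unit]
        tifffile.imwrite(
            path,
            pages,
            imagej=True,
            resolution=(1.0 / sx, 1.0 / sy),
            metadata={"spacing": sz, "unit": unit_code, "axes": "ZYX"},
        )
    else:
        raise ValueError(f"unsupported volume format {ext!r} (use .mrc, .tif or .tiff)")


def read_volume(path, unit: str = None, spacing=None) -> VoxelVolume:
    """Read a volume from MRC or TIFF.

    Parameters
    ----------
    unit : optional
        Unit to express spacing in. Defaults to "nm" for MRC and to the unit
        recorded in the TIFF metadata.
    spacing : optional
        Explicit (sx, sy, sz) override, required for TIFFs that carry no
        resolution metadata; must then be accompanied by ``unit``.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".mrc":
        from . import mrc

        data, voxel_angstrom, origin_angstrom = mrc.read_mrc(path)
        unit = unit or "nm"
        f = _UNIT_TO_ANGSTROM[unit]
        if spacing is not None:
            return VoxelVolume(data, np.asarray(spacing, dtype=float), unit=unit)
        return VoxelVolume(data, voxel_angstrom / f, origin_angstrom / f, unit)
    if ext in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            pages = tf.asarray()
            if pages.ndim == 2:
                pages = pages[None]
            meta = tf.imagej_metadata or {}
            page0 = tf.pages[0]
            xres = page0.tags.get("XResolution")
            yres = page0.tags.get("YResolution")
        data = np.ascontiguousarray(pages.T)  # -> (x, y, z)
        if spacing is not None:
            if unit is None:
                raise MissingSpacingError(f"{path}: explicit spacing requires a unit")
            return VoxelVolume(data, np.asarray(spacing, dtype=float), unit=unit)
        if xres is None or yres is None or "spacing" not in meta:
            raise MissingSpacingError(
                f"{path}: TIFF carries no voxel-size metadata; pass spacing=(sx, sy, sz) "
                "(CLI: --spacing)"
            )
        sx = xres.value[1] / xres.value[0]
        sy = yres.value[1] / yres.value[0]
        sz = float(meta["spacing"])
        file_unit = {"micron": "um", "um": "um", "nm": "nm", "\\u00b5m": "um"}.get(
            meta.get("unit", "um"), "um"
        )
        vol = VoxelVolume(data, (sx, sy, sz), unit=file_unit)
        return vol.to_unit(unit) if unit else vol
    raise ValueError(f"unsupported volume format {ext!r}")


# ---------------------------------------------------------------------------
# meshes


def extract_mesh(labels: VoxelVolume, label_id: int, step_size: int = 1,
                 smooth_sigma: float = 1.0) -> TriMesh:
    """Isosurface of one label of a label volume, at physical scale.

    Runs 0.5-level marching cubes on the binary mask of ``label_id``. The
    mask is zero-padded by one voxel so surfaces touching the volume border
    close, and lightly Gaussian-smoothed (sigma in voxels) before contouring:
    the 0.5 level of the smoothed mask stays on the object boundary while the
    staircase artefacts that inflate surface area by ~8% on digitised spheres
    are suppressed. Masks too small to survive smoothing fall back to the
    raw binary contour. Vertex coordinates honour the anisotropic spacing
    and the voxel-centre world convention.
    """
    mask = labels.data == label_id
    if not mask.any():
        raise EmptyMaskError(f"label {label_id} not present in volume")
    padded = np.pad(mask, 1).astype(np.float32)
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        smoothed = gaussian_filter(padded, sigma=smooth_sigma)
        if smoothed.max() > 0.5:
            padded = smoothed
    verts, faces, _, _ = _measure.marching_cubes(
        padded, level=0.5, spacing=tuple(labels.spacing), step_size=step_size
    )
    # padded index i corresponds to original index i - 1; voxel centres sit
    # at (i + 0.5) * spacing
    verts = verts + labels.origin + (0.5 - 1.0) * labels.spacing
    return TriMesh(verts, faces, labels.unit)


def write_mesh(mesh: TriMesh, path) -> None:
    """Write a mesh as binary little-endian PLY or as OBJ, by extension."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in (".ply", ".obj"):
        raise ValueError(f"unsupported mesh format {ext!r} (use .ply or .obj)")
    mesh.to_trimesh().export(path)


def read_mesh(path, unit: str = "um") -> TriMesh:
    loaded = _trimesh.load(os.fspath(path), force="mesh", process=False)
    return TriMesh.from_trimesh(loaded, unit)
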