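"""Ground-truthed synthetic tissue volumes and membrane phantoms.

Two generators stand in for the two acquisition regimes the analysis
targets:

* ``generate_tissue`` emulates a serial block-face SEM block: a dark-ish
  resin/tissue background crossed by tubular blood vessels, scattered with
  bright spheroidal inclusions (corpora amylacea, CA) 0.5-30 um in diameter,
  on an anisotropic grid (default 80 nm in XY, 70 nm in Z). CA positions are
  either uniform or attracted to vessel surfaces with an exponential decay
  kernel exp(-d/tau) — a modelling choice for testing, not a biological
  claim.
* ``generate_membrane_phantom`` emulates a binned TEM tomogram patch
  (1.7244 nm voxels) containing lipid-bilayer sheets: two parallel Gaussian
  density leaflets whose *inner half-maximum* surfaces sit a prescribed
  distance apart (default 6.9 nm), optionally bent, plus Gaussian noise.

Identical specs (including the seed) produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .proximity import MeshDistanceQuery
from .volume_io import TriMesh, VoxelVolume, extract_mesh, write_mesh, write_volume

__all__ = [
    "TissuePhantomSpec",
    "TissueGroundTruth",
    "MembranePhantomSpec",
    "generate_tissue",
    "generate_membrane_phantom",
    "place_ca_clustered",
    "PlacementError",
    "polyline_surface_distance",
    "save_tissue_phantom",
]

_HALF_MAX_FACTOR = np.sqrt(2.0 * np.log(2.0))  # half-maximum offset of a unit-sigma Gaussian


class PlacementError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# tissue phantom


@dataclass
class TissuePhantomSpec:
    """Parameters of a synthetic SBF-SEM tissue block.

    Defaults follow the overview-scan regime: 80 nm XY pixels, 70 nm Z steps
    (one ultrathin section per slice), CA diameters spanning 0.5-30 um. The
    default box is a small crop of the 1 mm x 1 mm x 60 um block so phantoms
    stay tractable on a laptop.
    """

    box_size_um: tuple = (40.0, 40.0, 14.0)
    voxel_size_um: tuple = (0.08, 0.08, 0.07)
    n_vessels: int = 1
    vessel_radius_um: float = 5.0
    vessel_model: str = "straight"  # or "random-walk"
    n_ca: int = 30
    ca_diameter_range_um: tuple = (0.5, 30.0)
    ca_placement: str = "uniform"  # or "clustered"
    clustering_scale_um: float = 5.0
    noise_sd: float = 0.02
    blur_sigma_um: float = 0.08
    seed: int = 0
    # rendering / policy knobs
    background: float = 0.2
    vessel_contrast: float = 0.25
    ca_contrast: float = 0.6
    ring_modulation: float = 0.0  # optional concentric-ring amplitude on CA
    ca_aspect_range: tuple = (0.6, 1.1)  # Z half-height / XY radius
    allow_ca_overlap: bool = True
    ca_min_gap_um: float = 0.3  # surface gap enforced when overlap is off
    max_trials_per_ca: int = 2000

    def __post_init__(self):
        box = np.asarray(self.box_size_um, dtype=float)
        vox = np.asarray(self.voxel_size_um, dtype=float)
        if np.any(box <= 0) or np.any(vox <= 0):
            raise ValueError("box and voxel sizes must be strictly positive")
        lo, hi = self.ca_diameter_range_um
        if not (0 < lo <= hi < box.min()):
            raise ValueError(
                f"ca_diameter_range_um {self.ca_diameter_range_um} must lie within (0, {box.min()})"
            )
        if self.vessel_model not in ("straight", "random-walk"):
            raise ValueError(f"unknown vessel_model {self.vessel_model!r}")
        if self.ca_placement not in ("uniform", "clustered"):
            raise ValueError(f"unknown ca_placement {self.ca_placement!r}")
        if self.ca_placement == "clustered" and self.clustering_scale_um <= 0:
            raise ValueError("clustering_scale_um must be positive")

    @property
    def grid_shape(self) -> tuple:
        return tuple(
            int(round(b / v))
            for b, v in zip(self.box_size_um, self.voxel_size_um)
        )

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "TissuePhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass
class TissueGroundTruth:
    """Everything the generator knows that a detector must recover."""

    vessel_mesh: TriMesh
    vessel_centerlines: list
    vessel_radius_um: float
    ca_centroids: np.ndarray  # (n, 3) um
    ca_radii_um: np.ndarray  # XY semi-axes
    ca_heights_um: np.ndarray  # full Z extents
    label_volume: VoxelVolume  # 0 background, 1 vessel, >=2 per-CA

    @property
    def n_ca(self) -> int:
        return len(self.ca_centroids)

    def vessel_surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Exact distance to the analytic vessel tube surface (capsule model).

        Negative inside the lumen.
        """
        return polyline_surface_distance(points, self.vessel_centerlines, self.vessel_radius_um)

    def vessel_interior_fn(self, points: np.ndarray) -> np.ndarray:
        if not self.vessel_centerlines:
            return np.zeros(len(np.atleast_2d(points)), dtype=bool)
        return self.vessel_surface_distance(points) < 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n_ca),
                "x_um": self.ca_centroids[:, 0] if self.n_ca else [],
                "y_um": self.ca_centroids[:, 1] if self.n_ca else [],
                "z_um": self.ca_centroids[:, 2] if self.n_ca else [],
                "radius_um": self.ca_radii_um,
                "height_um": self.ca_heights_um,
            }
        )


def _segments(polyline: np.ndarray) -> tuple:
    p = np.asarray(polyline, dtype=float)
    return p[:-1], p[1:]


def polyline_surface_distance(points, centerlines, radius: float) -> np.ndarray:
    """Signed distance from points to the surface of radius-``radius`` tubes
    swept along polylines (capsules); negative inside."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    best = np.full(len(pts), np.inf)
    for line in centerlines:
        a, b = _segments(line)
        ab = b - a  # (M, 3)
        denom = np.einsum("ij,ij->i", ab, ab)
        ap = pts[:, None, :] - a[None, :, :]  # (N, M, 3)
        t = np.clip(np.einsum("nmj,mj->nm", ap, ab) / np.where(denom > 0, denom, 1.0), 0.0, 1.0)
        closest = a[None] + t[..., None] * ab[None]
        d = np.linalg.norm(pts[:, None, :] - closest, axis=2).min(axis=1)
        best = np.minimum(best, d)
    return best - radius


def _make_centerlines(spec: TissuePhantomSpec, rng: np.random.Generator) -> list:
    box = np.asarray(spec.box_size_um, dtype=float)
    r = spec.vessel_radius_um
    lines = []
    long_axis = int(np.argmax(box))
    for _ in range(spec.n_vessels):
        if spec.vessel_model == "straight":
            perp = [ax for ax in range(3) if ax != long_axis]
            start = np.zeros(3)
            end = np.zeros(3)
            for ax in perp:
                c = rng.uniform(r, box[ax] - r) if box[ax] > 2 * r else box[ax] / 2
                start[ax] = end[ax] = c
            end[long_axis] = box[long_axis]
            lines.append(np.stack([start, end]))
        else:
            # fixed-step walk with bounded turning angle, run until it exits
            step = max(2.0, 4 * max(spec.voxel_size_um))
            max_turn = np.deg2rad(20.0)
            pos = rng.uniform(0.3, 0.7, size=3) * box
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pts = [pos.copy()]
            for _ in range(2000):
                # perturb within the turning cone
                perturb = rng.normal(size=3)
                perturb -= perturb @ direction * direction
                norm = np.linalg.norm(perturb)
                if norm > 0:
                    angle = rng.uniform(0, max_turn)
                    direction = np.cos(angle) * direction + np.sin(angle) * perturb / norm
                    direction /= np.linalg.norm(direction)
                pos = pos + step * direction
                pts.append(pos.copy())
                if np.any(pos < 0) or np.any(pos > box):
                    break
            lines.append(np.asarray(pts))
    return lines


def _rasterize_capsules(label: np.ndarray, spec: TissuePhantomSpec, centerlines: list) -> None:
    vox = np.asarray(spec.voxel_size_um, dtype=float)
    shape = np.asarray(label.shape)
    r = spec.vessel_radius_um
    for line in centerlines:
        a_all, b_all = _segments(line)
        for a, b in zip(a_all, b_all):
            lo = np.maximum(np.floor((np.minimum(a, b) - r) / vox).astype(int), 0)
            hi = np.minimum(np.ceil((np.maximum(a, b) + r) / vox).astype(int) + 1, shape)
            if np.any(hi <= lo):
                continue
            ix, iy, iz = [np.arange(lo[k], hi[k]) for k in range(3)]
            gx, gy, gz = np.meshgrid(
                (ix + 0.5) * vox[0], (iy + 0.5) * vox[1], (iz + 0.5) * vox[2], indexing="ij"
            )
            pts = np.stack([gx, gy, gz], axis=-1)
            ab = b - a
            denom = float(ab @ ab)
            t = np.clip((pts - a) @ ab / (denom if denom > 0 else 1.0), 0.0, 1.0)
            d = np.linalg.norm(pts - (a + t[..., None] * ab), axis=-1)
            inside = d <= r
            label[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]][inside] = 1


def _rasterize_spheroid(label, intensity, spec, center, r_xy, half_h, label_id, rng) -> None:
    vox = np.asarray(spec.voxel_size_um, dtype=float)
    shape = np.asarray(label.shape)
    ext = np.array([r_xy, r_xy, half_h])
    lo = np.maximum(np.floor((center - ext) / vox).astype(int), 0)
    hi = np.minimum(np.ceil((center + ext) / vox).astype(int) + 1, shape)
    if np.any(hi <= lo):
        return
    ix, iy, iz = [np.arange(lo[k], hi[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(
        (ix + 0.5) * vox[0], (iy + 0.5) * vox[1], (iz + 0.5) * vox[2], indexing="ij"
    )
    rho2 = ((gx - center[0]) ** 2 + (gy - center[1]) ** 2) / r_xy**2 + (
        (gz - center[2]) ** 2
    ) / half_h**2
    inside = rho2 <= 1.0
    sub_lab = label[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub_int = intensity[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    claim = inside & (sub_lab != 1)  # never overwrite the vessel
    sub_lab[claim] = label_id
    level = spec.ca_contrast
    if spec.ring_modulation > 0:
        n_rings = max(2, int(round(r_xy / 1.5)))  # more rings on larger CA
        ring = 1.0 + spec.ring_modulation * np.cos(2 * np.pi * n_rings * np.sqrt(rho2))
        sub_int[inside] = spec.background + level * ring[inside]
    else:
        sub_int[inside] = spec.background + level


def generate_tissue(spec: TissuePhantomSpec):
    """Render a tissue phantom and return ``(VoxelVolume, TissueGroundTruth)``.

    Intensity = background + vessel contrast + bright CA spheroids, blurred
    by a Gaussian PSF, plus zero-mean Gaussian noise. CA may overlap each
    other (adjacent/fused inclusions occur in real blocks) but never a
    vessel; set ``allow_ca_overlap=False`` for disjoint phantoms.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box_size_um, dtype=float)
    shape = spec.grid_shape
    vox = np.asarray(spec.voxel_size_um, dtype=float)

    centerlines = _make_centerlines(spec, rng) if spec.n_vessels else []
    label = np.zeros(shape, dtype=np.int32)
    if centerlines:
        _rasterize_capsules(label, spec, centerlines)

    # CA sizes first, positions by rejection
    d_lo, d_hi = spec.ca_diameter_range_um
    radii = rng.uniform(d_lo, d_hi, size=spec.n_ca) / 2.0
    aspects = rng.uniform(*spec.ca_aspect_range, size=spec.n_ca)
    half_heights = radii * aspects
    tau = spec.clustering_scale_um
    centroids = np.zeros((spec.n_ca, 3))
    for i in range(spec.n_ca):
        r_bound = max(radii[i], half_heights[i])
        margin = np.array([radii[i], radii[i], half_heights[i]])
        lo_box, hi_box = margin, box - margin
        if np.any(hi_box <= lo_box):
            raise PlacementError(
                f"CA {i} (radius {radii[i]:.2f} um) does not fit in box {box}"
            )
        placed = False
        for _ in range(spec.max_trials_per_ca):
            p = lo_box + rng.random(3) * (hi_box - lo_box)
            d_vessel = (
                polyline_surface_distance(p[None], centerlines, spec.vessel_radius_um)[0]
                if centerlines
                else np.inf
            )
            if d_vessel < r_bound:  # CA-vessel overlap forbidden
                continue
            if spec.ca_placement == "clustered" and np.isfinite(d_vessel):
                if rng.random() > np.exp(-max(d_vessel, 0.0) / tau):
                    continue
            if not spec.allow_ca_overlap and i > 0:
                # bounding spheres plus a gap, so "disjoint" stays resolvable
                # after PSF blurring
                prev_bound = np.maximum(radii[:i], half_heights[:i])
                sep = np.linalg.norm(centroids[:i] - p, axis=1)
                if np.any(sep < prev_bound + r_bound + spec.ca_min_gap_um):
                    continue
            centroids[i] = p
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place CA {i} after {spec.max_trials_per_ca} trials "
                f"(radius {radii[i]:.2f} um, placement={spec.ca_placement}, "
                f"tau={tau}, box={tuple(box)})"
            )

    intensity = np.full(shape, spec.background, dtype=np.float32)
    intensity[label == 1] = spec.background + spec.vessel_contrast
    # largest first: a small CA overlapping a larger neighbour keeps its own
    # label where they intersect, so every CA retains a labelled core
    for i in np.argsort(-radii):
        _rasterize_spheroid(
            label, intensity, spec, centroids[i], radii[i], half_heights[i], 2 + int(i), rng
        )

    if spec.blur_sigma_um > 0:
        intensity = gaussian_filter(intensity, sigma=spec.blur_sigma_um / vox)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    label_vol = VoxelVolume(label, vox, unit="um")
    vessel_mesh = (
        extract_mesh(label_vol, 1) if (centerlines and (label == 1).any()) else TriMesh(
            np.empty((0, 3)), np.empty((0, 3), dtype=int), "um"
        )
    )
    gt = TissueGroundTruth(
        vessel_mesh=vessel_mesh,
        vessel_centerlines=centerlines,
        vessel_radius_um=spec.vessel_radius_um,
        ca_centroids=centroids,
        ca_radii_um=radii,
        ca_heights_um=2.0 * half_heights,
        label_volume=label_vol,
    )
    return VoxelVolume(intensity.astype(np.float32), vox, unit="um"), gt


def place_ca_clustered(
    vessel_mesh: TriMesh,
    n: int,
    tau_um: float,
    box,
    rng_seed: int = None,
    interior_fn=None,
    min_acceptance: float = 1e-4,
    batch: int = 4096,
) -> np.ndarray:
    """Sample ``n`` points attracted to a vessel surface.

    Rejection scheme: propose uniformly in the box (minus the vessel
    interior), accept with probability exp(-d / tau) where d is the distance
    to the vessel surface. tau -> inf recovers uniform placement.
    """
    if tau_um <= 0:
        raise ValueError("tau_um must be positive")
    if vessel_mesh.n_faces == 0:
        raise ValueError("vessel mesh is empty")
    if n == 0:
        return np.empty((0, 3))
    lo, hi = (np.asarray(v, dtype=float) for v in box)
    query = MeshDistanceQuery(vessel_mesh)
    if interior_fn is None:
        from .proximity import mesh_contains

        def interior_fn(pts):
            return mesh_contains(vessel_mesh, pts)
    rng = np.random.default_rng(rng_seed)
    accepted = []
    got = 0
    proposed = 0
    max_proposals = max(int(n / min_acceptance), 100 * batch)
    while got < n and proposed < max_proposals:
        pts = lo + rng.random((batch, 3)) * (hi - lo)
        proposed += batch
        inside = interior_fn(pts)
        pts = pts[~inside]
        u = rng.random(len(pts))
        # two-stage thinning: a certified lower distance bound rejects most
        # far proposals outright (u > exp(-lo/tau) >= exp(-d/tau)); only the
        # survivors need an exact distance
        d_lo, _ = query.bounds(pts)
        maybe = u <= np.exp(-d_lo / tau_um)
        keep = np.zeros(len(pts), dtype=bool)
        if maybe.any():
            d = query.distances(pts[maybe])
            keep[maybe] = u[maybe] <= np.exp(-d / tau_um)
        accepted.append(pts[keep])
        got += int(keep.sum())
    if got < n:
        raise PlacementError(
            f"clustered placement acceptance rate below {min_acceptance}: "
            f"increase tau_um (={tau_um}) or shrink the domain"
        )
    return np.concatenate(accepted)[:n]


# ---------------------------------------------------------------------------
# membrane phantom


@dataclass
class MembranePhantomSpec:
    """Parameters of a synthetic bilayer tomogram patch.

    The voxel size defaults to 1.7244 nm (a 4.311 angstrom detector pixel
    binned by 4). Each bilayer is two Gaussian density sheets placed so that
    their *inner half-maximum* surfaces are ``leaflet_spacing_nm`` apart.
    ``noise_sd`` defaults to twice the leaflet peak amplitude (SNR 0.5, the
    regime the averaging stage is designed for).
    """

    box_voxels: tuple = (128, 128, 72)
    voxel_size_nm: float = 1.7244
    leaflet_spacing_nm: float = 6.9
    leaflet_width_nm: float = 1.2
    curvature: str = "sinusoidal"  # gently bent sheets; "flat" for exact constructions
    bend_amplitude_nm: float = 1.0
    bend_period_nm: float = 160.0
    n_sheets: int = 1
    amplitude: float = 1.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.leaflet_spacing_nm <= 0 or self.voxel_size_nm <= 0:
            raise ValueError("spacing and voxel size must be positive")
        if self.leaflet_spacing_nm < 2 * self.voxel_size_nm:
            raise ValueError(
                f"leaflet spacing {self.leaflet_spacing_nm} nm is not resolvable at "
                f"{self.voxel_size_nm} nm voxels (needs >= 2 voxels)"
            )
        if self.curvature not in ("flat", "sinusoidal"):
            raise ValueError(f"unknown curvature {self.curvature!r}")


def generate_membrane_phantom(spec: MembranePhantomSpec):
    """Render bilayer sheets and return ``(VoxelVolume, true_spacing_nm)``.

    Leaflet centres sit at +- (spacing/2 + width * sqrt(2 ln 2)) from the
    sheet midplane, so the inner half-maximum crossings of the two peaks are
    exactly ``leaflet_spacing_nm`` apart.
    """
    nx, ny, nz = spec.box_voxels
    v = spec.voxel_size_nm
    x = (np.arange(nx) + 0.5) * v
    z = (np.arange(nz) + 0.5) * v
    half_sep = spec.leaflet_spacing_nm / 2.0 + spec.leaflet_width_nm * _HALF_MAX_FACTOR
    data = np.zeros((nx, ny, nz), dtype=np.float32)
    box_z = nz * v
    for s in range(spec.n_sheets):
        z0 = box_z * (s + 1) / (spec.n_sheets + 1)
        if spec.curvature == "sinusoidal":
            surf = z0 + spec.bend_amplitude_nm * np.sin(2 * np.pi * x / spec.bend_period_nm)
        else:
            surf = np.full(nx, z0)
        dz = z[None, :] - surf[:, None]  # (nx, nz)
        sheet = np.exp(-((dz - half_sep) ** 2) / (2 * spec.leaflet_width_nm**2)) + np.exp(
            -((dz + half_sep) ** 2) / (2 * spec.leaflet_width_nm**2)
        )
        data += spec.amplitude * sheet[:, None, :].astype(np.float32)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape).astype(np.float32)
    vol = VoxelVolume(data, (v, v, v), unit="nm")
    return vol, float(spec.leaflet_spacing_nm)


# ---------------------------------------------------------------------------
# on-disk export


def save_tissue_phantom(spec: TissuePhantomSpec, vol: VoxelVolume, gt: TissueGroundTruth, outdir):
    """Write volume (MRC + TIFF), ground-truth CSV, vessel PLY and spec YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(vol, outdir / "phantom.mrc")
    write_volume(gt.label_volume, outdir / "labels.tif")
    gt.to_dataframe().to_csv(outdir / "ca_truth.csv", index=False)
    if gt.vessel_mesh.n_faces:
        write_mesh(gt.vessel_mesh, outdir / "vessels.ply")
    spec.to_yaml(outdir / "spec.yaml")
    return {
        "volume": str(outdir / "phantom.mrc"),
        "labels": str(outdir / "labels.tif"),
        "ca_truth": str(outdir / "ca_truth.csv"),
        "vessels": str(outdir / "vessels.ply") if gt.vessel_mesh.n_faces else None,
        "spec": str(outdir / "spec.yaml"),
    }
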