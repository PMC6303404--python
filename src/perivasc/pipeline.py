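"""End-to-end orchestration: synthesize -> detect -> proximity -> STA.

A run is driven by a YAML config with per-stage parameter blocks and a
single global seed; each stage receives a child seed derived from the global
one through ``numpy.random.SeedSequence`` spawn keys, so stages are
individually reproducible and never share streams. The manifest records
inputs, a parameter hash, seeds, package version and every output path;
identical configs produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("perivasc.pipeline")

_STAGE_ORDER = ("synth", "detect", "proximity", "sta")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "perivasc_run"
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "perivasc_run")),
            stages=raw.get("stages", {}),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {"seed": self.seed, "outdir": self.outdir, "stages": self.stages},
                sort_keys=False,
            )
        )

    def stage_seed(self, stage: str) -> int:
        idx = _STAGE_ORDER.index(stage)
        ss = np.random.SeedSequence(self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2**31))

    def param_hash(self) -> str:
        blob = json.dumps({"seed": self.seed, "stages": self.stages}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _validate(config: RunConfig) -> None:
    enabled = [s for s in _STAGE_ORDER if config.stages.get(s, {}).get("enabled", False)]
    if not enabled:
        raise ValueError("no stage enabled in config")
    for stage in enabled:
        block = config.stages.get(stage, {})
        for key in ("input", "ca", "vessels"):
            path = block.get(key)
            if path is not None and not Path(path).exists():
                # inputs produced by an earlier enabled stage are resolved later
                raise StageError(stage, FileNotFoundError(f"declared input {key}={path!r} not found"))


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest."""
    from . import __version__

    _validate(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "outputs": {},
    }
    context = {}
    for stage in _STAGE_ORDER:
        block = config.stages.get(stage, {})
        if not block.get("enabled", False):
            continue
        seed = config.stage_seed(stage)
        logger.info("stage %s (seed %d)", stage, seed)
        try:
            outputs = _RUNNERS[stage](block, seed, outdir, context)
        except Exception as e:  # noqa: BLE001 - re-raised with stage name
            manifest["stages"][stage] = {"status": "failed", "error": str(e)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(stage, e) from e
        manifest["stages"][stage] = {"status": "ok", "seed": seed, "params": block}
        manifest["outputs"].update(outputs)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _run_synth(block: dict, seed: int, outdir: Path, context: dict) -> dict:
    from .synthetic_data import (
        MembranePhantomSpec,
        TissuePhantomSpec,
        generate_membrane_phantom,
        generate_tissue,
        save_tissue_phantom,
    )
    from .volume_io import write_volume

    params = dict(block.get("params", {}))
    params.setdefault("seed", seed)
    for key in ("box_size_um", "voxel_size_um", "ca_diameter_range_um", "ca_aspect_range"):
        if key in params:
            params[key] = tuple(params[key])
    spec = TissuePhantomSpec(**params)
    vol, gt = generate_tissue(spec)
    outputs = save_tissue_phantom(spec, vol, gt, outdir)
    context["tissue_spec"] = spec
    context["tissue_gt"] = gt
    context["tissue_vol"] = vol

    mem_params = dict(block.get("membrane", {}))
    mem_params.setdefault("seed", seed + 1)
    if "box_voxels" in mem_params:
        mem_params["box_voxels"] = tuple(mem_params["box_voxels"])
    mspec = MembranePhantomSpec(**mem_params)
    mvol, true_spacing = generate_membrane_phantom(mspec)
    write_volume(mvol, outdir / "membrane.mrc")
    context["membrane_vol"] = mvol
    context["membrane_true_spacing"] = true_spacing
    outputs["membrane"] = str(outdir / "membrane.mrc")
    return outputs


def _run_detect(block: dict, seed: int, outdir: Path, context: dict) -> dict:
    from .morphometry import DetectionParams, detect_ca, records_to_dataframe
    from .volume_io import read_volume

    if block.get("input"):
        vol = read_volume(block["input"], unit="um")
    elif "tissue_vol" in context:
        vol = context["tissue_vol"]
    else:
        raise FileNotFoundError("detect stage needs an input volume (synth disabled)")
    params = DetectionParams(**block.get("params", {}))
    records = detect_ca(vol, params)
    df = records_to_dataframe(records)
    path = outdir / "ca.csv"
    df.to_csv(path, index=False)
    context["ca_records"] = records
    return {"ca": str(path)}


def _run_proximity(block: dict, seed: int, outdir: Path, context: dict) -> dict:
    from .proximity import MeshDistanceQuery, distance_profile, enrichment, simulate_null
    from .volume_io import read_mesh

    if block.get("ca"):
        df = pd.read_csv(block["ca"])
        centroids = df[["x_um", "y_um", "z_um"]].to_numpy()
    elif "ca_records" in context:
        centroids = np.array([r.centroid_um for r in context["ca_records"]])
    elif "tissue_gt" in context:
        centroids = context["tissue_gt"].ca_centroids
    else:
        raise FileNotFoundError("proximity stage needs CA positions (csv or detect stage)")
    if block.get("vessels"):
        meshes = [read_mesh(block["vessels"])]
        interior_fn = None
    elif "tissue_gt" in context:
        meshes = [context["tissue_gt"].vessel_mesh]
        interior_fn = context["tissue_gt"].vessel_interior_fn
    else:
        raise FileNotFoundError("proximity stage needs a vessel mesh")
    if "box" in block:
        box = (np.zeros(3), np.asarray(block["box"], dtype=float))
    elif "tissue_spec" in context:
        box = (np.zeros(3), np.asarray(context["tissue_spec"].box_size_um, dtype=float))
    else:
        raise ValueError("proximity stage needs a bounding box")
    thresholds = np.asarray(block.get("thresholds", [5.0, 10.0]), dtype=float)
    query = MeshDistanceQuery(meshes)
    profile = distance_profile(centroids, meshes, query=query)
    null = simulate_null(
        n_ca=profile.n,
        box=box,
        vessel_meshes=meshes,
        R=int(block.get("R", 10000)),
        seed=seed,
        thresholds=thresholds,
        interior_fn=interior_fn,
        query=query,
    )
    report = enrichment(profile, null)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report.to_dict(), indent=2))
    env_path = outdir / "null_envelope.csv"
    null.to_dataframe().to_csv(env_path, index=False)
    hist_path = outdir / "distance_histogram.csv"
    pd.DataFrame(
        {"bin_left_um": profile.bin_edges[:-1], "count": profile.counts}
    ).to_csv(hist_path, index=False)
    return {"report": str(report_path), "envelope": str(env_path), "histogram": str(hist_path)}


def _run_sta(block: dict, seed: int, outdir: Path, context: dict) -> dict:
    from .membrane_sta import align_average, denoise, extract_particles, measure_spacing, pick_seeds
    from .volume_io import read_volume, write_volume

    if block.get("input"):
        vol = read_volume(block["input"], unit="nm")
    elif "membrane_vol" in context:
        vol = context["membrane_vol"]
    else:
        raise FileNotFoundError("sta stage needs an input tomogram (mrc)")
    if block.get("denoise_iterations", 0):
        vol = denoise(vol, iterations=int(block["denoise_iterations"]))
    seeds = pick_seeds(
        vol,
        contrast_percentile=float(block.get("contrast_percentile", 99.0)),
        min_separation_voxels=int(block.get("min_separation", 4)),
    )
    stack = extract_particles(vol, seeds, cube_side_voxels=int(block.get("cube", 30)))
    n_max = int(block.get("max_particles", 100))
    if len(stack) > n_max:
        from .membrane_sta import ParticleStack

        stack = ParticleStack(stack.particles[:n_max], stack.centers[:n_max], stack.voxel_size_nm)
    avg = align_average(
        stack,
        max_iter=int(block.get("max_iter", 20)),
        rotation_mode=block.get("rotation_mode", "none"),
    )
    est = measure_spacing(avg)
    from .volume_io import VoxelVolume

    avg_path = outdir / "avg.mrc"
    write_volume(
        VoxelVolume(avg.data, [avg.voxel_size_nm] * 3, unit="nm"), avg_path
    )
    spacing_path = outdir / "spacing.json"
    spacing_path.write_text(
        json.dumps(
            {
                "spacing_nm": est.spacing_nm,
                "uncertainty_nm": est.uncertainty_nm,
                "n_particles": avg.n_particles,
                "converged": avg.converged,
                "iterations": len(avg.iteration_log),
            },
            indent=2,
        )
    )
    profile_path = outdir / "profile.csv"
    pd.DataFrame(
        {"position_nm": est.profile_position_nm, "density": est.profile_density}
    ).to_csv(profile_path, index=False)
    return {"avg": str(avg_path), "spacing": str(spacing_path), "profile": str(profile_path)}


_RUNNERS = {
    "synth": _run_synth,
    "detect": _run_detect,
    "proximity": _run_proximity,
    "sta": _run_sta,
}
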