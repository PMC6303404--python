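# perivasc

Analysis of cerebral **corpora amylacea** (CA) — the dense spheroidal
inclusions of the aged human brain — in 3D electron-microscopy volumes:

* **morphometry** — detect CA in serial block-face SEM blocks and estimate
  radius, height, sphericity, size class and areal concentration;
* **perivascular proximity statistics** — test whether CA cluster around
  blood vessels by comparing nearest-surface distances against a Monte
  Carlo randomized-placement null;
* **sub-tomogram averaging** — pick, extract, align and average cubic
  sub-volumes from TEM tomogram patches and measure lipid-bilayer leaflet
  spacing from the average;
* **synthetic data** — ground-truthed tissue and membrane phantoms so every
  stage is testable without any acquired data.

Written for microscopists and image analysts who have reconstructed volumes
(MRC or TIFF stacks) in hand and want reproducible, scripted statistics
rather than interactive segmentation.

## The statistics at the core

**Proximity.** Each inclusion is reduced to its centroid `x_i`, each vessel
to a triangulated surface `S`; the per-object statistic is
`d_i = min_{s in S} ||x_i - s||`, the exact point-to-mesh distance. The null
hypothesis of random scattering is simulated by placing the same number of
points uniformly in the tissue box (homogeneous Poisson conditioned on `n`,
vessel lumina excluded) `R` times; for each distance threshold `t` the
envelope of null counts `N_r(t) = #{d_i <= t}` yields an expectation,
variance, 2.5/97.5% quantiles, and the add-one empirical p-value

    p(t) = (1 + #{r : N_r(t) >= N_obs(t)}) / (R + 1).

**Leaflet spacing.** Particles are unit-normalised and aligned by
alternating maximisation of the mean normalised cross-correlation against
the evolving average (FFT translation search with sub-voxel refinement;
optional rotation grids), which makes the objective non-decreasing by
construction. The spacing is read off the average's axial density profile
as the distance between the **inner half-maximum crossings** of the two
leaflet peaks, i.e. inner surface to inner surface.

## Worked example

Generate a clustered phantom, detect the inclusions, and test perivascular
enrichment:

```python
import numpy as np
from perivasc import (TissuePhantomSpec, generate_tissue, detect_ca,
                      MeshDistanceQuery, distance_profile, simulate_null,
                      enrichment, perivascular_fraction)

spec = TissuePhantomSpec(
    box_size_um=(100.0, 100.0, 14.0), voxel_size_um=(0.2, 0.2, 0.2),
    n_vessels=1, vessel_radius_um=5.0,
    n_ca=40, ca_diameter_range_um=(2.0, 8.0),
    ca_placement="clustered", clustering_scale_um=5.0,
    noise_sd=0.02, allow_ca_overlap=False, seed=11)
vol, truth = generate_tissue(spec)

records = detect_ca(vol)
centroids = np.array([r.centroid_um for r in records])
query = MeshDistanceQuery(truth.vessel_mesh)
profile = distance_profile(centroids, [truth.vessel_mesh], query=query)
null = simulate_null(profile.n, (np.zeros(3), np.array(spec.box_size_um)),
                     [truth.vessel_mesh], R=2000, seed=7,
                     thresholds=[5.0, 10.0],
                     interior_fn=truth.vessel_interior_fn, query=query)
report = enrichment(profile, null)
for t, c, f, e, p in zip(report.thresholds, report.observed_counts,
                         report.fraction_within_pct,
                         report.null_expectation, report.p_empirical):
    print(f"within {t:.0f} um: {c}/{report.n_ca} CA ({f}%), "
          f"null expects {e:.1f}, p = {p:.4f}")
print(f"perivascular fraction (10 um proxy): "
      f"{perivascular_fraction(profile, 10.0):.1f}%")
```

Output:

```
within 5 um: 19/39 CA (49%), null expects 5.2, p = 0.0005
within 10 um: 31/39 CA (79%), null expects 9.5, p = 0.0005
perivascular fraction (10 um proxy): 79.5%
```

39 of the 40 generated inclusions are detected (one sits too close to a
neighbour and merges). Under random placement only ~5 of 39 objects would
fall within 5 um of the vessel surface; 19 are observed, and no null
randomization among 2000 reached the observed counts, so the enrichment
p-value is at its floor of 1/2001 — the clustered placement is decisively
detected. The "perivascular fraction" is the percentage of objects within a
10 um distance threshold, a proxy for membership in the perivascular
(glymphatic) zone.

The same stages run from the shell:

```sh
perivasc synth  --out phantom_dir --seed 11
perivasc detect --in phantom_dir/phantom.mrc --out ca.csv
perivasc proximity --ca ca.csv --vessels phantom_dir/vessels.ply \
    --box 40,40,14 --R 10000 --seed 7 --thresholds 5,10 --out report.json
perivasc sta --in tomo.mrc --cube 30 --max-iter 20 \
    --out avg.mrc --report spacing.json
perivasc run --config demo.yaml          # full pipeline with a manifest
```

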