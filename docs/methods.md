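# Methods

`perivasc` analyses 3D electron-microscopy volumes of cerebral corpora
amylacea (CA): it detects and measures the inclusions, tests whether they
cluster around blood vessels, and measures lipid-bilayer leaflet spacing by
sub-tomogram averaging. Because the image stacks such studies rest on are
rarely released, the package ships a first-class synthetic-data module that
generates ground-truthed phantoms with the statistical structure the
analysis assumes; every downstream stage is validated against those
phantoms.

## Coordinate and unit conventions

Volumes are scalar grids indexed `[x, y, z]` with explicit anisotropic
voxel spacing; a voxel with index `i` is centred at
`origin + (i + 0.5) * spacing`. Tissue-scale data are in micrometres
(default spacing 0.08 x 0.08 x 0.07 um, the overview regime of serial
block-face SEM: 80 nm pixels, 70 nm sections), tomogram patches in
nanometres (default 1.7244 nm, a 4.311 angstrom detector pixel binned by
four). All geometry — meshes, centroids, distances — is emitted in physical
units, never voxel indices.

## Synthetic tissue blocks

`generate_tissue` renders a background-intensity block crossed by tubular
vessels (straight, or a fixed-step random walk with turning angle bounded
at 20 degrees, swept by a constant-radius tube) and scattered with bright
spheroidal CA. CA are prolate/oblate spheroids with an XY semi-axis drawn
uniformly from the configured diameter range (default 0.5-30 um) and a Z
half-height equal to that radius times an aspect factor uniform in
0.6-1.1, so radius and height are separately estimable. Intensity is
background + vessel contrast + CA contrast (CA brighter than background, as
heavy-metal-stained inclusions are electron dense; the detector's polarity
is configurable), blurred by a Gaussian PSF and finished with white
Gaussian noise. Identical specs, including the seed, give bit-identical
volumes.

Placement: CA-vessel overlap is forbidden (rejection on the analytic
capsule distance); CA-CA overlap is permitted by default because adjacent
and fused inclusions occur in real blocks (`allow_ca_overlap=False` yields
disjoint phantoms for recovery tests). Under `clustered` placement a
proposal at surface distance d is accepted with probability exp(-d/tau).
The exponential kernel is a modelling choice that produces tunable
perivascular attraction for testing; it is not a claim about the biology.
The label volume records 0 = background, 1 = vessel, >= 2 = one label per
CA; spheroids are rasterised largest-first so an overlapped smaller CA
keeps its own labelled core and labels stay one-to-one with centroids.

The default tissue box is 40 x 40 x 14 um — a small crop of the
1 mm x 1 mm x 60 um blocks the analysis is designed for — purely so that
phantom grids (500 x 500 x 200 voxels) remain comfortable on one CPU; all
geometric reasoning is scale-free.

## Membrane phantoms

`generate_membrane_phantom` builds bilayer sheets: two Gaussian density
leaflets (sigma 1.2 nm) placed so that the *inner half-maximum* surfaces
are exactly `leaflet_spacing_nm` apart (default 6.9 nm). The default sheet
is gently bent (sinusoidal, 1 nm amplitude over a 160 nm period, about a
2-degree maximal tilt) rather than flat: real membrane fragments in these
inclusions are curved, and a perfectly flat, axis-aligned sheet is also a
degenerate measurement target — every column samples the profile at the
same sub-voxel phase, so the half-maximum crossings alias at the 1.72 nm
sampling pitch. The gentle bend spreads sample phases continuously without
meaningfully tilting the local normal. Default noise is twice the leaflet
peak amplitude (SNR 0.5), the regime averaging is meant to rescue.

## CA detection and morphometry

The detector is deterministic: Gaussian smoothing (sigma 0.16 um), global
intensity threshold (Otsu unless given), 26-connected components, then two
refinements per component — the boundary is re-cut at the mid-level between
the component's inside and outside means (for a blurred step edge this is
the gradient-maximum surface, so "edge detection" and size fidelity
coincide), and a local-variance texture gate can reject flat false
positives. Components below 0.5 um equivalent diameter (the smallest
inclusions reported in this material) are discarded, and components with
sphericity below 0.8 are rejected as non-CA: an ideal sphere scores ~0.92
on the raw digitised surface and vessel-like tubes at most ~0.76, so the
gate separates the two without any tube model.

Shape descriptors: radius = equivalent-circle radius of the largest-area Z
slice; height = occupied Z slices x Z spacing; sphericity =
pi^(1/3)(6V)^(2/3)/A with V from voxel counts and A from the *unsmoothed*
marching-cubes surface (consistent across shapes; the closed-form cube
value ~0.81 is preserved). `extract_mesh` itself defaults to lightly
smoothing the binary mask (sigma 1 voxel) before contouring because the raw
staircase surface overestimates a digitised sphere's area by ~8%; masks too
small to survive smoothing fall back to the raw contour. Size classes
follow a pure diameter threshold at 10 um ("intracellular-scale" below,
"extracellular-scale" above); a genuine intracellular call would need the
enclosing membrane, which is out of scope, and the naming says so.
Abundance is count per mm^2 with a two-sided unpaired t-test across
samples; two constant identical groups return p = 1 by convention.

## Nearest-surface distances

Each CA is reduced to its centroid (a surface-to-surface mode is offered);
each vessel to a triangulated surface; the statistic is the minimum
point-to-triangle distance over all faces of all vessels. Distances are
exact: faces are first subdivided by longest-edge bisection to a bounded
edge length (this changes nothing about the surface), a k-d tree over
triangle centroids yields a certified upper bound (centroids lie on the
surface) and a lower bound (minus the largest centroid-to-corner radius),
and only triangles whose centroid ball intersects the bound are examined.
The result is contractually identical to an exhaustive scan, and the test
suite holds it to 1e-9 against both the internal exhaustive path and an
independent implementation. For Monte Carlo threshold counts the bounds
alone classify almost every point; only points whose bound interval
straddles a threshold get an exact distance, which keeps tens of millions
of null points tractable on one CPU without any approximation of the
counts.

## The randomized-placement null

The null re-places the observed number of points independently and
uniformly in the tissue box (homogeneous Poisson conditioned on n, matching
"each randomization set contains the same objects"), excluding vessel
interiors by default — a point cannot occupy a lumen, and for thin vessels
the exclusion changes the null negligibly (interior fraction under 1% in
the reference geometry). Both modes are available. Interior exclusion uses
an analytic capsule test when vessel centerlines are known (synthetic
ground truth) and falls back to ray-cast containment on the watertight mesh
otherwise; ray casting is the slow path and is only sensible for modest
R x n. R randomization sets (default 10,000) give per-threshold
expectation, variance, 2.5/97.5% quantiles, and the add-one empirical
p-value (1 + #{null >= observed}) / (R + 1), which can never be zero.
Histogram bins are 1 um wide, left-closed; thresholds are evaluated on the
raw distance set, not binned counts. The perivascular ("glymphatic-zone")
fraction is reported as the percentage of objects within a distance
threshold (default 10 um) and is labelled a proxy: the visually traced
anatomical zone that motivates it is not algorithmically defined.

Correctness anchors: on a single straight cylinder (r = 5 um) through a
100 um box the expected fraction within 10 um has the closed form
pi((r+10)^2 - r^2)L / (V - pi r^2 L) ~ 0.0633, and null counts are
Binomial(n, p); the Monte Carlo expectation and variance are held to those.
Calibration (data generated under the null are rejected at ~5% at alpha =
0.05) and power (exponential attraction at tau = 5 um detected with
p < 0.01) are exercised at R = 200 per dataset — a scaled-down randomization
budget chosen so the full calibration suite of 200 datasets runs in minutes;
the p-value mechanics are identical at any R.

## Sub-tomogram averaging

Picking computes a local-SD contrast map on a smoothed copy (sigma 2.5
voxels — raw local SD is dominated by voxel noise at SNR 0.5), takes local
maxima above a percentile (default 98.5), re-centres each candidate to the
local centre of mass of smoothed density (contrast peaks sit on the flanks
of dense structures; two passes of a 15-voxel COM window move flank hits of
either leaflet onto the bilayer midplane, giving a single registration
class), and thins greedily to a minimum separation. Ordering is by
descending contrast with deterministic tie-breaks.

Cubic particles (default 30^3 voxels = 51.7 nm) are aligned by alternating
maximisation: particles are unit-normalised; translations are circular
shifts found exhaustively by FFT cross-correlation within +-8 voxels, with
per-axis parabolic sub-voxel refinement applied through the Fourier shift
theorem and kept only when it genuinely raises the correlation; the
reference update is the normalised mean of the aligned particles, which is
exactly the unit vector maximising the mean correlation. Both half-steps
maximise the same objective, so the mean particle-to-reference correlation
is non-decreasing by construction — the suite asserts this on every run.
Iteration stops when the mean parameter change falls below the search
resolution (0.5 voxel translation; the angular step for rotations) or at 20
iterations. Rotational search (in-plane or a coarse two-angle grid, 15
degrees) is available; the default is translation-only, because the
phantoms' sheets share one orientation and a full Euler grid at this
resolution buys nothing for its considerable cost — on real tomograms with
arbitrarily oriented fragments the grid modes are the ones to use. The
final map averages the best-correlating 80% of the stack: picking is
contrast-driven, so a minority of seeds contain no structure and would
otherwise fill in the inter-leaflet trough.

Spacing is measured "inner surface to inner surface": the membrane normal
is the thinnest axis of the average's density-weighted inertia ellipsoid;
the density profile along it (restricted to a central column, since
curvature across the full cube width would smear the peaks) is refined by
cubic-spline upsampling; the spacing is the distance between the inner
half-maximum crossings of the two leaflet peaks. A single (bin width,
lateral radius) choice leaves those crossings sensitive to how the binning
phase falls on the voxel grid, so the estimate is the median over a 3 x 3
grid of extraction settings — the landmark definition itself is never
changed. The uncertainty is the half-set split difference divided by
sqrt(2). Fewer than two detectable peaks raises a no-bilayer error rather
than returning a number.

Known limitations of this stage: the half-maximum landmark inherits a small
negative bias (about -0.2 nm at the reference conditions) from residual
sub-voxel registration jitter, which broadens the leaflets symmetrically;
no CTF correction or missing-wedge compensation is attempted (phantoms are
real-space, so passing recovery tests says nothing about wedge artefacts);
and at spacings well above the default (8.6 nm) occasional runs still
mis-register a subpopulation and land ~1.1-1.4 nm low.

## Denoising

An explicit 3D Perona-Malik scheme with conductance exp(-(|grad|/kappa)^2);
the step size is capped at the 3D stability bound 1/6 and larger steps are
rejected rather than silently clamped. Zero iterations is the identity.

## Pipeline and reproducibility

`perivasc run --config demo.yaml` executes synthesize -> detect ->
proximity -> STA. One global seed fans out to per-stage child seeds through
`SeedSequence` spawn keys (stage-level reproducibility without stream
collisions; all derived seeds stay below 2^31). The manifest records the
package version, a SHA-256 parameter hash, per-stage seeds and all output
paths; rerunning an identical config reproduces every CSV/JSON byte for
byte. A stage failure aborts with the stage named and partial outputs
retained. I/O: MRC2014 (an internal minimal mode-2 reader/writer carrying
the voxel size in CELLA) and multi-page TIFF with resolution metadata for
volumes; binary PLY/OBJ for meshes; CSV with fixed headers for tables;
YAML for specs and configs. TIFFs without voxel-size metadata are refused
unless an explicit spacing is supplied.

## What the phantoms do and do not show

The phantoms reproduce the *geometry and statistics* the analysis relies on
— anisotropic sampling, vessel tubes, spheroid size ranges, exponential
perivascular attraction, bilayer density profiles at the binned tomogram
scale, Gaussian noise. They do not simulate electron-optical image
formation, charging, section compression, tilt-series artefacts, staining
heterogeneity, or the concentric lamination of real CA (rendered only as an
optional intensity modulation, and deliberately not exploited by the
detector). Green tests therefore demonstrate that the algorithms are
correct and calibrated under their stated assumptions, not that those
assumptions exhaust real tissue.

## Problem sizes

Default validation scales were chosen to keep the whole suite comfortable
on a single CPU: null calibration uses 200 datasets at R = 200 (the
production default remains R = 10,000); power uses 100 runs; morphometry
recovery 20 phantoms; spacing recovery 20 seeded runs at 100 particles on a
128 x 128 x 72 phantom. All are plain parameters, and nothing in the
statistics changes with scale except Monte Carlo resolution.
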