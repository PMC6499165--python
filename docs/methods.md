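# Methods

This note documents the models and numerical procedures implemented in
`tmsmap`, the defaults they ship with, and what the synthetic-data tests
do and do not demonstrate about real data.

## Coordinate model

Stimulation events arrive as 3D scanner-space coordinates (mm; +x
left→right, +y posterior→anterior, +z inferior→superior) with MEP
peak-to-peak amplitudes (μV). Because a TMS coil always sits on the
scalp, the events form a 2D sheet, and all fitting happens in angular
coordinates about the centroid **o** of the head segmentation:
inclination θ = arccos((z−z_o)/‖p−o‖) ∈ [0, π] from the +z axis and
azimuth φ = atan2(y−y_o, x−x_o) ∈ (−π, π]. The two-argument arctangent
is used throughout — a single-argument form would collapse the two
hemispheres onto one.

### Head segmentation and point cloud

Segmentation is deliberately simple and deterministic: Otsu threshold,
morphological closing (ball radius 2 voxels), interior hole fill,
largest connected component. It separates head from background; it is
not a brain extraction, and it will fail (by design, with
`NoForegroundError`) on constant volumes. The mask becomes a point
cloud by taking every 25th foreground voxel in raster order; the
stride-25 default balances density (a few thousand points for a head
scan) against least-squares cost.

### Scalp surface

The map from angular coordinates back to 3D is an "ellipsoid with a
polynomial radius": per Cartesian axis,

    x − x_o = w₁ + (w₂ + w₃θ + w₄φ + w₅θ² + w₆φ² + w₇θ³ + w₈φ³ + w₉θ⁴ + w₁₀φ⁴) · sin θ cos φ

with factors sin θ sin φ and cos θ for the y and z axes, ten weights per
axis solved independently by `lstsq`. Ten terms is the default model
order; the per-axis residual is non-increasing as terms are added (the
designs are nested), and in practice the gain flattens near ten. A
sphere of radius R about the centroid is represented exactly (w₂ = R,
rest 0), and a 90/110/80 mm ellipsoid is approximated to under 2 % RMS
radial error.

Note one subtlety: the fitted surface is only approximately radial
about the centroid, so converting a surface point back to angular
coordinates does not exactly recover the angles it was generated from
(a few percent of the radius for a head-shaped fit, exactly zero for a
sphere). All pipeline quantities use one consistent direction —
3D → angular via `cartesian_to_angular`, angular → 3D via the fitted
surface — so this distortion cancels everywhere except in the
topographic display itself, where it is the familiar map-projection
stretching near the poles. To keep the working region away from the
poles, `snap_cog_to_equator` applies the single minimal rigid rotation
about the centroid (axis = COG direction × its equatorial projection)
that brings the data's center of gravity to inclination π/2. Rotation
is rigid, so all distance-based reports are unaffected; the rotation is
undefined (and refused) when the COG coincides with the centroid or
sits exactly on the pole axis.

### Topographic display

The globe-like projection samples the scan at the scalp surface point
of every (θ, φ) pixel by nearest-voxel lookup — no interpolation, so
raw intensities are preserved — with out-of-volume pixels set to a
background value. Default raster: full sphere at 512 × 1024 pixels
(spacing π/512 rad).

## Clustering and consolidation

Repeated-measures protocols stimulate each site several times. The
quality-threshold clustering uses pairwise 3D distances divided by the
dataset's maximum pairwise distance, so the user-facing threshold is a
fraction of the map diameter: 0 keeps every event separate and 1 merges
everything. Candidate clusters are grown greedily from every remaining
seed (add the point that least increases the diameter while the
normalised diameter stays within the threshold); the largest candidate
is extracted, ties resolving to the lowest seed index for determinism.
The threshold is a user choice made by inspection; no automatic
selection is attempted.

Each cluster is consolidated to its unweighted mean position with one
value: mean, max, min, population variance Σ(vᵢ−μ)²/N, or response
probability — the percentage of member MEPs strictly above the
binarization threshold (default 40 μV). Equality at the threshold
counts as non-responsive; the comparison is strict and configurable. A
cluster of {150, 120, 50} μV at a 100 μV threshold therefore
consolidates to 66.67 %.

## Surface fitting

Four non-parametric fitters produce S(θ, φ):

| algorithm | construction | interpolates? |
|---|---|---|
| `piecewise_cubic` | C1 Clough–Tocher on a Delaunay triangulation | yes |
| `piecewise_linear` | barycentric linear on the same triangulation | yes |
| `biharmonic_v4` | biharmonic spline, kernel g(r) = r²(ln r − 1) | yes |
| `lowess` | local first-order regression, tricube weights, span 0.25 | no |

Numerical choices: the biharmonic system is bordered with a constant
offset term (one extra unknown with Σaᵢ = 0), which leaves the
interpolation property untouched, improves conditioning, and makes
predictions exactly equivariant under value shifts; duplicate sites are
collapsed by averaging before the solve. Lowess uses the nearest
⌈0.25·N⌉ ≥ 3 sites per query and falls back to a single global linear
fit when too few are available. No fitter extrapolates: outside the
convex hull of the training sites the surface is undefined (NaN) and
those cells are excluded from every integral.

## Measurements

COG and peak are computed from the raw (consolidated) events — they
need no surface. SA and VI are discrete integrals over the dense
angular grid of the fitted surface: each cell strictly above the
threshold contributes ‖p × q‖, where p and q are the 3D edge vectors
obtained by pushing (θ, φ), (θ+s, φ), (θ, φ+s) through the scalp model.
The default measurement grid covers the training hull at s = π/512 rad;
the scheme is first-order, converging to the closed-form spherical-cap
area within 1 % at s = 0.005 rad in the tests. SA's threshold defaults
to 0 μV. Positions are reported as signed per-axis offsets plus the
Euclidean distance from the reference point, which defaults to the
dataset's imported reference and then to the head centroid. Distances
are reported in mm throughout (voxel spacing is applied on load).

Hotspot discretization seeds a watershed of the negated surface at the
local maxima whose prominence is at least `min_prominence` (default
0.1) times the global maximum — implemented via the h-maxima transform
— intersected with the above-threshold set; per-region COG/peak/SA/VI
use only within-region cells, with region COG weighted by value × patch
area (the discrete analogue of the continuous COG over the region).

## Comparison

Continuous mode fits both datasets with the same algorithm and reports
deltas (B − A) of all metrics, a difference grid over the hull overlap,
and RMSE between A's raw values and B's surface predictions at the same
angular locations, dropping A-points outside B's hull and refusing
(`NoOverlapError`, surfaced as a flagged `None`) when nothing overlaps
— RMSE between maps of disjoint regions is meaningless. Datasets
declaring different reference points are rejected
(`FrameMismatchError`).

Categorical mode takes a probability-consolidated training map and a
raw testing set: testing MEPs are binarized at the μV threshold, model
predictions at each of 1001 evenly spaced percentage cutoffs
(predicted-positive iff prediction ≥ cutoff, so cutoff 0 marks all
positive), and TPR/FPR accumulate a ROC curve whose endpoints are
forced to (0, 0) and (1, 1) by two extra cutoffs beyond the prediction
range (this also absorbs round-off that pushes an interpolated
prediction marginally outside [0, 100]). AUC is the trapezoidal
integral of the sorted curve; testing sets that are all-positive or
all-negative are rejected rather than silently reported.

## Synthetic data

The generators exist so every pipeline stage is testable with known
ground truth. The head phantom is a solid ellipsoid (default radii
80/90/75 mm, 64³ voxels at 3 mm) with optional additive Gaussian noise.
The motor map emulates a grid-mapped session: a square grid of sites
(default 0.5 cm spacing, 4 cm extent — matching dense repeated-measures
protocols; 1 cm grids are a spec away) laid over the fitted scalp
model, MEPs drawn from an isotropic Gaussian response field (default
amplitude 1000 μV, width 0.12 rad ≈ 1 cm on an adult head) at each
site's angular coordinates as the pipeline itself would derive them,
with three repeats per site, multiplicative log-normal noise of unit
mean (default CV 10 %, the order of within-session MEP variability),
optional additive floor, truncation at zero, and 0.5 mm isotropic
positional jitter for coil repositioning error. No published
distribution exists for MEP noise; log-normal-times-field is a declared
modelling choice, not a claim. All randomness hangs off one explicit
seed, and ground-truth COG/peak/SA/VI are integrated numerically from
the noiseless field at 0.002 rad resolution.

What passing synthetic tests show: the pipeline's algebra and geometry
are correct, stable under the modelled noise (mean COG recovery error
≈ 0.14 mm over 20 seeded replicates, versus the 5 mm grid spacing), and
its metrics converge with grid refinement. What they do not show:
robustness to real segmentation artifacts (hair, headrests), to
non-Gaussian multi-peak response fields beyond the two-bump
discretization tests, to vendor-specific coordinate conventions, or to
MEP noise that departs from the log-normal model.

## Problem sizes and tolerances

Tests run on desk-scale inputs chosen to keep the whole suite fast: 64³
phantoms, 81–289-site maps, measurement grids of 0.004–0.01 rad except
the 0.005 rad cap-convergence check. Interpolation identities are
asserted at 1e-6–1e-12; statistical checks (chance-level AUC at
n = 10 000) at the binomial sampling error (±0.02).

## Known limitations

- The angular parametrization distorts near the poles; equator snapping
  mitigates but does not remove this, and no equal-area projection is
  attempted.
- SA/VI integration is first-order in the pixel spacing.
- MATLAB's scattered "cubic" interpolant is undocumented; Clough–Tocher
  is the closest openly specified construction, so cubic-fit values can
  differ between implementations at the patch-smoothing level.
- Between-subject comparison is out of scope: maps are only comparable
  within one subject and one reference frame.
- Vendor session files (Nexstim/BrainSight binary exports) are not
  parsed; data enter through the neutral CSV schema.
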