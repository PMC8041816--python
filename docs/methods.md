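# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish about real acquisitions.

## Input model

The unit of input is a molecule list: drift-corrected fluorophore
blinking events (x, y in nm, intensity in photon-count-like units) for
one cropped structure — either a top-view ring or a side-view pair of
bars.  Event order is meaningless; every result is invariant under row
permutation.  Only delimited-text lists are read (vendor binary formats
are reconstruction-software internals; the interchange format is the
text export).  Column names are matched case-insensitively against an
extensible alias map; coordinate columns whose names declare pixel units
are scaled by `pixel_size_nm` (default 157.646 nm, a common EMCCD pixel
pitch at 100× magnification).

## Ring-center identification

k-means over k = 6…15 (coordinates only — intensity never enters the
distance metric), model selection by mean silhouette score, ties broken
toward smaller k.  k-means uses 20 seeded restarts; all seeds flow from
one master seed, so runs are bit-reproducible.  The two clusters with the
lowest summed intensity are flagged as background and excluded (only
k−1 when k ≤ 2, so the model is never emptied); the remaining cluster
centers are fit with a circle and its center becomes the ring center.

The circle fit is geometric least squares: a Kåsa algebraic fit
initialises a Levenberg–Marquardt refinement over the center, with the
radius profiled out (given a center, the optimal radius is the mean
distance).  Goodness of fit is a positional R²,

    R² = 1 − Σ‖pᵢ − p̂ᵢ‖² / Σ‖pᵢ − p̄‖²,

with p̂ᵢ the nearest point of the fitted circle and p̄ the centroid.
The numerator is the usual radial residual sum Σ(dᵢ − r)².  The
denominator is total positional variance rather than the variance of the
distances: the latter would make R² identically zero for the optimal
geometric fit (the fitted radius *is* the mean distance), i.e. no
definition of R² on distance-space deviations can gate anything.  The
positional form is translation/rotation invariant, equals 1 for points
exactly on a circle, and degrades sharply when off-ring clusters poison
the fit — which is what the 0.9 QC gate is for.  Structures failing the
gate are flagged, never silently dropped.

## Radial analysis

Distances from the ring center are histogrammed at 2 nm (half-open bins
[2m, 2m+2), mass conservation exact).  Bin masses at bin centers (odd
nm values — unbiased abscissae for symmetric densities at this width)
are fit by unweighted nonlinear least squares with two models:

- Gaussian: `A·exp(−(ρ−r)²/2σ²)`;
- circularly convolved Gaussian (Rice form):
  `A·ρ·exp(−(ρ²+r²)/2σ²)·I₀(ρr/σ²)` — the radial density of a circle of
  radius r under isotropic Gaussian blur σ.  The reported radius is the
  circle parameter r, not the profile mode (which exceeds r for σ > 0,
  by ≈ σ²/2r in the large-r/σ limit; the two models' fitted radii agree
  to < 0.5 nm once r/σ ≳ 15).

Numerics: the Rice form is evaluated as
`ρ·exp(−(ρ−r)²/2σ²)·i0e(ρr/σ²)` with the exponentially scaled Bessel
function, which cannot overflow.  Initialisation: r₀ at the heaviest
bin, σ₀ the mass-weighted sd; a few perturbed restarts guard against
rare non-convergence, after which a flagged fit-failure result is
returned.  By default both models are fit and the higher-R² one is
reported with the other kept in provenance; a config flag enables
1/√mass Poisson-style weighting.  Individual rings are gated at
R² ≥ 0.8; passing profiles are summed, normalized by ring count, and
refit for the cohort radius.  Cohort uncertainty is SEM = sd/√n over
per-ring fitted radii.  Averaged rings are rendered by rotating the
(interpolated or fitted) radial distribution about an image center.

## Axial analysis

A 2-component full-covariance Gaussian mixture (seeded, multiple
restarts, hard assignment by maximum responsibility) splits a side view
in two; collinear degeneracy falls back to a flagged 1D split along the
principal axis.  The brighter cluster is the one with larger summed
intensity (ties: more events, flagged).  The canonical frame puts the
midpoint of the two cluster centers at the origin and rotates the
intensity-weighted second-moment major axis of the brighter cluster onto
X; the dimmer cluster is placed at +Y by rotating a further π when
needed (a rotation, not a reflection, so geometry stays rigid).  A
near-isotropic brighter cluster (eigenvalue ratio < 1.05) has no usable
axis; orientation then comes from the perpendicular of the inter-center
axis, flagged.  The 2 nm Y histogram (grid anchored at multiples of
2 nm so cohort bins align) is fit with a sum of two Gaussians
initialised at the cluster-center Y values; distance = |μ₂ − μ₁|, QC at
R² ≥ 0.7.  Cohorts: per-axis histograms summed and normalized by
dataset count; the cohort distance comes from refitting the summed Y
distribution; the average image is the outer product of the normalized
Y and X distributions (rank 1 by construction).

## Linkage-error model

Geometry (all in-plane): primary antibody of length L = 12 nm with its
label centroid a = 6 nm from the epitope (labelling sites uniform along
the antibody); secondary label centroid b = 6 nm beyond the primary's
far end, orientation free.  End-to-end binding and coplanarity are
deliberate worst-case assumptions — they maximise the reported
uncertainty interval.  For an observed indirect-minus-direct offset Δ:

    feasible cos θ = [−1, 1] ∩ [(Δ−b)/(L−a), (Δ+b)/(L−a)]
    epitope − direct-label position = −a·cos θ
    width = a · (feasible-range length)

|Δ| > (L−a)+b = 12 nm is infeasible and raises an error.  The continuous
solution replaces per-angle enumeration; an enumeration mode (pointwise
feasibility on a θ grid, bisection-refined at the boundaries) is kept as
an independent auditing oracle and agrees to < 10⁻⁶ nm at 10⁴ grid
points.  The interpretation of "angle" is the angle between the primary
antibody axis and the measurement axis through the epitope; the
enumeration oracle makes that auditable.

## Cluster counting and statistics

Counting reuses the silhouette/k-means engine with k = 3…15 (mutant
rings can drop below 6 sites), then suppresses clusters whose summed
intensity is below 10% (configurable) of the median cluster intensity.
Group comparison: Welch's t-test (Student's optional) and Mann–Whitney
U — exact two-sided p by complete enumeration over rank assignments
(midranks for ties) whenever C(n₁+n₂, n₁) ≤ 2·10⁵, tie-corrected normal
approximation otherwise.  Reports carry mean ± SD, SEM, 95% CI and
significance markers (* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001).
Identical zero-variance groups short-circuit to p = 1, flagged.

## Synthetic-data generator

Top views: n clusters (default 9) at angles 2πj/n plus Gaussian jitter
(0.05 rad) on a circle (default radius 150 nm), 5 fluorophores per
cluster scattered with 5 nm sd, blink counts max(1, Poisson(10)),
isotropic 10 nm localization error per blink, lognormal intensities
(log-mean 6, log-sd 0.5 — right-skewed photon counts with median ≈ 400),
10 uniform background events over a 500×500 nm field.  The field and
background emulate a *tight interactive crop* around one cilium base
with sparse nonspecific binding; with that ring/cluster geometry the
radii of blurred events follow the Rice law exactly (a property test
checks the KS statistic against the closed-form CDF).  Side views: two
parallel bars (300 nm long, 10 nm thickness sd, 10 nm localization sd,
300 events each), reference bar brighter by a configurable ratio
(default 2), separated along pre-rotation Y.  Antibody displacement
re-draws each fluorophore's label along a uniformly oriented in-plane
antibody (direct: uniform along the 12 nm primary; indirect: 12 nm plus
6 nm along an independent orientation), then re-applies blink scatter.

Per-cluster random streams are spawned from the master seed, so deleting
clusters (`missing_cluster_indices`) leaves all other events
bit-identical.  Ground truth is a sidecar record, never embedded in the
molecule list.

What the generator does **not** emulate: emitter photophysics (on/off
kinetics, repeated-localization correlations), residual drift,
anisotropic PSFs, z-dependent blur, structured (non-uniform) background,
or partial labelling gradients.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated statistical
model, not robustness to every artefact of real acquisitions.

## Problem sizes and tolerances

The recovery suites use 100 simulated rings per (radius, sd) condition
across {140, 150, 165} nm × {8, 15} nm and 50 side views per separation
across {160, 190, 210, 280} nm; the standalone reproduction script runs
40 rings / 25 views per condition, sizes at which cohort-level
estimates are already stable to well under the asserted tolerances
(averaged-fit radial bias < 1 nm, cohort axial bias < 2 nm,
cohort-difference offset < 3 nm).  Clustering model-selection accuracy
is asserted at ≥ 95% over 100 fixtures; decoy background clusters in
those fixtures are placed well away from the ring annulus (one at the
ring center, one in a crop corner), since silhouette selection cannot —
and should not — resolve two decoys placed within one cluster diameter
of each other.

## Known limitations

- The silhouette criterion degrades when dense uniform background
  pervades a wide field; the pipeline assumes tight crops (the QC gates
  then catch most failures, at the cost of attrition).
- Exactly two background clusters are removed before the circle fit
  (per the counting rules of the analysis this reproduces); fields with
  more than two background blobs rely on the R² gate instead.
- The axial model fits exactly two layers; structures with three axial
  bands must be analysed as separate cohorts.
- The linkage model is 2D; out-of-plane antibody orientations would
  shrink the feasible interval, so reported widths are conservative.
- z coordinates, if present in input files, are ignored.
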