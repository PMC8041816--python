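# stormring

Particle-averaging analysis of ring-shaped protein assemblies in
single-molecule localization microscopy (STORM/SMLM) data.

Many structures at the base of cilia — the transition zone, the docking
sites of intraflagellar-transport (IFT) trains, the BBSome — are built on
the ninefold symmetry of the microtubule doublets.  Imaged by STORM, a
protein decorating these sites appears in *top view* as a ring of ~9
discrete clusters of fluorophore blinking events, and in *side view* as
two parallel bars (the target plus a brighter reference structure).
This package turns cropped molecule lists (tables of drift-corrected
blinking events: x, y in nm plus intensity) into:

- **ring radii** — the radial position of the labelled epitope from the
  cilium axis,
- **inter-ring axial distances** — the position along the cilium axis
  relative to a reference marker,
- **antibody linkage-error bounds** — how far the epitope can sit from
  the fluorophore, constrained by comparing direct and indirect staining,
- **cluster counts** — for comparing wild-type and mutant rings,

plus averaged-ring renderings and cohort statistics (mean ± SEM, Welch
t-test, exact Mann–Whitney).  A synthetic-data generator with ground
truth makes every stage testable end to end.

## Method

**Ring centers.** Events are clustered by k-means with k = 6…15; k is
chosen by the mean silhouette score.  The two clusters with the lowest
summed event intensity are removed as background, and a least-squares
circle through the remaining cluster centers gives the ring center
(geometric fit, Kåsa-initialised; QC gate R² > 0.9 on positional
residuals).

**Radii.** Event intensities are summed in 2 nm bins of distance ρ from
the center and the profile is fit with either a Gaussian
`A·exp(−(ρ−r)²/2σ²)` or a circularly convolved Gaussian (Rice form)

    A · ρ · exp(−(ρ² + r²)/(2σ²)) · I₀(ρr/σ²),

whose location parameter r is the radius of the underlying circle.
Individual rings are gated at R² ≥ 0.8; passing profiles are summed,
normalized by ring count, and refit to give the cohort radius.
Uncertainties are SEM over contributing rings.

**Axial distances.** Side views are split in two by a full-covariance
Gaussian mixture; the scene is rotated so the intensity-weighted major
axis of the brighter (reference) cluster lies along X; the 2 nm Y
histogram is fit with a sum of two Gaussians (gate R² ≥ 0.7) and the
distance between the means is the axial distance.  Cohorts are averaged
by summing histograms and refitting; the averaged image is the outer
product of the normalized X and Y distributions.

**Linkage error.** With a 12 nm primary antibody labelled at centroid
offset a = 6 nm and a secondary adding b = 6 nm beyond the primary's far
end, a direct-vs-indirect position offset Δ constrains the primary
orientation: cos θ feasible iff |Δ − (12−a)·cos θ| ≤ b, and the epitope
lies at −a·cos θ from the direct-staining centroid.  The closed form is
cross-checked by an angle-grid enumeration oracle.

## Worked example

Simulate a cohort of 12 top-view rings (true radius 150 nm) and run the
full pipeline:

```python
from stormring import RunConfig, run_pipeline, estimate_linkage

rep = run_pipeline("top_view", RunConfig(seed=42), n_simulated=12)
print(rep.n_passing, round(rep.mean, 2), round(rep.sem, 2))
print(round(rep.averaged_fit.radius_mean, 2),
      round(rep.averaged_fit.width_sd, 2))
```

prints (this exact run):

```
11 151.0 0.58
150.75 12.96
```

— 11 of 12 rings passed both QC gates (one fell below the radial-fit R²
threshold), the per-ring radii average 151.0 ± 0.6 nm (mean ± SEM), and
the fit to the averaged profile gives a 150.8 nm radius with a 13 nm
ring width, bracketing the simulated truth of 150 nm.  A direct/indirect
staining offset of +6 nm constrains the epitope to lie 0–6 nm inward of
the direct label:

```python
est = estimate_linkage(6.0)
print(est.epitope_offset_range, est.width)   # (-6.0, -0.0) 6.0
```

The same stages are available from the shell:

```sh
stormring run --kind top_view --simulate 12 --seed 42 --out out/
stormring simulate --config ring.yaml --seed 1 --out ring
stormring fit-ring ring.tsv
stormring linkage --offset 6
```

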