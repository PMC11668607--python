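# Methods

This note documents the models implemented in `gediagb`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that affect results.

## Allometric plot biomass

Single-tree aboveground biomass follows the binary power-law models of
the Chinese forestry-industry standards for *Picea* and *Abies*:

    M_spruce = 0.09152 · D^2.21060 · H^0.25663
    M_fir    = 0.06127 · D^2.05753 · H^0.50839

with D the diameter at breast height (cm) and H tree height (m). The
per-tree unit is taken as kilograms — the convention of the LY/T
standard series — and conversion to tonnes happens at plot aggregation:
plot AGB density (t/hm²) is the tree-mass sum divided by plot area.
This unit decision matters: plot-level magnitudes (tens to hundreds of
t/hm²) depend on it, so it is fixed here rather than configurable.
Species outside the two models raise an error; mixed-stand callers are
expected to exclude them explicitly.

## Inverse distance weighting

The interpolator predicts `Z*(x₀) = Σ wᵢ Z(xᵢ)` with weights
`dᵢ⁻ᵖ / Σ dⱼ⁻ᵖ` over the N nearest measured footprints.

Defaults and rationale:

* **p = 2** — the common geostatistical default among the conventional
  choices p = 1 or 2.
* **N = 12 neighbors, unlimited search radius** — a standard
  moving-neighborhood size; N = 0 uses all points. With a finite radius,
  cells with no neighbor become nodata rather than extrapolations.
* **30 m cells** — matches the scale of the ~25 m footprints; grids are
  axis-aligned, row-major, origin at the upper-left corner, and
  predictions are made at cell centers. Points exactly on the outer
  boundary belong to the edge cell.
* **Exact interpolation** — a query within 10⁻⁹ m of a measured point
  returns that measurement, avoiding the division by zero; ties among
  equidistant N-th neighbors resolve to the lowest shot id (tables are
  sorted by shot id before fitting), making predictions
  order-independent.

Neighbor search uses a k-d tree; the weighting itself is implemented
here and verified in tests against an all-pairs brute-force oracle to
1e-10 relative on instances of up to 500 points.

Accuracy is scored with R² = 1 − SS_res/SS_tot, RMSE and MAE between
observed and predicted values. When the observations are constant,
SS_tot = 0 and R² is undefined: the metrics object flags this
(`r2_defined=False`) instead of propagating NaN silently.

## The footprint-density experiment

For each thinning interval k the runner: thins the quality-filtered
table per beam (keeping within-beam shot ranks ≡ offset mod k), splits
the survivors into a seeded uniform 70/30 train/validation partition,
interpolates every variable from the train fraction only, and scores at
the held-out footprints. Validation points are never interpolation
sources. Thinning is rank-based and deterministic by default; a seeded
random per-beam offset reproduces random extraction where that is
preferred. Whether thinning should pool beams or act per beam is not
determined by the source workflow; per-beam is the default and pooled
ranking is available via a flag.

The direction of the density–accuracy relationship is deliberately not
asserted anywhere: with track-clustered validation points, accuracy can
*increase* as footprints are removed (validation points end up farther
from their sources in a way that differs between density levels), which
is the opposite of classical sampling theory under uniform random
sampling. The runner reports whatever the input geometry produces.

## Biomass modeling

Features are the interpolated surfaces sampled at the cell containing
each plot center — deliberately no bilinear smoothing, so the feature
semantics match the IDW surface exactly. Nearest-footprint attachment
is a reasonable alternative the data cannot arbitrate; surface sampling
is the implemented default. Variables are ranked by |Pearson r| against
plot AGB (significance marked at 0.05/0.01; zero-variance features are
flagged and ranked last) and the top five enter the models.

The three learners use fixed hyperparameters: random forest with 300
trees and 2 candidate variables per split; RBF support-vector
regression with C = 1 and γ = 0.92 (γ being the RBF kernel coefficient,
in e1071 notation "g"); k-nearest-neighbor regression with k = 9.
Cross-validation is a seeded shuffled 10-fold partition at plot level —
no spatial blocking, which is a known optimism source flagged here as a
limitation. Both the per-fold-averaged metrics and the pooled
out-of-fold metrics (every plot predicted once by a model that never
saw it) are reported.

Wall-to-wall prediction applies the trained model to every cell whose
feature vector is complete; the map summary reports min/mean/max in
t/hm² and the total in 10⁴ t (mean × mapped area). Random-forest and
k-NN maps are averaging predictors and therefore bounded by the
training response range — asserted in tests; SVR is exempt.

## Waveform processing

Smoothing convolves with a unit-area Gaussian kernel, width 6.5 ns
interpreted as the kernel **sigma** (an `interpret="fwhm"` option
divides by 2√(2 ln 2); the source description is ambiguous). Boundaries
use reflective padding, so constant waveforms are invariant and energy
is conserved to ~1e-6. The background threshold is exactly
`noise_mean + c·noise_std`. `searchstart`/`searchend` are the first and
last bins above threshold; `toploc`/`botloc` are the outermost positions
where two *adjacent* bins both exceed it — implemented literally; a
single isolated super-threshold bin yields a search window but no
top/bottom location. Second-pass peak filtering (ground vs canopy
peaks) is out of scope: footprint products already contain those
results.

## The synthetic generator

The generator emulates what the analysis assumes, not the instrument
physics:

* **Metric fields** are stationary Gaussian random fields with an
  exponential covariance, synthesized spectrally (white noise filtered
  by √S(k), S(k) ∝ a²/(1+(ak)²)^{3/2}, on a 2×-padded FFT grid) and
  rescaled to the exact target sill; a nugget fraction is added as
  white noise. Defaults: range 12 km, nugget 0.02. The correlation
  length is calibrated so that the density experiment on the default
  scene reproduces the accuracy regime observed in practice for
  interpolating these metrics at ~1.3 k-footprint density (validation
  R² in the 0.8–0.9 range at interval 100); substantially rougher
  fields understate what real acquisitions support. Per-metric means
  and sills default to values plausible for a high-elevation spruce-fir
  landscape (cover ≈ 0.55, DEM ≈ 3500 m, pai ≈ 3, …).
* **Track geometry** is planar: straight beam lines per overpass
  azimuth, eight beams 600 m apart centered on the scene, shots every
  60 m starting where each line enters the extent. No orbital
  mechanics, Earth curvature, or cloud gaps. The default scene is a
  42 km square with 21 crossing overpasses — 131,808 raw shots, chosen
  to match the ~1.3×10⁵-shot scale at which interval-100 thinning of
  the filtered set retains ~1.3×10³ footprints.
* **Quality contamination** draws each violation independently per
  criterion (quality_flag, degrade_flag, sensitivity); real flag
  correlations are not modeled. Defaults 5 %/2 %/5 %.
* **Plots** (default 138, 0.0667 hm²) get tree lists with lognormal
  DBH, Chapman-Richards heights H = 1.3 + a(1−e^{−bD})^c with
  multiplicative lognormal noise, and a configurable spruce fraction.
  When AGB–field coupling is configured, trees are added one at a time
  until the allometric plot AGB best matches the coupled target
  (linear combination of local field values plus Gaussian noise,
  floored at 1 t/hm²) — so plot AGB is *always* the allometry of the
  actual tree list, and the only residual at zero coupling noise is the
  discrete-tree granularity. The default scene couples five structure
  metrics (rg, pai, pgap_thea, cover, fhd_normal) with per-SD strengths
  (37, 30, −25, 25, 20 t/hm²) about a 100 t/hm² mean, and sets the
  coupling noise SD to 30 % of the deterministic AGB SD — yielding plot
  populations with mean ≈ 95 and SD ≈ 60 t/hm², the magnitude range of
  montane spruce-fir inventories.
* **Waveforms** are a Gaussian noise floor plus rectangular signal
  bumps with the true extent recorded; the default 2 ns bin width keeps
  the 6.5 ns smoothing sigma at 3.25 bins so detection overshoot stays
  within a few bins of a rectangular edge.

Determinism: every generator is a pure function of its spec and seed;
per-component sub-seeds are derived by mixing the seed with a stable
CRC-32 of a component label, so adding a metric does not perturb the
others and all derived seeds stay below 2³¹.

What passing tests on synthetic data do **not** show: robustness to
geolocation error, correlated quality flags, non-stationary or
anisotropic canopy structure, species mixtures beyond spruce/fir, or
the radiometric behaviour of real waveforms. Results on real granules
depend on all of these.

## Problem sizes used in the test suite

The default synthetic scene (42 km, 131,808 shots, 14 metric fields at
60 m) builds in ~10 s; the end-to-end recovery check runs it for five
seeds with 120 m feature rasters, chosen as the coarsest sampling that
leaves the plot-feature extraction indistinguishable from the 30 m
default in this smooth-field regime. The density-experiment check uses
a 15 km scene. Oracle-equivalence checks cap at 500 measured points and
1000 queries, where the all-pairs brute force is still instant.

## Known limitations

* Planar coordinates throughout synthetic mode; real lon/lat data must
  be projected before interpolation (a config choice, not automatic).
* The greedy tree-fill couples plot AGB to fields with a granularity of
  one tree (~2–5 t/hm² at the default plot area); exact equality with a
  continuous target is not attainable by construction.
* Raster output is ESRI ASCII grid — readable everywhere, but without
  an embedded CRS; the grid convention is documented above.
* `read_l2b` maps the official beam-group dataset layout by default but
  does not parse orbit metadata or handle L2A/L4 products.
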