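# Methods

## Scope and model

`telostorm` quantifies the spatial extent and shape of telomeres imaged by 3D
stochastic optical reconstruction microscopy (STORM). A telomere appears in a
molecule list as a cluster of hundreds of localizations; the scalar shape
statistic is the radius of gyration

Rg² = (1/N) Σₖ ‖r⃗ₖ − r⃗_com‖²,

the root-mean-square distance of the N localization points from the cluster's
center of mass. Rg is computed in 3D by default, with a 2D (XY-projected)
mode exposed, since for some historical datasets the dimensionality of the
published statistic is ambiguous. Two exact identities back every computed
value: the pairwise-distance form Rg² = (1/(2N²)) Σᵢ Σⱼ ‖r⃗ᵢ − r⃗ⱼ‖² (used
as an independent oracle in tests), and the trace identity Σ axis-spreads² =
Rg², which links Rg to the principal-axis decomposition used for the
anisotropy ("compact in one dimension") read-out.

The package also carries the companion assays of a telomere chromatin study:
two-channel nuclear foci scoring (% area per nucleus, % telomeres
colocalized with a partner channel, % telomere-dysfunction-induced foci),
the telomere restriction fragment (TRF) mean length
ΣIntᵢ / Σ(Intᵢ/MWᵢ) — an intensity-weighted harmonic mean that weights
fragment *number* rather than mass — and ChIP dot-blot normalization to a
10% input spot with optional per-H3 renormalization.

## Pipeline stages and their parameters

**Drift correction** (`correct_drift`). Localizations are binned temporally
(`frames_per_bin`, default 500 frames), each bin rendered as a 2D histogram
(`pixel_size`, default 30 nm — of the order of the localization precision),
and each bin's displacement relative to the first bin estimated from the
peak of the zero-padded FFT cross-correlation with per-axis parabolic
sub-pixel interpolation. Histograms are Gaussian-smoothed (`smooth_px`,
default 2 px); the broader smoothing makes the correlation peak of sparse
histograms smooth enough that the parabolic fit is accurate. The per-bin
displacement is linearly interpolated across frames and subtracted. Axial
drift correction (1D z-histogram correlation) is available behind
`correct_z` but off by default: lateral drift dominates in focus-locked
systems. Bins with fewer than `min_bin_count` localizations are interpolated
from their neighbours with a warning.

**Clustering** (`cluster_localizations`). The original workflow selected
telomeres manually; this package substitutes DBSCAN in 3D with
`linkage_radius` = 75 nm and `min_cluster_seed` = 10 (both configurable).
Rationale: telomere foci are well separated (hundreds of nm) relative to
their ~80 nm Rg, so density-based clustering with a radius below the typical
inter-telomere distance and above the localization precision recovers the
manual selection; on simulated nuclei the recovered clusters are ≥ 95% pure
against generator ground truth, and the recovered Rg of isolated clusters is
unbiased.

**Filtering** (`filter_clusters`). Three screens, in order: strictly more
than `min_points` localizations (default 200 — the boundary is exact: a
200-point cluster is excluded, 201 kept); center of mass within
`focal_window` of the focal plane (default 250 nm about the z-depth
midpoint — "near the focal plane" is qualitative in the source workflow, so
this is an explicit, configurable choice); and optionally an XY overlay mask
gating out non-telomeric background, mirroring the
conventional-image-overlay exclusion step.

**Irregular fraction** (`fraction_irregular`). The cutoff is always the
*recomputed* arithmetic mean Rg of the designated reference group on the
dataset at hand — a printed cutoff value from any particular study is that
study's realized mean, not a constant of the method. The comparison is
inclusive ("equal or greater"), so ties at the cutoff count as irregular.
For a right-skewed Rg distribution the reference group's own fraction falls
slightly below 0.5 (mean > median); only a symmetric distribution splits at
exactly one half.

**Statistics** (`stats`). Group means are reported with s.e.m. =
s.d./√n. Panels against a control use one-way ANOVA with Dunnett's
many-to-one adjustment; all-pairs Rg comparisons use Tukey's HSD; simple
two-group contrasts use the two-tailed unpaired t test (equal-variance by
default, Welch optional), all at the 95% confidence level via
`scipy.stats`. Per-telomere Rg values from the same nucleus are treated as
independent observations — this matches the convention of the source
workflow and is a documented caveat, not a modelling claim; a mixed-effects
treatment is out of scope. Degenerate zero-variance t-test input with equal
means returns p = 1 by convention.

## What the synthetic-data generator emulates

The generator reproduces the acquisition statistics of the imaging
conditions the pipeline targets:

* **Localization error.** Independent Gaussian error per axis with
  σ_xy = 30 nm and σ_z = 70/2.355 ≈ 29.7 nm. The nominal "~30 nm XY
  precision" is interpreted as 1σ and the "~70 nm Z resolution" as a FWHM;
  neither convention is universal, so both defaults are configurable.
* **Blinking.** Each emitter yields a geometric number of localizations
  (mean `blink_mean`, default 3). The geometric family is the simplest
  heavy-tailed choice that reproduces the broad observed spread of
  localizations per telomere; with the default 200 emitters per telomere it
  gives ~600 localizations per telomere, matching the per-group averages
  (420–664) the pipeline's study conditions are built around.
* **Acquisition geometry.** 35,000 frames, 700 nm z-depth (focal plane at
  z = 0), uniform frame assignment, optional per-frame drift function, and
  homogeneous-Poisson background localizations per µm³.
* **Structures.** Uniform balls (globular telomeres; Rg = √(3/5)·R),
  triaxial ellipsoids with one short axis for the irregular
  "compact in one dimension" class, and segmented paths (random polylines
  with radial jitter) as an alternative irregular model. Per-telomere size
  heterogeneity is lognormal with CV 0.25 by default, chosen to reproduce
  the wide per-nucleus Rg spread seen in real per-telomere scatter plots.
  `radius_for_target_rg` inverts the noise-additivity law
  E[Rg_obs²] = Rg_struct² + 2σ_xy² + σ_z² so study arms can be specified by
  their intended *observed* RMS Rg.

Ground truth is recorded everywhere: per-structure emitter Rg and noise-free
(blink-weighted) Rg, cluster membership labels, planted foci overlap plans,
per-band gel compositions and their exact weighted-mean length, and dot-blot
ratio designs. All generators are bit-reproducible from a seed.

What the generator does **not** emulate: camera-frame formation and PSF
fitting (the pipeline starts at the molecule list), dye photophysics beyond
blink counts, chromatin polymer structure, spatially varying background, and
the deconvolution/Z-projection upstream of foci scoring (foci images are
generated directly as 2D projections). Passing tests therefore demonstrate
correctness of the analysis given a molecule list or projected image with
these statistics — not robustness to upstream fitting artifacts.

## Numerical choices

* Rg uses the population (1/N) normalization of the defining formula, not a
  ddof-corrected variance.
* Anisotropy takes √eigenvalues of the (1/N) covariance; clusters with
  N < 3 or rank ≤ 1 (collinear) are flagged degenerate rather than silently
  returning zeros. Planar clusters are valid (third spread 0).
* The drift cross-correlation peak is refined per axis by a parabolic fit
  through the peak and its two neighbours; a non-concave neighbourhood falls
  back to the integer lag.
* Ladder calibration interpolates log10(MW) piecewise-linearly in migration
  position; anchors are reproduced exactly, queries beyond the anchors warn
  and extrapolate from the outermost segment, and profiles whose nonzero
  support leaves the calibrated domain are an error unless extrapolation is
  explicitly allowed.
* Lane background subtraction is a centred rolling minimum (default window
  51 samples); negative post-subtraction samples are clipped to zero with a
  warning.
* Foci are 8-connected components; `min_area` defaults to 4 px; the
  colocalization overlap criterion is ≥ 1 shared pixel (configurable).
  Thresholds are fixed global intensities, set once per channel per
  experiment — per-group thresholds are not expressible in the scoring
  configuration, by construction.
* The permutation null repositions each partner focus's full pixel set
  uniformly inside the nucleus mask (rejection-sampled so the footprint
  stays inside), which makes the analytic expectation exact for point-like
  reference foci.
* Pipeline randomness derives from one root seed expanded via
  `numpy.random.SeedSequence.spawn` into per-nucleus substreams, so reports
  are byte-identical across runs and stages are independently re-runnable.

## Validation problem sizes

The bundled validation suite and `scripts/acceptance.py` use problem sizes
chosen to make Monte-Carlo error small relative to each tolerance while
keeping a desk-scale runtime: 100 random clusters (10–2000 points) for the
pairwise-identity check; 10⁵ localizations for the uniform-ball closed form
(1% tolerance); 200 clusters for noise additivity (2%); 5,000-frame
acquisitions with 50 nm injected linear drift for drift recovery (per-bin
RMSE < 5 nm, Rg restored within 5%); 100 seeded replicates of a four-arm
design (~450 telomeres/arm, one arm with an 8% larger mean Rg — an
84 → 90.7 nm contrast) for discrimination power; and 1000 replicates for type-I calibration of the t/Dunnett/Tukey
procedures, with a 10⁴-resample permutation oracle for the t test.

## Known limitations

* DBSCAN can merge telomeres closer than the linkage radius and trims
  extremely sparse cluster peripheries; at realistic inter-telomere
  distances this is negligible, but densely packed nuclei would need a
  smaller radius or a different segmentation.
* Drift correction assumes the field contains enough structure for
  cross-correlation; a nearly empty bin falls back to interpolation.
* The TRF formula is evaluated on profile samples as printed — no bin-width
  reweighting — so strongly non-uniform sampling of a lane should be
  resampled first; on smooth profiles halving the sampling changes the
  result by < 0.5%.
* The irregular-fraction statistic inherits the variance of the reference
  group's mean; with small reference groups the cutoff itself is noisy.
* Foci scoring is 2D on projected images; overlapping nuclei and 3D focus
  structure are out of scope.
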