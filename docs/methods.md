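# Methods

This note documents the models behind `chrysaspec`, the choices made
where the design was genuinely open, and what the synthetic data can
and cannot establish.

## The measurement model

A line-scan NIR imaging spectrograph observes a scene as a hypercube
`data[line, sample, band]` over 256 bands spanning 874–1734 nm. The
band-center axis is taken as linear between those endpoints, because
only the endpoints and the band count are known; on that convention the
conventional "74th waveband" (1-based) used for segmentation sits at
≈1120 nm, and the 975–1646 nm window holds 199 bands. A real
spectrograph's axis is slightly nonlinear, so counts quoted for such
windows can differ by one band from the linear convention; the axis is
header-overridable wherever cubes are read.

Raw counts are converted to relative reflectance per pixel and band:

    R = (I_raw − I_dark) / (I_white − I_dark)

Dark and white references may be full frames, single scan lines
(broadcast along the scan direction), or per-band vectors. Pixels where
`I_white − I_dark ≤ ε` (ε = 1e−6 count units) carry no radiometric
information; they are masked invalid and excluded from every downstream
statistic rather than becoming infinities. The transform is invariant
to rescaling all three inputs by a common positive factor, which the
tests assert.

## Segmentation

Foreground is `reflectance > 0.122` (strict) on the band plane nearest
1119 nm, intersected with the valid-pixel mask. Connected components
with area strictly below 40 px are discarded; a 40-px component is
kept. Both comparisons had to be fixed by fiat — either convention is
defensible — and they are configuration with these defaults.
8-connectivity is the default for roundish blobs; 4-connectivity is
available. Components are labeled 1..K in raster-scan order of their
first pixel, so labels are reproducible. Touching-flower separation
(watershed) is deliberately out of scope: the imaging protocol places
single flowers separately.

## Pixel-wise preprocessing

Two chains are supported, `[WT]` and `[WT, SNV]`, and averaging over a
region always happens **after** the per-pixel chain; for the nonlinear
SNV step the order changes the answer, and a test pins the pixel-first
order.

**WT smoothing** is a level-3 Daubechies-8 discrete wavelet
decomposition with all detail coefficients zeroed before
reconstruction — an approximation-only, deterministic smoother.
Zeroing (rather than thresholding) was chosen as the simplest seed-free
reading of "smoothing"; a thresholding rule would introduce a tuning
constant without changing any qualitative behavior here. Boundaries use
symmetric extension. Two properties matter and are tested: the operator
is linear, and Daubechies 8's eight vanishing moments annihilate the
*central* detail coefficients of polynomials up to degree 7 to machine
precision. Note the boundary caveat: no finite-signal extension makes
polynomial reproduction exact at the edges (a straight line already
picks up ~3e−3 edge error over 256 points), so edge bands of a smoothed
spectrum are mildly biased. All 256 bands are nevertheless retained —
the bias is identical across samples and harmless to regression.

**SNV** maps each spectrum to zero mean and unit standard deviation
using the n−1 (sample) denominator, the dominant chemometric
convention. Constant spectra are rejected as degenerate.

## Reference-assay arithmetic

The colorimetric reference methods enter only through their standard
curves. Units: the glucose curve's concentration is mg/mL at the 1-mL
calibrated volume before reagent addition (its stock series spans
≈0.02–0.10 mg/mL, keeping absorbance in the photometric range for a
slope of ≈9.9 per mg/mL); the rutin curve's concentration is µg/mL at
the 25-mL final volume (slope ≈0.013 per µg/mL). The dilution chain
(sample mass, extract volume, aliquot, assay volume, concentration
unit) is explicit configuration on `AssayDesign` because the full bench
arithmetic is not recoverable from the published volumes alone; the
defaults reproduce the expected % w/w ranges under unit analysis, e.g.
an in-tube 0.047 mg/mL glucose reading maps to 3.76 % w/w with the
0.25 g / 100 mL / 0.5 mL → 1 mL design.

## Calibration/prediction split

Samples are ranked by reference content (stable sort; ties keep input
order). In each consecutive triple of ranks, the first and third go to
calibration, the second to prediction; leftovers go to calibration.
This yields |calibration| = 2⌊n/3⌋ + (n mod 3) — 186/93 at n = 279 —
and guarantees the prediction set is spanned by the calibration range.
The ranking is per constituent, so the two analytes use different
splits of the same samples.

## Regression engines

**PLS.** `PLSRegressor` mean-centers X and y (no per-band autoscaling —
reflectance bands share units and autoscaling would inflate noise
bands) and selects the number of latent variables in 1..20 minimising
leave-one-out RMSECV, smallest count on ties. The candidate bound is
clipped to the data rank and fold size with a warning. For efficiency,
each CV fold fits once at the maximum count and evaluates all smaller
counts from the cumulative coefficient path (the bilinear
decomposition's per-component additivity makes this exact; a test
checks it against direct per-count fits). The default of 20 leaves
ample headroom: optima on both synthetic and typical real NIR data sit
well below 10.

**LS-SVM.** Training solves the (n+1)-dimensional KKT system

    [[0, 1ᵀ], [1, K + I/γ]] · [b; α] = [0; y]

with RBF kernel `K_ij = exp(−‖x_i − x_j‖²/σ²)` (σ² divides the squared
distance directly). Leave-one-out residuals come from the closed form
`r_i = α_i / (A⁻¹)_ii` on the inverse KKT matrix — equivalent to n
refits but costing one factorization — verified in the tests against
naive per-fold refits. Hyperparameters are selected on a coarse 10×10
log-spaced grid (γ ∈ 10⁰..10⁷, σ² ∈ 10⁰..10⁵) followed by a 5×5
refinement spanning one coarse step around the optimum; ties keep the
first candidate in a fixed iteration order so selection is
deterministic. The ranges comfortably bracket the optima observed for
spectra of this scale; the refinement may step slightly outside the
coarse bounds, which is intended. A singular system raises with the
offending (γ, σ²) reported. k-fold CV is available as a speed option
for both engines but leave-one-out is the default.

## Evaluation and maps

R² is 1 − SSres/SStot (not squared Pearson correlation — the two only
coincide for fits with intercept on the same data). RPD divides the
prediction set's reference SD (n−1) by RMSEP; this definition
reproduces the published summary-table RPDs exactly from their printed
SD/RMSEP pairs, which is what pins it down. Interpretation bands:
RPD < 2 unusable, 2–2.5 usable, 2.5–3 good, > 3 excellent; R² < 0.61
unusable, 0.61–0.81 usable, 0.81–0.9 good, > 0.9 excellent. Metrics
are kept at full precision internally and rounded only for display.

Model comparison ranks by RPD descending with RMSEP ascending as the
tie-break; the winner renders the maps. Maps assign each flower a
single value (its mean preprocessed spectrum's prediction) — per-flower
rather than per-pixel because grading decisions are per flower; a test
asserts zero within-flower variance. Map scenes are chosen as the
*representative* prediction-set sample of each size class (contents
closest to the class means in pooled-SD units), so the mapped class
trend reflects the class, not one arbitrary draw. Pseudocolor images
stack the 1000/1200/1400 nm planes min–max scaled per channel over
valid pixels; a zero-range channel maps to 0.

## The synthetic-data generator

One *sample* is a handful of five same-class flowers imaged together in
one 160×160 px scene and sharing one assayed chemistry value — the
in-memory analogue of a pooled 3-g specimen. The study-scale default is
93 samples per class × 3 classes = 279.

What it emulates, and why these numbers:

* **Three size classes** (disk radii 8/14/20 px on a 0.05-reflectance
  background) with polysaccharides increasing (class means
  3.50/3.76/4.05 % w/w) and flavonoids decreasing (10.00/9.11/8.20 %)
  with flower size. Within-class SDs (0.167 and 0.447 %) are set so the
  pooled SDs come out at ≈0.28 and ≈0.86 % — the reference-chemistry
  summary this generator is meant to mirror. Class draws are clipped at
  ±2.5 SD.
* **Spectral signatures**: class baseline plus fixed Gaussian peaks at
  1119 and 1311 nm (amplitudes 0.060/0.045, σ 28/32 nm), minus
  content-proportional Gaussian troughs at 1210 nm (0.08 reflectance
  per % polysaccharides, σ 30 nm) and 1487 nm (0.03 per % flavonoids,
  σ 40 nm). Baselines rise gently with size (0.40/0.41/0.42): flower
  size and polysaccharide content rise together, so a large baseline
  spread would confound—and with a +0.02 step would nearly cancel—the
  trough signal between classes; the narrow spread keeps the
  content–reflectance correlation at the 1210 nm trough near −0.95
  across samples while preserving the size-orders-baseline trend.
* **Sensor model**: raw counts are `dark + R·(white − dark) + noise`,
  the exact inverse of the calibration equation, with deterministic
  band-dependent dark/white single-line references and i.i.d. Gaussian
  noise of sd `noise_sd · (white − dark)` counts (noise_sd = 0.005
  reflectance units). At zero noise the calibration round-trip is exact
  to < 1e−10, which the tests assert.
* **Irreducible error**: each flower's contents jitter by 3 % (relative,
  clipped at zero) around the sample's assayed value, standing in for
  flower-to-flower heterogeneity plus reference-assay error — the
  assays' published relative SDs (2.89 %/2.35 %) motivate the scale.
  Averaged over five flowers this floors the achievable RMSEP and holds
  end-to-end R²p in the mid-to-high 0.9s instead of ≈1, matching the
  performance class the pipeline is meant to demonstrate.

Randomness: one integer seed spawns child streams in a fixed order
(stream 0: chemistry, class by class, polysaccharide then flavonoid
then flower jitters; stream 1+i: scene i's placement and noise), so any
scene regenerates bit-identically on demand and the dataset never needs
to be held in memory.

What it does **not** emulate: petal BRDF and shading, line-scan
artifacts (smile/keystone, stray light), instrument axis nonlinearity,
spatially correlated noise, within-flower chemical gradients, and
touching flowers. Consequently, passing tests show the *pipeline logic*
is correct and recovers known structure at realistic noise; they do not
certify instrument-specific performance on real flowers.

## Problem sizes

Unit tests run on 96–120 px scenes with 2–3 flowers and a handful of
samples; the end-to-end checks and the acceptance script run the full
279-sample study at default geometry (about two minutes of scene
rendering plus model fitting on one CPU). The class-statistics
convergence checks draw 500 samples per class of chemistry only, which
needs no rendering.

## Known limitations

* The linear wavelength axis is an approximation; band indices quoted
  for real instruments can be off by one near window edges.
* PLS deserialization returns the collapsed linear predictor, not the
  factor structure; refit if loadings are needed.
* The LS-SVM grid, while wide, is log-discrete; pathological kernels
  between grid points are possible in principle.
* `rank_split` assumes exchangeable ties; with heavily quantised
  reference values the middle-of-triple rule can correlate with input
  order.
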