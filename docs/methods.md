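# Methods

`wormcars` quantifies label-free coherent anti-Stokes Raman scattering (CARS)
images of *C. elegans* to measure two linked processes: aberrant accumulation
of secreted yolk lipoprotein in the pseudocoelomic cavity, and lipid delivery
into the developing oocyte queue. Because no raw microscopy from the original
study is available, the package ships a seeded synthetic generator whose
defaults plant the published measurement statistics as ground truth; every
analysis stage is then validated closed-loop by rendering scenes and
recovering the planted values through the same chain a microscopist would run.

## Accumulation quantification

A frame at the lipid band (~2845 cm⁻¹, CH₂ stretch) is divided by the mean
intensity of an operator-chosen surrounding-buffer ROI to give a
dimensionless ratio image. Pixels with ratio in `[ratio_low, ratio_high]`
(default 1.47–3.12) inside the pseudocoelom-eligible mask — internal organs,
embryos and body wall are excluded up front via the label raster — are
binarized and grouped into connected components (8-neighbour by default, so
diagonally touching polygon pixels stay one blob); components smaller than
`min_area` (default 10 μm²) are discarded, matching the method's measured
detection limit. Component areas are pixel counts × pixel area.

Pooled areas over a cohort are binned at `bin_width` = 20 μm²; the per-worm
frequency times the bin midpoint gives the area-contribution curve, whose sum
approximates the mean total accumulation area per worm. The midpoint
representative minimizes binning bias; the conservation error is bounded by
`n_bins × (bin_width/2) × max frequency` and vanishes when areas sit on bin
midpoints (both properties are tested). `fraction_below(cutoff)` summarizes
the curve (e.g. the wild-type "~72% of contribution below 80 μm²" statistic),
counting straddled bins pro rata.

Design points the underlying measurement leaves open, decided here:
thresholding is per-pixel (component mean ratios are still reported for
comparability); components clipped by the eligible-mask boundary keep their
visible area; no smoothing is applied before thresholding; the band is a
parameter (default 2845 cm⁻¹). The large/small accumulation distinction is
reported as a continuous size, since no class boundary is defined anywhere;
the generator alone uses a 30 μm² boundary to decide which contrast
distribution a planted blob samples from.

## Oocyte quantification

Per-oocyte lipid content is the integrated CARS statistic Σ√(I − B) over the
oocyte mask, with B the mean intensity of the oocyte's nucleus (the
non-lipid cellular background). Negative background-subtracted values are
clamped to zero before the square root. The sentence defining B admits two
readings — "background = nucleus mean" vs "a separately determined background
subtracted from the nucleus mean"; the first is implemented. The square-root
sum is treated as the quantity linear in lipid amount throughout (the
generator's inverse mapping relies on the same convention, so the chain is
self-consistent and the noiseless recovery is exact by construction).

Carrier (GFP-tagged yolk protein) content is the plain background-subtracted
sum over the oocyte, with background the mean of a carrier-negative region;
fluorescence is linear so no square root is applied. Δ signals reference the
−5 oocyte, whose carrier signal is essentially undetectable. The carrier–
lipid regression is ordinary least squares of mean ΔCARS on mean ΔGFP across
positions −4…−1 (position means, matching how the published correlation was
computed), and its intercept carries the carrier-independent delivery
contribution.

Oocyte geometry: the cylinder model `volume = π × length × (width/2)²`.
Length and width come from mask principal axes — orientation from second
moments, extents from the projected pixel footprint. A pure second-moment
ellipse was rejected because it overestimates a rectangle's length by ~15%
(4σ vs the true extent); the extent estimator recovers rectangle sides,
disk diameters and ellipse axes exactly up to discretization (~1 px) and is
rotation-invariant, which is what a manual length/width measurement
approximates.

## Reproduction metrics

Per-worm ovulation rate = (eggs laid + final retained − initially retained) /
(hours × gonad arms). Negative rates (inconsistent counts) are returned with
a warning, never clamped, because they diagnose assay errors. Rates are per
gonad arm; per-worm rates are 2× under the default two arms. Lipid delivery
rate across the −n → −(n−1) transition is the lipid increment times the
ovulation rate (the inverse ovulation rate being the mean residence time per
position); the rates telescope exactly to C(−1) − C(−5) per unit residence
time, tested to 1e-12. Normalization against a reference strain divides each
transition by the reference's same transition by default (a switch selects
the single −2→−1 reference instead; which convention the original figure
used is not stated).

## Statistics

Group comparisons use Welch's two-sided unequal-variance t test — the test
family behind the published star codings is not named, and Welch is the
robust default across strains with unequal spreads; it is cross-checked
against a studentized permutation oracle in the tests. Pearson's
product-moment r serves the strain-level metric-vs-egg-number correlations
(computed on strain means, matching the 9-condition design), the per-pixel
protein/lipid band co-localization, and the oocyte size–lipid correlation.
Leave-one-out recomputation (e.g. excluding *fat-1*, whose accumulation
reflects carrier over-production rather than uptake failure) is supported.
No multiple-testing correction is applied by default; a Bonferroni helper
exists.

## Synthetic generator

The generator renders a 512 × 512 raster for the ~141 × 141 μm² field
(pixel edge 141/512 ≈ 0.2754 μm — chosen so blob areas of tens of μm² span
hundreds of pixels; the acquisition pixel count was never published), three
bands (1665/2200/2845 cm⁻¹), a GFP channel and a label raster. Counts are
12-bit (0–4095). Scene content:

* **Accumulations**: random convex polygons (5–8 vertices, trimmed to the
  target pixel count) in the pseudocoelom band, per-blob contrast drawn from
  the strain's large (2.53 ± 0.59) or small (1.69 ± 0.22) statistics.
* **Lipid droplets**: circles in the hypodermis strip at contrast 4.39 ± 0.21.
* **Oocytes**: five vertical ellipses, linear size factors 0.62…1.00 of the
  −1 oocyte, whose length/width are drawn per worm (wild type 50.9 ± 2.0 ×
  22.4 ± 1.0 μm, giving the ~20000 μm³ mature volume). Cytoplasm intensity is
  set so Σ√(I − B) equals the profile's lipid content exactly before noise;
  the GFP channel renders carrier = max(0, lipid − offset)/slope the same
  way. The wild-type relative profile (1/3, 0.45, 0.55, 2/3, 1) fixes the
  +50% −2→−1 step; mutants scale it (fat-2 × 0.75 ⇒ the 25% −1/−2 deficit
  and, with its 0.5 /arm/h ovulation rate, a −2→−1 delivery rate ~15% of
  wild type, consistent with the reported hierarchy).
* **Noise**: multiplicative Gaussian with CV 0.05 by default (speckle-like;
  no additive read noise — no noise model was published), then quantization
  and clipping. Profiles whose contrast × buffer would saturate are rejected.
* **Texture**: an optional shared within-blob texture (off by default) gives
  the protein/lipid bands their per-pixel co-localization; noiseless default
  renders stay piecewise-uniform so exact round-trip tests hold.

Ground truth (per-blob masks and contrasts, per-oocyte planted and
post-quantization lipid, carrier amounts, geometry) is returned alongside the
images. Reproduction assays draw new ovulations per worm from
Poisson(rate × arms × hours) and split them between laid and retained, so the
assay formula recovers the draw exactly and the estimator is unbiased (tested
over 1000 cohorts).

Preset values with no published number — accumulation counts per worm
(Poisson means 8–25), size distributions (wild type lognormal(ln 35, 0.664),
solved in closed form so the frequency mode lands in the 20–40 μm² bin and
the area-weighted fraction below 80 μm² is ≈ 0.72; mutants lognormal(ln 60,
0.70)), egg numbers, carrier slope/offset, buffer level 500 counts — are
fixed once in `presets.py` with provenance comments and are not tuning knobs.

The detection-limit experiment plants one blob per area on a 2–40 μm² grid
(0.5 μm² steps) at the small-accumulation *mean* contrast with pixel noise
CV 0.05, 20 frames, and reports the smallest grid area detected in ≥95% of
instances. Sampling per-blob contrasts from the full N(1.69, 0.22) spread
would put ~16% of blobs below the 1.47 threshold regardless of size, making
a 95% criterion unreachable at any area; fixing the mean isolates the
size-dependent sensitivity that the original detection-limit experiment (a
GFP cross-reference on real accumulations) measured.

What the generator does **not** emulate: optics (no point-spread function,
no resonant/non-resonant interference beyond a constant offset band), organ
autofluorescence, motion, depth attenuation, or segmentation-mask
uncertainty (region labels are ground truth, as the original analysis drew
organ exclusions by hand). Passing closed-loop tests therefore shows the
measurement chain is correct and unbiased under the stated image model, not
that it is robust to real-microscopy artifacts.

## Problem sizes and determinism

Default validation sizes: 20-worm cohorts for oocyte statistics, 30 blobs
for contrast recovery, 200 worms for assay estimates, 20 seeds for the
detection limit — large enough that 2-SE tolerances are decisive, small
enough that the whole suite runs in well under a minute. All randomness
flows through `numpy.random.default_rng` seeds; identical seeds give
byte-identical images and tables.

## Known limitations

* The intensity model is piecewise-uniform; real accumulations have internal
  structure beyond the optional texture term.
* `axes_from_mask` measures extents, which overestimate slightly (+1 px) and
  are noisier on small jagged masks.
* The GFP positive-part sum has a small positive bias (~0.5% here) for
  near-zero-carrier oocytes because noise is rectified; Δ-referencing cancels
  most of it.
* Strain presets outside the anchored values are qualitative; cross-strain
  correlation magnitudes from `strain_survey` should be read as structural,
  not quantitative, reproductions.
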