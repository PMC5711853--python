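# Methods

This note documents the models, conventions and numerical choices behind
`canopyvi`, in the order data flows through the package.

## Color model and RGB indices

Input images are assumed sRGB-encoded 8-bit with a D65 white point.
Consumer cameras emit sRGB by default and no color-calibration targets are
assumed, so no further characterization (ICC profiles, white-balance
estimation, chromatic adaptation) is attempted; this is a known limitation
when comparing absolute index values across cameras or illumination.

Three color models are used:

* **HSI.** Hue is the hexcone angle (0° red, 60° yellow, 120° green,
  180° cyan).  It is computed on the *gamma-encoded* channels, as imaging
  tools conventionally do, and on the raw channel values rather than the
  normalized ones — hue is scale-invariant, and integer channel
  differences divide exactly, which makes classification at the window
  boundaries (60°, 80°, 180°) bit-deterministic.  Saturation uses the HSI
  variant S = 1 − min(r,g,b)/I with I = (r+g+b)/3, which is exactly zero
  iff r=g=b.  Achromatic pixels have undefined hue; they are assigned hue
  0, are never counted green, and carry zero weight in the per-plot hue
  mean.
* **CIELab / CIELuv.** Computed from gamma-decoded linear RGB through CIE
  XYZ (D65/2°), via scikit-image.  The rounded sRGB→XYZ matrix leaves
  ~10⁻³ residual chroma on the neutral axis, so achromatic inputs are
  collapsed to a\*=b\*=u\*=v\*=0 exactly (neutral is neutral by
  definition).  Lightness is reported as L\* on 0–100; Intensity
  separately on 0–1 (the two are not interchangeable: typical canopy
  scenes sit near L\*≈42–55 while I≈0.36–0.50).

Per-plot aggregation: Hue is a circular (vector) mean over chromatic
pixels — angular quantities cannot be averaged linearly (the mean of 350°
and 10° is 0°, not 180°); every other color component is an arithmetic
mean.  A perfectly balanced hue set (zero resultant) returns 0° by
convention.  Note the vector mean coincides with the arithmetic mean
exactly only for two-point or symmetric sets; for tightly clustered hues
the difference is second-order in the dispersion.

**GA and GGA.** GA is the fraction of pixels with hue in [60°, 180°], GGA
in [80°, 180°]; both bounds inclusive (a measure-zero choice, fixed for
reproducibility).  No saturation or lightness floor is applied before hue
classification; whether the original plot-analysis tools applied one is
not documented anywhere we could verify, so none is invented here.

## Spectral indices

The camera model is an 11-band visible/NIR imager (450, 550, 570, 670,
700, 720, 780, 840, 860, 900, 950 nm).  All twelve indices are evaluated
exactly as printed in the source configuration table, with two deliberate
exceptions kept visible in the API:

* **TCARI.**  The printed formula string is parenthesis-ambiguous and, as
  literally parsed, reads 3·(B700−B670) − 0.2·(B700−B550)·(B700/B670),
  which contradicts the index's canonical definition.  The default is the
  canonical bracketing 3·[(B700−B670) − 0.2·(B700−B550)·(B700/B670)]; the
  literal parse is available via `form="literal"`.
* **WBI.**  As printed, the formula has the identical algebraic shape as
  RDVI rather than the canonical 900/970 nm water-band ratio.  It is
  implemented as printed under the name used in the source; the canonical
  ratio is provided separately as `water_index_900_970` (and cannot be
  computed from this camera's band set, which lacks 970 nm).  The printed
  EVI row similarly cites only "Red, NIR" although the formula uses
  B450; the formula, not the label, is authoritative here.

Zero denominators yield NaN — an explicit undefined-value sentinel, never
a silent infinity; summaries record which indices were undefined, and the
table writer emits empty cells for them (count logged).

Plot-level aggregation defaults to **mean-reflectance** (formula applied
to the plot's mean band reflectances), matching plot-level reporting
conventions; a **per-pixel** mode (index evaluated per pixel, finite
values averaged) is provided for sensitivity analysis.  Whether the
original analysis averaged before or after the formula is undocumented;
the two agree exactly on spatially uniform scenes and differ on
heterogeneous ones (Jensen-type gaps), which is why both are exposed.
SAVI's soil factor defaults to L = 0.5 ("intermediate" vegetation),
configurable to 1 (low) and 0.25 (high).

## Aerial-platform emulation

The reference acquisition geometry gives ~4,608×3,072 px/plot on the
ground and ~488×193 px/plot from the air.  The emulator is a pure integer
block-mean: the image is cropped to the largest multiple of the factor,
each factor×factor block is replaced by its mean color (rounded to 8
bits), and the platform tag flips to "aerial".  No optics are modelled
(no PSF, no motion blur, no perspective): block averaging is the simplest
model that produces the phenomenon of interest, mixed vegetation/soil
pixels at canopy boundaries.  The printed ground/aerial linear ratios
(≈9.4 horizontally, ≈15.9 vertically) cannot both be matched by one
integer factor; the default is 10.  Block means conserve the image mean
to within 8-bit rounding, so mean-color indices (a\*, u\*, Hue) survive
downsampling almost exactly, while hue-threshold cover fractions (GA,
and especially GGA with its tighter window) reclassify mixed pixels —
the package's ground-vs-aerial comparison asserts exactly this ordering.
Note that on real two-camera data additional effects (illumination,
exposure self-adjustment, mosaicking) overlay this mechanism, and the
observed ordering of ground↔aerial agreement can differ from the pure
resolution effect modelled here.

## Synthetic scenes and trials

The generator exists so that every downstream stage is testable without
any external imagery; it emulates structure, not radiometry.

**Scenes.** Canopy is rendered as random elliptical blobs (seedling
rosettes, default radius ≈2% of the short image side) on a textured soil
background, so that downsampling creates genuine boundary mixed pixels —
a spatially uncorrelated noise image would make the resolution comparison
meaningless.  The realized green-pixel count hits the requested cover
fraction exactly: the final blob is trimmed pixel-by-pixel, and the
per-class counts are returned as ground truth.  Foliage color is sampled
in HSV around a green center; *chlorosis* (0–1) shifts the hue center
from ≈115° toward ≈70° and slightly darkens; *purpling* (0–1) adds dark
red-purple foliage (≈25% of the green area at full strength) outside the
green bookkeeping.  Saturation/value floors and a guard band around the
80° GGA boundary keep every rendered class on the correct side of the
hue windows after 8-bit quantization (worst-case quantization hue error
< ~3° at the floors), so GA/GGA computed from the rendered image equal
the bookkeeping to the last pixel.

**Reflectance stacks.** Pixel-aligned 11-band stacks follow a
two-endmember model with declared constant spectra: a healthy leaf (low
red, 0.04 at 670 nm; high NIR, 0.50 at 840 nm), a chlorotic leaf (red up
to 0.14, NIR down to 0.40; linear interpolation in the chlorosis dial,
hence strictly monotone NDVI response) and soil (slowly rising, NDVI
≈0.10).  Purpled foliage uses the leaf spectrum at chlorosis+0.6,
attenuated 15%.  Multiplicative pixel noise (σ=2%) and a shared
low-frequency soil-brightness texture are added; values are clipped to
[0, 1].  No radiative transfer (PROSAIL-class), no BRDF, no atmosphere.

**Trials.** 26 genotypes × {NPF, OP} = 52 plots.  Grain yield is

    GY = mean_t + g_i + β·(cover − mean-cover_t) + ε,

with treatment means 5.64/7.50 t·ha⁻¹, genotype effects g_i ~ N(0, 0.6²)
shared across arms, residual ε ~ N(0, 0.35²), and β = 25 t·ha⁻¹ per unit
cover.  Cover is drawn per arm (NPF 0.08±0.03, OP 0.21±0.04 — the
treatment split of green cover), chlorosis (0.60/0.15) and purpling
(0.50/0.05) are higher without phosphorus.  These choices plant
within-treatment cover→yield correlations of ≈0.73 (NPF) and ≈0.82 (OP)
— exposed in closed form via
`TrialDesign.planted_cover_yield_correlation` — and a per-plot yield SD
of ≈1.0 t·ha⁻¹, consistent with treatment-level standard errors of ≈0.2
over 26 plots.  Leaf traits (P, chlorophyll, N, C, δ13C, δ15N) are drawn
from treatment-dependent normal models whose means are the study-level
treatment summaries and whose SDs are the reported standard errors scaled
by √26; C/N is computed from the drawn C and N.  Traits are independent
of yield within arms — the strong pooled trait↔index correlations arise
from the treatment split, mirroring the field situation where
within-arm trait correlations are weak.  One global seed drives a
per-plot seed sequence (seed, plot index), so single plots are
reproducible in isolation.

**Default sizes.**  Default rendered plots are 576×384 px (1/8 linear
scale of the reference ground resolution); tests and examples use smaller
scenes where only cardinality or statistics are under test.  All
structural claims (mixed-pixel mechanism, exact cover bookkeeping) are
scale-free down to the guard bands described above.

What passing tests on this generator do **not** show: robustness to real
soil spectra variation, specular leaves, shadows, row structure, weeds,
illumination drift between platforms, or camera self-adjustment.  The
generator validates the pipeline's arithmetic and its qualitative
mechanisms, not field-readiness of any particular threshold.

## Statistics

* **Treatment ANOVA** is the one-way between/within F-test with group
  means ± SE.  (The underlying field design is described as a split-plot
  without replicates, but the reported analysis is a simple treatment
  contrast, which is what is implemented.)
* **Correlation tables** report two-sided Pearson r/p/n per index ×
  target × group; "Combined" pools both arms without adjustment.  Missing
  pairs are dropped pairwise; cells with fewer than 3 complete pairs are
  reported NaN with their n, never fabricated.  No multiple-testing
  correction is applied anywhere.
* **Forward stepwise regression** enters, at each step, the candidate
  with the smallest partial-F p-value (equivalently the two-sided t-test
  of its coefficient in the augmented model) while p < α_enter (default
  0.05); pure forward, no removal step; refit after every entry.  Entry
  stops when the current model is numerically saturated (RSS ≤ 10⁻¹⁰·TSS)
  — partial tests on rounding noise would otherwise admit arbitrary
  terms.  Reported: coefficients, R², RSE = √(RSS/(n−k−1)), the overall
  model F p-value, and per-term variance portions.
* **Variance portions** are not uniquely defined in common reporting
  practice; the default here is the LMG decomposition (incremental R²
  averaged over all entry orderings, normalized to sum to 1), which gives
  1.0 for a single term and equal shares for orthogonal standardized
  predictors with equal coefficients; a normalized squared-standardized-
  coefficient alternative (`method="beta_sq"`) is provided.  LMG is
  factorial in the number of terms and is capped at 10.  A design
  collinear to machine precision raises an error naming the terms.
* **δ notation**: δ = (R_sample/R_standard − 1)·1000 ‰, with a positive
  standard required.

## Pipeline and reproducibility

A run is fully specified by a `RunConfig` (input mode, generator design,
SAVI L, aggregation mode, downsample factor, α_enter, output directory,
seed).  All randomness flows from the single seed; reruns are
bit-identical for CSV contents (checked by checksum in the tests).  CSVs
are comma-separated UTF-8 with 6-significant-digit numerics and empty
cells for undefined values; significance stars follow the 0.05/0.01/0.001
convention.  In directory mode, unreadable plot images are skipped with a
logged reason and counted in the manifest rather than aborting the run.
16-bit input images are rescaled to 8-bit by max-value mapping;
single-channel images are promoted to RGB with a warning; other channel
counts are format errors.

## Known limitations

No geometric processing (ortho-mosaicking, georeferencing, lens
correction) — cropping starts from flat mosaics or per-plot images.  No
radiometric calibration or atmospheric correction for the band stacks.
No vegetation segmentation beyond hue thresholding.  No genotype BLUPs,
spatial trend correction or heritability estimation in the statistics
layer.  The stepwise procedure inherits the usual caveats of greedy
selection (unstable term choice under collinearity; optimistic R² on
small n).
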