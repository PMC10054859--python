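# Methods

`seagrassrs` implements a semi-automated monitoring pipeline for subtidal
seagrass in shallow, optically complex lagoons, driven by 30 m multiband
surface-reflectance scenes. The stages, in run order: scene simulation (or
ingestion), dark-object atmospheric correction, five-class per-pixel
classification with an optically-deep mask, bottom-reflectance/LAI retrieval
and a biomass–carbon transfer chain, multi-decade trend statistics, and
presence/absence map agreement. This note records the models, the defaults
and why, and what the synthetic tests do and do not demonstrate.

## Forward optical model and LAI retrieval

Bottom-reflected light in the green band (560 nm) is modelled with a
single-scattering, two-path water column:

    R_rs = (R_b / π) · exp(−(K_d + K_Lu) · H)

with `R_b` the bottom reflectance, `H` the tide-adjusted depth (m, positive
down; `H = dem + tide`, clipped at 0 for emergent bottom), `K_d` the
downwelling and `K_Lu` the upwelling diffuse attenuation coefficient (1/m at
560 nm). When `K_Lu` is not measured it is derived as `K_d / 2π`, treating
upwelling bottom radiance as an isotropic source spread over the upward
hemisphere. Defaults are the long-term means of the emulated system:
`K_d = 0.734`, hence `K_Lu ≈ 0.117`, tide `0.24 m`.

LAI relates to bottom reflectance log-linearly, `LAI = a + b·ln(R_b) + c`
with `b < 0` (denser canopy absorbs more green light). The simulator's
forward LAI→R_b law is the exact inverse of this retrieval, so with zero
noise and zero path offset the full simulate → correct → retrieve → invert
chain is an identity up to float rounding — the pipeline's central contract,
asserted to < 1e−6 (measured ~1e−15) on 128×128 scenes. The default
coefficients `a = −0.61`, `b = −1.2`, `c = 0` were chosen so LAI ∈ [0, 3]
maps onto a plausible bottom-reflectance range R_b ∈ (0.05, 0.60); site-
calibrated coefficients can be substituted without code change. `c` is the
cross-sensor brightness correction: an ordinary least-squares fit of a
reference sensor's LAI on the target sensor's LAI over shared valid pixels
returns a slope and intercept, and when the slope's confidence interval
includes 1 the intercept is folded additively into `c`.

Numerical guards: retrieval invalidates (rather than overflows on) pixels
whose attenuation exponent exceeds 50; inversion invalidates `R_b ≤ 0` and
clips negative LAI to 0.

## Carbon transfer chain

Per seagrass pixel, fresh aboveground biomass density is `500 g m⁻² × LAI`;
dry biomass is `0.2 ×` fresh; aboveground organic carbon is `0.34 ×` dry;
belowground carbon is `3 ×` aboveground carbon (root/rhizome-dominated
meadows with a 1:3 aboveground:belowground biomass ratio); total carbon is
their sum. Totals integrate over the pixel area (900 m² at 30 m) and are
reported in Gg (`×10⁻⁹` from grams); the widely used shortcut constant falls
out of the chain as `500·0.2·0.34·3 = 102 g C m⁻²` of belowground carbon per
unit LAI. The literature's transfer-coefficient equations are sometimes
printed with stray `×10⁹` factors and without the areal integration; they
are implemented here as dimensionally consistent unit conversions, since only
that reading reproduces the bay-scale reference values (23 km² at mean LAI
1.6 → 18.4 Gg fresh, 3.68 Gg dry, 5.0 Gg total C, 3.75 Gg belowground C).
Note the "total organic carbon" transfer coefficient alone yields only the
aboveground pool; both `ag_carbon` and `total_carbon = ag + bg` are exposed.
Sediment (detrital) carbon is out of scope.

## Atmospheric correction and scene conditioning

Dark-object subtraction uses the strict minimum of the NIR band inside a
water mask (NIR over water is near-fully absorbed, and the mask keeps the
dark pixel out of shadowed land and inland ponds); ties resolve to the first
pixel in row-major scan order. The offset subtracted from each band is that
pixel's own value in that band (not the NIR value), configurable. Negative
results clip to 0 with the clipped count logged. The correction is
idempotent: offsets recomputed on corrected output are exactly zero.

A one-pixel dark estimate inherits one noise draw per band; with sensor
noise σ this leaves a ~N(0, σ) residual offset per scene. This is inherent
to single-pixel DOS, and it is why retrieval accuracy statements below are
made about means over replicate scenes rather than single scenes.

Scanline-gap filling is deliberately simple: gap pixels are seeded with the
mean of their valid 8-neighbours (iterated inward), then the gap region is
relaxed by repeated neighbourhood averaging with non-gap pixels held fixed
until the fill stabilises. The relaxation makes fills across stripes agree
with linear interpolation to ~1e−11 on ramps; it is a documented stand-in
for purpose-built scanline-repair tooling, not a reconstruction of it.

## Classification, extent, band importance

Training spectra come from 3–6 homogeneous rectangular regions of interest
per class — land, optically-deep water, seagrass, submerged sand, intertidal
— with the same ROI locations reusable across scenes. Classes are balanced
by random upsampling with replacement to 20,000 samples each, split 90/10
stratified (exactly `round(0.9·n)` per class), and fed to a small
fully-connected network on per-pixel band vectors (scikit-learn MLP, two
hidden layers of 64, 50 epochs, seeded). Per-pixel spectra carry the class
signal at 30 m; the architecture is a configuration knob, not a contract,
and the suite also verifies a plain logistic regression clears 95% on the
default synthetic separation, so the ≥ 99% neural benchmark is not an
artifact of model capacity.

After prediction, pixels whose tide-adjusted depth strictly exceeds 2.5 m
are masked as optically deep (boundary pixels retained); seagrass extent is
the unmasked seagrass pixel count × pixel area. Extent is monotone
non-increasing under additional masking.

Band attribution uses exact Shapley values: all 2^n band coalitions are
enumerated (n ≤ 8; a permutation-sampling estimator sits behind a flag for
wider stacks), absent bands are replaced by their training means, and a
coalition's value is the model's probability for the class predicted from
the full band vector. Efficiency — attributions summing to
f(all) − f(none) — holds to machine precision by construction and is
asserted to 1e−9. Reported percentages are normalised mean absolute
attributions.

## Trend statistics

The seasonal Mann–Kendall test accumulates the concordance statistic S
within season blocks, with tie-corrected variance
`n(n−1)(2n+5)/18 − Σ t(t−1)(2t+5)/18` per block and a continuity-corrected
two-sided normal p-value; a single season reduces to the ordinary test, an
all-tied series returns τ = 0, p = 1 with a warning, and an exact
permutation p is available for a single season with n ≤ 9. τ is S over the
total within-season pair count, labelled by conventional thresholds
(|τ| ≥ 0.5 strong, ≥ 0.3 moderate, ≥ 0.1 weak, else none). Empirical size
at α = 0.05 on 2,000 white-noise series of n = 31 is ~0.046.

The Theil–Sen slope is the median of within-season pairwise slopes
(duplicate-year pairs skipped), robust to 20% contamination. Percent change
per year is `100 · slope / mean(series)`; this definition is documented
because published percent-change columns for such series are not always
reverse-engineerable from their printed slopes and means.

Trend detectability is summarised by

    γ = [ (F · σ_N / |slope|) · sqrt((1+φ)/(1−φ)) ]^(2/3)

with σ_N the residual standard deviation about the Sen line, φ the lag-1
residual autocorrelation, and γ undefined at slope 0. The factor `F`
defaults to 3.3 (≈ z₀.₉₇₅ + z₀.₉₀), the familiar literature constant, which
strictly refers to the monthly-cadence noise formulation; for annual series
the power-matched factor is larger by √12. Because the constant's cadence
convention is ambiguous in common usage, `F` is an explicit argument, and
the suite verifies the design property at the annual-matched factor
(Mann–Kendall power ≈ 0.9 at n = γ, > 0.9 a third beyond).

Per-pixel seagrass frequency over a scene stack is the seagrass count over
the valid count, with masked scenes excluded from both numerator and
denominator at that pixel; it is permutation-invariant in the stack order.
Climate attribution is ordinary least squares of a metric on intercept +
ENSO and NAO indices (any covariate columns can be named), with
per-coefficient t and two-sided p on n−k−1 degrees of freedom and adjusted
r²; rank-deficient designs are rejected naming the collinear columns. A
forward-stepwise variant is deliberately not the default.

## Map agreement

Class maps are binarised to seagrass presence/absence over unmasked pixels
and compared over co-valid pixels as a paired 2×2 table. The report carries
precision, recall and harmonic-mean F for both presence and absence, overall
accuracy, and Cohen's kappa from marginal chance agreement. Zero-denominator
ratios are reported as NaN, never 0. McNemar's test on the discordant
counts is `χ² = (b−c)²/(b+c)` with 1 df, uncorrected by default (the
continuity-corrected form, which is the classical approximation to the exact
binomial test, sits behind a flag). Swapping the two maps swaps b↔c and
precision↔recall and leaves accuracy, kappa and χ² unchanged.

## Synthetic scenes: what they emulate, and what they do not

The generator is a pure function of a configuration and a seed (same seed ⇒
bit-identical outputs, via independent named substreams per product). It
emulates: a lagoon cross-section with a land strip, a thin intertidal ring,
a broad shallow vegetated platform deepening quadratically to 2.5 m (mean
vegetated depth ≈ 0.9 m, matching the shallow meadow habitat the pipeline
targets) and a deep basin to 8 m; a spatially smooth LAI field (mean 1.6,
sd 0.3, clipped to [0, 3]) under seagrass patches occupying a configured
fraction of the shelf; depth-dependent exponential attenuation of the green
band through the shared forward law; class mean spectra from a fixed library
with a configurable separation multiplier; an additive per-band path offset
(default 0.01); and i.i.d. Gaussian sensor noise (default σ = 0.001
reflectance, a typical surface-reflectance noise floor for modern 30 m
multispectral sensors). Optically-deep water is rendered as a full absorber
— zero surface signal plus path offset — so the darkest NIR pixel satisfies
the dark-object assumption exactly and the noise-free roundtrip is exact.

Real scenes violate several of these idealisations: spatially correlated
and signal-dependent noise, multiplicative atmospheric effects, sun glint,
CDOM plumes that blur the seagrass/deep-water boundary, mixed pixels at
patch edges, bathymetry error, and class spectra that drift across sensors
and dates. Passing the synthetic suite therefore demonstrates internal
consistency and correct statistics, not field accuracy; the ≥ 99% classifier
benchmark in particular reflects the configured spectral separation, and
real-scene accuracy must be established against reference maps via the
agreement module.

## Problem sizes and runtime choices

Default scenes are 128×128 pixels (≈ 14.7 km² at 30 m). The classifier
benchmark trains on 4,000 balanced samples per class (the 20,000-per-class
convention is asserted separately on the balancing operation); the
Mann–Kendall size experiment uses 2,000 null series of n = 31; LAI
parameter recovery averages 8 replicate scenes per LAI level
(0.5 / 1.6 / 2.5) with the pipeline's own deep-water exclusion, reflecting
that bay means in a monitoring time series are estimated from many scenes
while single-scene retrievals carry the DOS dark-pixel noise. The full
suite runs in well under a minute on one CPU.

## Known limitations

- No radiative-transfer atmosphere (additive offset only), no sun glint, no
  georeferencing beyond an identity transform; rasters are plain TIFF.
- K_d is an input (or long-term mean fallback for early years), not derived
  from water-quality constituents.
- The LAI–R_b coefficients default to plausible placeholders; site work
  must calibrate `a`, `b` and the cross-sensor offset `c`.
- The exact γ cadence convention differs between software packages; choose
  `F` to match the comparison target.
- Reference maps for agreement must arrive as co-registered rasters;
  polygon rasterisation is out of scope.
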