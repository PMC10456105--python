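# Methods

## Texture model

The package measures second-order gray-level statistics of a rectangular
skin ROI through the co-occurrence matrix. For a raster with levels
`0 .. G-1` and a displacement given by distance `d` (pixels) and angle
`θ ∈ {0°, 45°, 90°, 135°}`, entry `(i, j)` counts ordered pairs
(reference level `i`, neighbor level `j`). Conventions, fixed once and used
everywhere:

- the row axis points down the image, so `θ = 0°` is `(Δrow, Δcol) = (0, +d)`
  (the immediate right neighbor), `θ = 90°` is `(−d, 0)`, `θ = 45°` is
  `(−d, +d)`, `θ = 135°` is `(−d, −d)`;
- counting is **asymmetric** by default ("to the right of" is an ordered
  relation); symmetric counting, which adds the transposed pair, is an
  explicit option;
- pairs are counted only where both endpoints lie inside the raster — no
  padding, no wrap-around, so a cropped ROI never co-occurs with pixels
  outside it;
- normalization divides by the number of counted pairs (not the image area),
  so entries form a probability distribution summing to 1 within 1e-12;
- the matrix dimension defaults to `G = 256` (the full 8-bit range);
  requantization to fewer levels is a separate, explicit operation
  (`floor(v * G_new / G_old)`), never implicit, because silent requantization
  changes feature values.

Features of the normalized matrix `p`:

- contrast `Σ (i−j)² p(i,j)`, in `[0, (G−1)²]`, zero iff all mass is
  diagonal;
- homogeneity `Σ p(i,j) / (1 + |i−j|)`, in `(0, 1]`, one iff all mass is
  diagonal.

The homogeneity denominator is linear in the level difference, taken as
`1 + |i−j|` so it stays positive for `i < j`. The quadratic variant
`1 + (i−j)²` (the inverse difference moment of common texture libraries,
including scikit-image) is available as an option and is used in the test
suite to cross-check against scikit-image; the linear form is the package
default. Both feature weights depend on `|i−j|` only, so both features are
invariant under matrix transposition — a property the test suite asserts.

Grayscale conversion uses Rec. 601 luma weights (0.299, 0.587, 0.114),
rounded half-up — the de-facto behaviour of mainstream imaging toolchains —
and is configurable. Images are strictly 8-bit; 16-bit input is rejected
rather than silently rescaled, because the 0–255 brightness scale is part of
the measurement definition. Coordinates are 0-based, row-major; ROIs are
half-open rectangles.

## Cohort statistics

Per-patient before/after values are aggregated with arithmetic means and
sample standard deviations (n−1). The mean absolute change equals
`mean(after) − mean(before)`; the cohort percent change is the percent
change of the two means. Percent changes use the **larger-denominator
convention**: `|after − before| / max(before, after)`. This one rule
reproduces the conventional clinical reporting in which increases are quoted
against the post value and decreases against the pre value, and it is
symmetric in the two measurements; "before" and "after" denominators are
explicit options. Per-patient extremes are ranked by the magnitude of the
change, ties broken toward the lower patient id.

The packaged data comprise a published 12-subject cohort: per-patient
brightness, GLCM contrast and GLCM homogeneity tables, plus a cohort-level
per-channel means table (the per-channel source data were published only as
means, so the channel fixture is a means table read by its own loader; the
per-patient `summarize_channels` path is exercised on simulated cohorts).
All comparisons against printed values round half-up at the printed
precision; internal computation is at full precision. Two transcription
notes: the printed brightness SDs (10.68/11.05) do not follow from the
printed per-patient table (which yields 17.35/16.98 — the package reports
the table-derived values), and the smallest printed contrast decrease
(0.24) belongs to patient 6 by the table, although the running text
attributes it to patient 5.

Paired t and Wilcoxon signed-rank tests are provided as clearly labelled
post-hoc plumbing; degenerate difference sets (zero variance; all zeros) are
flagged rather than reported as spurious statistics.

## Synthetic skin model

The simulator stands in for cross-polarized forearm photographs, which are
not publicly available for any comparable study. Pixel model for channel
`k ∈ {R, G, B}` with absorption weight `w_k` and stage factor `λ_stage`
(0 before treatment, λ after):

```
clamp(round(tone_k + σ_base · f(r,c)
            − w_k (1 − λ_stage) Σ_b a_b exp(−dist_b²/2σ_b²)
            + ε), 0, 255)
```

- `f` — smooth base reflectance: unit-SD Gaussian-blurred white noise,
  correlation length 50 px at the reference raster, amplitude `σ_base = 6`
  gray levels. Emulates gradual tone variation of forearm skin; gives the
  stationarity the repeatability checks assume.
- base tones (R, G, B) = (190, 150, 120): lightly pigmented skin under
  cross-polarized flash is brightest in red and darkest in blue.
- lesions: 35 isotropic Gaussian decrements per 7 cm field, center depth
  15–40 levels, σ 8–24 px, uniformly placed. Weights
  `(w_R, w_G, w_B) = (0.5, 0.75, 1.0)` encode stronger melanin absorption at
  shorter wavelengths, so blobs darken blue most and per-channel contrast
  decreases scale approximately as `w_k²` — the blue channel therefore shows
  the largest treatment effect, matching the clinical expectation.
- sensor noise: additive Gaussian, SD 2 gray levels, drawn independently per
  stage and channel, applied after blob subtraction, then rounded and
  clamped — adequate for 8-bit flash photography at base ISO.
- treatment factor λ multiplies every lesion amplitude by (1 − λ) in the
  "after" image; base field and lesion layout are shared between stages, so
  the pair differs only by treatment and noise.

All numeric defaults are artifact choices, documented here; nothing claims
to match a particular camera quantitatively. The reference raster is
800×727 (a common clinical acquisition size for a 7 cm field);
`SyntheticSkinParams.scaled(h, w)` images the same 7 cm field at reduced
resolution by shrinking every length (blob σ, base correlation) by `w/800`
and growing the mm-per-pixel scale to match, preserving scene statistics
per unit skin area. Tests and the acceptance script use scaled rasters
(128×128 cohorts, 256×256 repeatability ROIs) to keep runtimes in seconds.

What the simulator does **not** model: physically based skin optics
(Kubelka–Munk, photon transport), hair, specular highlights (removed by
cross-polarization in the emulated acquisition), illumination gradients,
registration error between visits, and real lesion morphology (macules are
not Gaussian). Passing tests therefore demonstrate that the pipeline
recovers a treatment signal with the assumed structure, not that any
clinical treatment works.

## Repeatability checks

A texture measurement is credible only if small ROI placement errors do not
move it. `sensitivity_check` recomputes both features after a perturbation
and reports `|perturbed − baseline| / baseline` per feature against a 1%
threshold (the conventional repeatability criterion; configurable).
Swapping baseline and perturbed leaves the numerator unchanged; only the
denominator moves. A zero baseline (constant ROI) makes the relative change
undefined and is flagged rather than divided.

Two perturbations are built in:

- **shift**: the ROI origin moves by `round(mm / scale)` pixels along one
  axis; no resampling is involved. The packaged check shifts by 10 mm with
  the ROI side spanning the 7 cm protocol field (37 px at side 256). On
  lesion-free simulated textures this passes the 1% criterion in 10/10
  seeds, and the mean change shrinks as the ROI side grows (asserted over
  sides 64/128/256) — feature estimates tighten with the pair count.
  A single lesion confined to the original ROI, with the shift moving the
  window fully off it, fails the check by construction (contrast collapses);
  the check is a guard against exactly such non-stationarity.
- **rotation**: the sampling grid rotates about the ROI centre and the image
  is resampled by nearest neighbour, which preserves the gray-level set
  (any interpolating kernel smooths the raster and deflates contrast on its
  own). Nearest-neighbour resampling has, however, an irreducible bias of
  its own at the method's `d = 1` horizontal offset: after rotation by θ,
  the fraction `(1 − cos θ)(1 − sin θ)` of adjacent output pairs rounds to
  the *same* source pixel — ≈ 1.26% at θ = 10° — contributing zero
  difference and thus deflating contrast and inflating homogeneity by about
  that fraction on noise-dominated textures (structure-dominated textures
  are biased the other way: the mean sampled pair distance rises to ≈ 1.06).
  Measured on ten simulated stationary textures at 256×256 the rotation
  moves the features by 1.0–1.6%, straddling the 1% criterion from above;
  the rotation check is therefore expected to *fail* a strict 1% threshold
  under this estimator even though the underlying texture field is
  rotationally stationary. The package keeps the operation and reports the
  number honestly; for rotation-robustness claims at the 1% level a
  resampling-free acquisition (re-imaging the rotated scene) would be
  required, which pixel data alone cannot provide.

## Numerical conventions and degenerate inputs

- Round-half-up (ties away from zero) for all comparisons against printed
  values, at the printed precision; `decimal`-based, not banker's rounding.
- GLCM of an image too small to contain one displaced pair raises an
  "empty co-occurrence domain" error; features of an empty matrix are
  undefined and raise rather than returning 0/NaN.
- Pixel values at or above the configured `G` raise a quantization-contract
  error instead of being clipped.
- A single-subject cohort reports means and changes with SDs flagged as
  undefined; an all-tied channel comparison reports a tie instead of an
  arbitrary argmax.
- Simulator determinism: one `numpy` Generator seeded from the stated seed
  drives base field, lesion layout and both noise draws in a fixed order;
  cohort seeds derive from a `SeedSequence` of the master seed. Identical
  seeds reproduce images bit for bit, and the cohort writer emits
  byte-identical PNGs and manifests across reruns.

## Problem sizes

Defaults throughout the tests and the acceptance script: 12-subject cohorts
at 128×128 (ten master seeds), repeatability on 256×256 ROIs inside 420×420
canvases (ten seeds), oracle cross-checks on images up to 12×12 over the
full small grid of `d`, θ, `G`, symmetry. The full suite runs in well under
a minute on one CPU; the acceptance script in a few seconds.
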