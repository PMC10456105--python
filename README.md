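# glcmskin

Quantitative assessment of skin hyperpigmentation change from paired
before/after clinical photographs, using gray-level co-occurrence matrix
(GLCM) texture statistics.

Cosmetic and dermatological interventions that lighten hyperpigmented skin
(for example microneedle mesotherapy with ascorbic acid) are routinely judged
by eye. This package implements the objective alternative: cross-polarized
photographs of the treated region of interest (ROI) are reduced to three
numbers per image — mean brightness, GLCM contrast and GLCM homogeneity — and
before/after change is summarized over a cohort, per RGB channel. Because
melanin absorbs short wavelengths most strongly, pigmented macules darken the
blue channel most, and the blue channel is where treatment effects show the
largest contrast change.

It is intended for image-analysis practitioners in dermatology/cosmetology
research who need reproducible, testable texture measurements rather than a
clinical scoring scale.

## Method

For an image with gray levels `0 .. G-1`, the co-occurrence matrix for
displacement `(d, θ)` counts ordered pixel pairs: entry `(i, j)` is the
number of times a reference pixel of level `i` has a neighbor of level `j`
at distance `d` in direction `θ` (default: the immediate right neighbor,
`d = 1`, `θ = 0°`). With `p(i, j)` the normalized matrix:

- **contrast** `= Σᵢⱼ (i − j)² p(i, j)` — local gray-level variation;
  0 for uniform skin, large for mottled, hyperpigmented skin;
- **homogeneity** `= Σᵢⱼ p(i, j) / (1 + |i − j|)` — concentration of mass
  near the diagonal; 1 for uniform skin.

Effective treatment raises mean brightness, lowers contrast and raises
homogeneity. Percent changes divide the absolute change by the larger of the
two values, which makes the convention symmetric in before/after.

The package also provides:

- an ROI-placement repeatability check (shift the ROI by a physical distance,
  or rotate its sampling window, and compare features against a 1% criterion);
- paired cohort statistics (means, sample SDs, per-patient extremes,
  per-channel aggregates, post-hoc paired t / Wilcoxon tests);
- a seeded synthetic cross-polarized skin simulator (smooth base reflectance,
  Gaussian hyperpigmented blobs weighted most in blue, sensor noise, and a
  treatment factor λ that attenuates blob amplitude) so the whole pipeline is
  testable without clinical data;
- packaged CSV transcriptions of a published 12-subject cohort
  (per-patient brightness, contrast, homogeneity, and per-channel means).

## Worked example

Simulate one subject at treatment factor λ = 0.6 and measure the pair:

```python
from glcmskin import SyntheticSkinParams, generate_pair, measure_pair, percent_change

params = SyntheticSkinParams.scaled(128, 128, treatment=0.6, seed=42)
pair = generate_pair(params)
record = measure_pair(pair.before, pair.after)
for metric in ("brightness", "contrast", "homogeneity"):
    b, a = record.get(metric)
    print(f"{metric:12s} before={b:7.3f} after={a:7.3f} "
          f"change={a-b:+7.3f} ({100*percent_change(b, a):.1f}%)")
```

```
brightness   before=155.384 after=156.410 change= +1.026 (0.7%)
contrast     before=  5.298 after=  4.330 change= -0.968 (18.3%)
homogeneity  before=  0.479 after=  0.494 change= +0.015 (3.1%)
```

Brightness rises and contrast falls because the simulated treatment shrank
every lesion's amplitude by 60%; the blue channel shows the largest contrast
drop (1.97 vs 0.69 in red for this seed), reflecting the melanin weighting.

The published cohort statistics recompute from the packaged tables:

```bash
glcmskin reproduce-tables
```

```
[ok ] mean brightness before                    recomputed=156.1  printed=156.1
[ok ] mean brightness after                     recomputed=174.6  printed=174.6
[ok ] mean brightness increase                  recomputed=18.5  printed=18.5
[ok ] mean brightness increase percent          recomputed=10.6  printed=10.6
...
```

Other CLI subcommands: `analyze` (one before/after pair of PNG/TIFF files),
`cohort` (a measurements CSV), `simulate` (write a synthetic cohort to disk),
`sensitivity` (ROI shift/rotation repeatability). All write JSON + CSV
reports embedding the configuration used; logs go to stderr.

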