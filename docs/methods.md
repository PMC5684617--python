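# Methods

## The enhancement model

The method assumes capsule-endoscopy frames whose intensity structure is
dominated by distance to the LED light source: a dark distant lumen, bright
nearby mucosa, and saturated specular reflections. It brightens with two
operators over overlapping 2×2 pixel groups, selected per pixel by the HSV
value channel `V = max(R, G, B)` against an empirical threshold `∂`.

Both operators are weighted sums of the four group pixels
`P₁..P₄ = I(r,c), I(r+1,c), I(r,c+1), I(r+1,c+1)`, applied identically to
the three RGB channels:

* dark branch: `HWB = ΣPₙ/2` — each conventional bilinear weight replaced
  by the constant half-unit ½, i.e. effective gain 2 over the group mean;
* bright branch: `TWB = ΣPₙ·(CWₙ + ½)/H_j` with `H_j = β + ω·j` and the
  bilinear weights `CWₙ` sampled at the group center `Δr = Δc = ½`
  (each ¼), so the four weights sum to `3/H_j`.

The bright interval `[∂, 1]` is quantized into `M = ⌈1/∂⌉` equal-width
V-buckets; a pixel with value `η ≥ ∂` lies on step
`j = min(M−1, ⌊(η−∂)/((1−∂)/M)⌋)`. `ω` is the difference between
consecutive denominators, so gain decreases in discrete steps as tissue
gets brighter. The branch output is blended with the reference image `I`
and clipped to `[0, 1]`.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `threshold` (∂) | 0.4 | V units, (0, 1) | dark/bright branch split; also fixes `M = ⌈1/∂⌉` (3 at default) |
| `beta` (β) | 1.5 | dimensionless, [1.45, 1.50] | first bright-step denominator; at 1.5 the step-0 gain `3/β` equals the dark-branch gain 2, making the branch border exactly invisible |
| `omega` (ω) | 0.025 | dimensionless, (0, 0.025] | per-step denominator increment; small values keep adjacent brightness steps seamless |
| `combine_mode` | `average` | — | blend with the reference: `(branch + I)/2` or literal `branch + I/2` |

The tie at `η = ∂` goes to the bright branch (the dark region is a strict
inequality `V < ∂`).

## Design choices where the design was open

* **TWB numerator.** The bright-branch weight numerator adds the per-pixel
  half-unit ½ to each bilinear weight, giving a step-0 weight sum of
  `3/β ≈ 2`. Reading the numerator as the dark branch's divisor 2 instead
  would give a weight sum of `9/β ≈ 6` — a 6× local gain that saturates
  almost any bright pixel and makes the β range meaningless; the ½ reading
  is the only one under which the documented β range produces the seamless
  dark/bright linkage the range exists for.
* **Group-center sampling.** Enhancement is same-resolution (no resizing),
  so the bilinear offsets have no natural fractional value; they are fixed
  at the group center `Δr = Δc = ½`, which also makes the dark branch the
  exact "replace each weight by ½" special case of the bright branch.
* **Combination rule.** The default averages the branch output with the
  reference, bounding the uniform-region gain at 1.5× ("brighter but not
  too bright"); the additive reading `branch + I/2`, which saturates all
  pixels above `I ≈ 0.4`, is kept as an explicit mode.
* **Step quantization.** `1/∂ = 2.5` is not an integer; the implementation
  uses `M = ⌈1/∂⌉ = 3` equal-width buckets on `[∂, 1]`. A continuous
  `H(V)` was considered and rejected: ω is defined as the difference
  between *consecutive* denominators, which only makes sense for discrete
  steps.
* **Borders.** The last row and column are edge-replicated so every pixel
  anchors a 2×2 group and output size equals input size.
* **Clipping.** Deferred until after combination; intermediate stage
  outputs may exceed 1. Clipping is the only hue-breaking operation in the
  pipeline, which is why hue guarantees are stated for non-clipped pixels.
* **Branch selection is per pixel, not per channel.** One V-based mask
  routes all three channels of a pixel, which is what makes the transform
  achromatic and hue preservation provable.

## Effective gain and the continuity measure

The branch-boundary continuity check measures effective gain as *branch
output divided by the 2×2-group mean* (the value a center-sampled
conventional bilinear interpolation would return). Under this definition
the gain is exactly the branch weight sum — 2 on the dark branch, `3/H_j`
on the bright — so on a smooth intensity ramp the jump at the threshold
column is exactly `0` for β = 1.5 and `3/1.45 − 2` for β = 1.45. Dividing
by the raw center pixel instead would fold the ramp's slope into the gain
(adjacent-column differences of order 10⁻⁴ on a 256-column ramp) and mask
the quantity the check is about.

## The synthetic frame generator

`generate_scene` renders, in order: a reddish mucosa base color
`(0.75, 0.35, 0.30)` times a radial vignette `1 − s·d²` (strength
`s = 0.9`, center jittered ±8% to mimic a wandering lumen direction, floor
0.02); multiplicative darkening along 4 random cubic-spline vessels
(gaussian cross-section, half-width 2.5 px, depth 0.55); a blend toward
pure white inside 3 specular discs (radius 4 px, saturated core with a
short soft shoulder); and achromatic gaussian noise (σ = 0.01) clipped per
pixel so no channel leaves `[0, 1]`. Defaults produce a dark-region
(V < 0.4) fraction of roughly 0.2–0.3 of the frame. Ground-truth masks
(dark region, specular spots, vessels) are computed on the noiseless
render so their semantics are exact. The default frame is 288×288, the
larger of the two common capsule frame-size categories; scenes are
bit-reproducible from their seed.

Two deliberate simplifications matter for interpreting test results. Every
rendered pixel has the form `base·L + c·(1,1,1)` (scalar shading `L`,
scalar white component `c`), and the noise is achromatic — one luminance
draw added to all three channels. Real sensors add chromatic noise, which
no channel-shared operator can leave hue-invariant at the 10⁻⁹ level; the
exact hue-preservation results on synthetic scenes therefore certify the
*operators*, not the behaviour of hue under real sensor noise. Likewise
the generator is not photorealistic (no reflectance model, no texture), so
SSIM values on synthetic scenes indicate relative ordering between methods
rather than the absolute scores one would measure on clinical frames.

## Numerical notes

* All computation is float64 on `[0, 1]`-normalized intensities; 8-bit
  inputs are divided by 255, 16-bit by 65535; outputs are rescaled and
  rounded half away from zero on write.
* Step lookup uses `floor` with a clamp to `M − 1`, so `η = 1` lands on
  the last step rather than one past it.
* The metrics define contrast as channel standard deviation and intensity
  as channel mean, both reported as relative change against the reference
  — the simplest statistics consistent with signed, dimensionless
  per-channel tables. SSIM uses the standard gaussian-window settings
  (11×11, σ = 1.5, K₁ = 0.01, K₂ = 0.03, population covariance) on a
  Rec.601 luminance conversion, computed by scikit-image.
* Degenerate inputs are rejected rather than coerced: images smaller than
  2×2, non-RGB arrays, constant reference channels in the contrast
  statistic, and out-of-range parameters all raise named errors.

## Problem sizes

The test suite and the acceptance script evaluate on ten seeded 288×288
synthetic frames (the full default frame size), twenty 16×16 random images
for the per-pixel reference cross-check, a 3×256 ramp for continuity, and
10⁴ random offsets for the weight law. These sizes make every run exact
and fast while exercising the full pipeline at its native frame size.

## Known limitations

* Specular highlights are not suppressed or inpainted; the bright branch
  only guarantees that their gain never exceeds the dark branch's, not
  that clipped areas cannot grow at all.
* Performance on small frames is the method's documented weak spot; the
  package does not attempt to compensate.
* No multiscale or resizing use of the bilinear kernels: enhancement is
  strictly same-resolution.
* The per-channel contrast/intensity statistics are descriptive, not
  quality scores; large positive values usually indicate over-enhancement.
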