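# capsenhance

Contrast enhancement for capsule-endoscopy images, built for the situation
every capsule recording shares: the capsule carries its own LEDs, so tissue
close to the lens is bright while vessels and structures in the distant
lumen vanish into darkness. `capsenhance` brightens those distant regions
strongly, brightens already-bright tissue gently, preserves hue exactly,
and avoids enlarging the saturated specular spots left by LED reflections.
It is aimed at researchers working on endoscopic image analysis who need a
deterministic, parameter-transparent enhancement step and a way to evaluate
it quantitatively.

## Method

Every pixel is routed by its HSV value channel `V = max(R, G, B)` at an
empirical threshold `∂` (default 0.4):

* **Dark branch (`V < ∂`)** — the *half-unit weighted-bilinear* operator
  (HWB). Each overlapping 2×2 group of pixels is summed and divided by
  `HW = 2`:

      HWB(r′,c′) = (P₁ + P₂ + P₃ + P₄) / 2,

  an effective local gain of 2 relative to the group mean.

* **Bright branch (`V ≥ ∂`)** — the *threshold weighted-bilinear* operator
  (TWB). The bright interval `[∂, 1]` is divided into `M = ⌈1/∂⌉` equal
  brightness steps; a pixel on step `j` is weighted by

      TWₙ = (CWₙ + ½) / H_j,   H_j = β + ω·j,

  with the conventional bilinear weights `CWₙ` sampled at the group center
  (each ¼), so the weight quadruple sums to `3/H_j` — strictly decreasing
  with brightness. Defaults `β = 1.5`, `ω = 0.025`: the first bright step
  has gain `3/β = 2`, exactly continuous with the dark branch, and the
  brightest step has gain `3/1.55 ≈ 1.94`, which is what keeps specular
  highlights from being pushed and enlarged further.

The selected branch output is averaged with the reference image
(`PM = (branch + I)/2`, a literal additive mode `branch + I/2` is also
available) and clipped to `[0, 1]`. Because the branch weights are shared
by the three channels of a pixel, the transform is achromatic and hue is
preserved at every non-clipped pixel.

The package also ships the evaluation metrics used to judge enhancement
(SSIM on luminance, per-channel relative contrast and intensity change) and
a synthetic capsule-frame generator (reddish mucosa, radial illumination
falloff, curvilinear vessels, specular spots, sensor noise) with
ground-truth region masks, so the whole pipeline is testable without any
clinical data.

## Worked example

```sh
python examples/enhance_synthetic_frame.py
```

```
mean intensity:  0.3156 -> 0.4679
dark-region gain:   1.5166  (25.6% of pixels, the distant lumen)
bright-region gain: 1.4833  (nearby tissue)
clipped pixels:     13.25%  (specular cores and the brightest tissue)
```

The distant dark lumen (a quarter of the frame) is brightened by ~1.52×
while bright tissue gains ~1.48× — the method's defining asymmetry: detail
is recovered where it was invisible without overexposing what was already
visible. `examples/branch_continuity.py` shows the branch gains joining
seamlessly at `V = 0.4` for `β = 1.5` (jump `0.000000`) and the
`3/1.45 − 2 ≈ 0.069` step for `β = 1.45`;
`examples/evaluate_enhancement.py` scores the two-branch method against a
single-branch (HWB-everywhere) baseline — SSIM 0.8877 vs 0.8867 on five
synthetic frames, the two-branch scheme staying structurally closer to the
reference.

A thin CLI wraps the same library calls:

```sh
capsenhance synth -o scene/ --seed 0
capsenhance enhance scene/scene.png -o enhanced.png --beta 1.5
capsenhance metrics -r scene/scene.png enhanced.png --csv report.csv
```

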