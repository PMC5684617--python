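"""Enhance one synthetic capsule frame and report what changed.

Renders a 288x288 frame with a dark distant-lumen region, vessels and
specular spots, runs the two-branch enhancement, and prints the brightness
gain in each region: dark tissue should gain ~1.5x while already-bright
tissue gains slightly less, and specular spots clip without growing gain.
"""

import numpy as np

from capsenhance import EnhanceParams, SceneParams, enhance_pm, generate_scene

image, truth = generate_scene(SceneParams(seed=0))
enhanced = enhance_pm(image, EnhanceParams())

valid = image.max(axis=2) > 1e-6
gain = enhanced.mean(axis=2)[valid] / image.mean(axis=2)[valid]
dark = truth.dark_mask[valid]

print(f"mean intensity:  {image.mean():.4f} -> {enhanced.mean():.4f}")
print(f"dark-region gain:   {gain[dark].mean():.4f}  "
      f"({truth.dark_mask.mean():.1%} of pixels, the distant lumen)")
print(f"bright-region gain: {gain[~dark].mean():.4f}  (nearby tissue)")
print(f"clipped pixels:     {np.any(enhanced >= 1.0, axis=2).mean():.2%}  "
      "(specular cores and the brightest tissue)")
# The dark branch applies effective gain 2 before blending (final ~1.5x);
# the bright branch shrinks its gain step by step with V, so dark regions
# are brightened hardest and highlights are not pushed further.
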