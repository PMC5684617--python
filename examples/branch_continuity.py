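"""Show that the two branches join seamlessly at the V threshold.

On an achromatic intensity ramp, the effective gain (branch output over the
2x2-group mean) is exactly 2 on the dark branch and 3/H_j on the bright
branch.  With beta = 1.50 the first bright step also has gain 3/1.5 = 2, so
the branch border is invisible; with beta = 1.45 a small step of
3/1.45 - 2 ~ 0.069 appears.
"""

import numpy as np

from capsenhance import (
    EnhanceParams, hwb_stage, make_ramp, split_value_map, twb_stage)

ramp = make_ramp(3, 256)
vmap = split_value_map(ramp)

for beta in (1.50, 1.45):
    params = EnhanceParams(beta=beta)
    hwb = hwb_stage(ramp)
    twb = twb_stage(ramp, vmap, params)
    branch = np.where((vmap < params.threshold)[:, :, None], hwb, twb)
    gain = branch[1, 1:, 0] / (hwb[1, 1:, 0] / 2.0)
    v = vmap[1, 1:]
    boundary = np.argmax(v >= params.threshold)
    jump = gain[boundary] - gain[boundary - 1]
    print(f"beta = {beta:.2f}: gain below threshold {gain[boundary-1]:.6f}, "
          f"above {gain[boundary]:.6f}, jump {jump:.6f}")
print("expected jump at beta=1.45:", 3 / 1.45 - 2)
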