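"""Naive per-pixel reference implementation of the enhancement pipeline.

Written with explicit Python loops and scalar arithmetic, independently of
the vectorised production code, so that agreement between the two is a real
cross-check of the array implementation.
"""

import math

PHI = 1.0
HALF_UNIT = 0.5


def enhance_reference(image, threshold=0.4, beta=1.5, omega=0.025,
                      combine_mode="average"):
    """Per-pixel loop version of the two-branch enhancement.

    ``image`` is a nested list or array of shape (H, W, 3) in [0, 1];
    returns a nested list of the same shape.
    """
    h = len(image)
    w = len(image[0])
    steps = math.ceil(PHI / threshold)
    bucket = (PHI - threshold) / steps

    out = [[[0.0, 0.0, 0.0] for _ in range(w)] for _ in range(h)]
    for r in range(h):
        for c in range(w):
            pixel = image[r][c]
            v = max(pixel[0], pixel[1], pixel[2])
            r2 = min(r + 1, h - 1)  # border replication
            c2 = min(c + 1, w - 1)
            for ch in range(3):
                p1 = image[r][c][ch]
                p2 = image[r2][c][ch]
                p3 = image[r][c2][ch]
                p4 = image[r2][c2][ch]
                if v < threshold:
                    branch = (p1 + p2 + p3 + p4) / 2.0
                else:
                    j = min(steps - 1,
                            int(math.floor((v - threshold) / bucket)))
                    tw = (0.25 + HALF_UNIT) / (beta + omega * j)
                    branch = (p1 + p2 + p3 + p4) * tw
                if combine_mode == "average":
                    value = (branch + pixel[ch]) / 2.0
                else:
                    value = branch + pixel[ch] / 2.0
                out[r][c][ch] = min(1.0, max(0.0, value))
    return out
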