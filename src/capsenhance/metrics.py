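"""Quantitative evaluation of enhancement results.

Two families of measures are exposed:

* :func:`ssim` — the structural similarity index between a reference and a
  test image, computed on a Rec.601 luminance conversion with the standard
  gaussian-window settings (11x11 window, sigma 1.5, K1 = 0.01, K2 = 0.03).
  SSIM close to 1 means the enhanced image retains the diagnostic structures
  of the reference.
* :func:`channel_contrast_change` / :func:`channel_intensity_change` —
  per-RGB-channel relative change of contrast (channel standard deviation)
  and intensity (channel mean) between reference and test.  Positive values
  mean the channel's contrast/brightness increased.  These are descriptive
  statistics, not quality scores: a huge positive contrast change usually
  signals over-enhancement.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from numpy.typing import NDArray
from skimage.metrics import structural_similarity

from .core import _validate_image
from .exceptions import SizeError, UndefinedStatisticError

__all__ = [
    "ChannelReport",
    "ssim",
    "channel_contrast_change",
    "channel_intensity_change",
]

# Rec.601 luma weights.
_LUMA = np.array([0.2989, 0.5870, 0.1140])


class ChannelReport(NamedTuple):
    """Signed relative change per RGB channel."""

    red: float
    green: float
    blue: float


def _validate_pair(reference: NDArray, test: NDArray):
    ref = _validate_image(reference)
    tst = _validate_image(test)
    if ref.shape != tst.shape:
        raise SizeError(
            f"reference shape {ref.shape} != test shape {tst.shape}")
    return ref, tst


def ssim(reference: NDArray, test: NDArray, *, win_size: int = 11,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean local structural similarity between two RGB images.

    Both images are converted to luminance (0.2989 R + 0.5870 G + 0.1140 B)
    and compared with a gaussian-weighted sliding window.  The result lies in
    [-1, 1], equal to 1 only for identical images.
    """
    ref, tst = _validate_pair(reference, test)
    if win_size > min(ref.shape[:2]):
        raise SizeError(
            f"window size {win_size} exceeds image extent {ref.shape[:2]}")
    luma_ref = ref @ _LUMA
    luma_tst = tst @ _LUMA
    return float(structural_similarity(
        luma_ref, luma_tst, win_size=win_size, gaussian_weights=True,
        sigma=sigma, K1=k1, K2=k2, use_sample_covariance=False,
        data_range=1.0))


def channel_contrast_change(reference: NDArray,
                            test: NDArray) -> ChannelReport:
    """Relative contrast change per channel: (std_test - std_ref) / std_ref.

    Raises :class:`UndefinedStatisticError` if any reference channel is
    constant (zero standard deviation).
    """
    ref, tst = _validate_pair(reference, test)
    std_ref = ref.std(axis=(0, 1))
    if np.any(std_ref == 0.0):
        raise UndefinedStatisticError(
            "contrast change undefined: a reference channel is constant")
    std_tst = tst.std(axis=(0, 1))
    return ChannelReport(*((std_tst - std_ref) / std_ref))


def channel_intensity_change(reference: NDArray,
                             test: NDArray) -> ChannelReport:
    """Relative intensity change per channel: (mean_test - mean_ref) / mean_ref.

    Raises :class:`UndefinedStatisticError` if any reference channel has zero
    mean.
    """
    ref, tst = _validate_pair(reference, test)
    mean_ref = ref.mean(axis=(0, 1))
    if np.any(mean_ref == 0.0):
        raise UndefinedStatisticError(
            "intensity change undefined: a reference channel has zero mean")
    mean_tst = tst.mean(axis=(0, 1))
    return ChannelReport(*((mean_tst - mean_ref) / mean_ref))
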