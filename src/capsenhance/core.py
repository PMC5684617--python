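"""Two-branch weighted-bilinear contrast enhancement.

Capsule-endoscopy frames are lit by LEDs on the capsule itself, so intensity
falls off sharply with distance: the lumen ahead of the capsule is nearly
black while tissue close to the lens is bright, with saturated specular spots
where the LEDs reflect directly off the wet mucosa.  The enhancement scheme
implemented here brightens both regimes with different gains, selected per
pixel by thresholding the HSV value channel V (the per-pixel max of R, G, B)
at an empirical threshold ``threshold`` (default 0.4):

* dark pixels (V < threshold) go through the *half-unit weighted-bilinear*
  operator (HWB): each overlapping 2x2 pixel group is summed and halved, an
  effective local gain of 2;
* bright pixels (V >= threshold) go through the *threshold weighted-bilinear*
  operator (TWB), whose four weights ``(CW_n + 1/2) / H_j`` shrink as the
  brightness step ``j`` of the pixel grows, ``H_j = beta + omega * j`` — the
  brighter the pixel, the gentler the gain, which avoids over-exposing and
  enlarging specular highlights.

The selected branch output is then blended with the reference image (by
default averaged with it) and clipped to [0, 1].  Because the branch weights
are identical for the three channels of a pixel, the whole pipeline applies
an achromatic (channel-uniform) transform and therefore preserves hue at
every pixel that does not clip.

All images are ``float`` arrays of shape (H, W, 3) with values in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numpy.typing import NDArray

from .exceptions import ConfigError, ParameterError, SizeError

__all__ = [
    "PHI",
    "HALF_UNIT",
    "EnhanceParams",
    "RegionMasks",
    "CwbWeights",
    "StepWeights",
    "split_value_map",
    "classify_regions",
    "cwb_weights",
    "hwb_stage",
    "step_index",
    "twb_weights",
    "twb_stage",
    "combine_pm",
    "enhance_pm",
    "enhance_hwb",
]

#: Maximum of the HSV value channel on [0, 1]-normalized images.
PHI = 1.0

#: The constant per-pixel weight that replaces the four bilinear weights in
#: the HWB, and that is added to each bilinear weight in the TWB numerator.
HALF_UNIT = 0.5

_COMBINE_MODES = ("average", "additive")


@dataclass(frozen=True)
class EnhanceParams:
    """Parameters of the two-branch enhancement.

    Parameters
    ----------
    threshold
        Empirical V threshold separating the dark branch (V < threshold)
        from the bright branch (V >= threshold).  Default 0.4.
    beta
        Initial value of the TWB denominator ``H_j``.  Valid range
        [1.45, 1.50]; at 1.50 the bright branch's first step has the same
        effective gain as the dark branch, making the branch boundary
        invisible.
    omega
        Increment between consecutive denominators, ``H_j = beta + omega*j``.
        Valid range (0, 0.025]; small values keep adjacent brightness steps
        visually seamless.
    combine_mode
        How the branch output is blended with the reference image ``I``:
        ``"average"`` (default) computes ``(branch + I) / 2``; ``"additive"``
        computes ``branch + I / 2``.
    """

    threshold: float = 0.4
    beta: float = 1.5
    omega: float = 0.025
    combine_mode: str = "average"

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ParameterError(
                f"threshold must lie in (0, 1), got {self.threshold}")
        if not 1.45 <= self.beta <= 1.50:
            raise ParameterError(
                f"beta must lie in [1.45, 1.50], got {self.beta}")
        if not 0.0 < self.omega <= 0.025:
            raise ParameterError(
                f"omega must lie in (0, 0.025], got {self.omega}")
        if self.combine_mode not in _COMBINE_MODES:
            raise ConfigError(
                f"combine_mode must be one of {_COMBINE_MODES}, "
                f"got {self.combine_mode!r}")

    @property
    def step_count(self) -> int:
        """Number of brightness steps M = ceil(phi / threshold), >= 1.

        The bright interval [threshold, phi] is split into M equal-width
        V-buckets; bucket ``j`` uses denominator ``H_j = beta + omega*j``.
        """
        return math.ceil(PHI / self.threshold)

    @property
    def bucket_width(self) -> float:
        """Width of one brightness step on the V axis."""
        return (PHI - self.threshold) / self.step_count


@dataclass(frozen=True)
class RegionMasks:
    """Disjoint dark / bright partition of an image on its V channel."""

    darker: NDArray[np.bool_]
    brighter: NDArray[np.bool_]
    threshold_used: float


class CwbWeights(NamedTuple):
    """The four conventional bilinear weights for offsets (dr, dc)."""

    w1: float
    w2: float
    w3: float
    w4: float


class StepWeights(NamedTuple):
    """TWB weight quadruple for one brightness step."""

    step: int
    denominator: float
    w1: float
    w2: float
    w3: float
    w4: float

    @property
    def weight_sum(self) -> float:
        return self.w1 + self.w2 + self.w3 + self.w4


def _validate_image(image: NDArray) -> NDArray[np.float64]:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise SizeError(
            f"expected an (H, W, 3) RGB array, got shape {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise SizeError(
            f"image must be at least 2x2, got {arr.shape[0]}x{arr.shape[1]}")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ParameterError("image intensities must lie in [0, 1]")
    return arr


def split_value_map(image: NDArray) -> NDArray[np.float64]:
    """Return the HSV value channel V: per pixel, max(R, G, B).

    The input is not modified; the result has shape (H, W).
    """
    arr = _validate_image(image)
    return arr.max(axis=2)


def classify_regions(vmap: NDArray, params: EnhanceParams) -> RegionMasks:
    """Partition pixels into darker (V < threshold) and brighter (V >= threshold).

    The inequality is strict on the dark side: a pixel exactly at the
    threshold belongs to the bright branch.
    """
    v = np.asarray(vmap, dtype=np.float64)
    darker = v < params.threshold
    return RegionMasks(darker=darker, brighter=~darker,
                       threshold_used=params.threshold)


def cwb_weights(dr: float, dc: float) -> CwbWeights:
    """Conventional bilinear weights for fractional offsets (dr, dc) in [0, 1].

    ``w1 = (1-dr)(1-dc)``, ``w2 = dr(1-dc)``, ``w3 = (1-dr)dc``,
    ``w4 = dr*dc``; the four always sum to 1.
    """
    if not (0.0 <= dr <= 1.0 and 0.0 <= dc <= 1.0):
        raise ParameterError(
            f"offsets must lie in [0, 1], got dr={dr}, dc={dc}")
    return CwbWeights(
        (1.0 - dr) * (1.0 - dc),
        dr * (1.0 - dc),
        (1.0 - dr) * dc,
        dr * dc,
    )


def _group_sum(arr: NDArray[np.float64]) -> NDArray[np.float64]:
    """Sum of each overlapping 2x2 group anchored at its top-left pixel.

    The last row and column are edge-replicated so the output has the input
    shape.  Works on (H, W) or (H, W, C) arrays.
    """
    pad = ((0, 1), (0, 1)) + ((0, 0),) * (arr.ndim - 2)
    p = np.pad(arr, pad, mode="edge")
    return p[:-1, :-1] + p[1:, :-1] + p[:-1, 1:] + p[1:, 1:]


def hwb_stage(image: NDArray) -> NDArray[np.float64]:
    """Half-unit weighted-bilinear operator: 2x2 group sum divided by 2.

    Applied per channel over overlapping groups; the output may exceed 1
    (clipping is deferred to :func:`combine_pm`).
    """
    arr = _validate_image(image)
    return _group_sum(arr) / 2.0


def step_index(eta: float, params: EnhanceParams) -> int:
    """Brightness step j of a bright-branch V value ``eta``.

    The bright interval [threshold, 1] is cut into ``step_count`` equal
    buckets; ``eta`` below the threshold is a contract violation (such pixels
    belong to the dark branch).
    """
    if eta < params.threshold:
        raise ParameterError(
            f"step_index is defined for V >= threshold "
            f"({params.threshold}), got {eta}")
    j = int(math.floor((eta - params.threshold) / params.bucket_width))
    return min(params.step_count - 1, j)


def _step_index_map(vmap: NDArray[np.float64],
                    params: EnhanceParams) -> NDArray[np.int_]:
    # Vectorised step_index; dark pixels harmlessly land on step 0 (callers
    # never use the bright branch there).
    j = np.floor((vmap - params.threshold) / params.bucket_width)
    return np.clip(j, 0, params.step_count - 1).astype(np.int_)


def twb_weights(j: int, params: EnhanceParams) -> StepWeights:
    """TWB weight quadruple for brightness step ``j``.

    Each weight is ``(CW_n + 1/2) / H_j`` with the bilinear weights sampled
    at the group center (dr = dc = 1/2, so each ``CW_n`` is 1/4) and
    ``H_j = beta + omega * j``.  The quadruple sums to ``3 / H_j``, strictly
    decreasing in ``j``: brighter steps receive gentler gain.
    """
    if not 0 <= j < params.step_count:
        raise ParameterError(
            f"step must lie in [0, {params.step_count}), got {j}")
    denom = params.beta + params.omega * j
    w = (0.25 + HALF_UNIT) / denom
    return StepWeights(j, denom, w, w, w, w)


def twb_stage(image: NDArray, vmap: NDArray,
              params: EnhanceParams) -> NDArray[np.float64]:
    """Threshold weighted-bilinear operator over the same 2x2 groups as HWB.

    Each output pixel is the weighted group sum with the step weights of its
    own V value; values are only meaningful on bright-branch pixels (callers
    select via :func:`combine_pm`).  May exceed 1 pre-clip.
    """
    arr = _validate_image(image)
    v = np.asarray(vmap, dtype=np.float64)
    if v.shape != arr.shape[:2]:
        raise SizeError(
            f"value map shape {v.shape} does not match image "
            f"shape {arr.shape[:2]}")
    j = _step_index_map(v, params)
    denom = params.beta + params.omega * j
    per_pixel_weight = (0.25 + HALF_UNIT) / denom
    return _group_sum(arr) * per_pixel_weight[:, :, None]


def combine_pm(image: NDArray, hwb_out: NDArray, twb_out: NDArray,
               masks: RegionMasks, params: EnhanceParams
               ) -> NDArray[np.float64]:
    """Select the branch per pixel and blend with the reference image.

    Dark pixels take the HWB output, bright pixels the TWB output — the same
    branch for all three channels of a pixel, which is what makes the
    transform hue-preserving.  ``average`` mode returns ``(branch + I) / 2``;
    ``additive`` returns ``branch + I / 2``.  The result is clipped to [0, 1].
    """
    arr = _validate_image(image)
    hwb_arr = np.asarray(hwb_out, dtype=np.float64)
    twb_arr = np.asarray(twb_out, dtype=np.float64)
    if hwb_arr.shape != arr.shape or twb_arr.shape != arr.shape:
        raise SizeError("stage outputs must match the reference image shape")
    if masks.darker.shape != arr.shape[:2]:
        raise SizeError("region masks must match the reference image shape")
    branch = np.where(masks.darker[:, :, None], hwb_arr, twb_arr)
    if params.combine_mode == "average":
        out = (branch + arr) / 2.0
    elif params.combine_mode == "additive":
        out = branch + arr / 2.0
    else:  # pragma: no cover - EnhanceParams already validates
        raise ConfigError(f"unknown combine_mode {params.combine_mode!r}")
    return np.clip(out, 0.0, 1.0)


def enhance_pm(image: NDArray,
               params: EnhanceParams | None = None) -> NDArray[np.float64]:
    """Full two-branch enhancement pipeline.

    Computes the V channel, partitions it at the threshold, runs both branch
    operators, and blends the selected branch with the reference.
    Deterministic; output has the input shape with values in [0, 1].
    """
    params = params or EnhanceParams()
    arr = _validate_image(image)
    vmap = arr.max(axis=2)
    masks = classify_regions(vmap, params)
    hwb_out = hwb_stage(arr)
    twb_out = twb_stage(arr, vmap, params)
    return combine_pm(arr, hwb_out, twb_out, masks, params)


def enhance_hwb(image: NDArray,
                params: EnhanceParams | None = None) -> NDArray[np.float64]:
    """Single-branch baseline: the HWB operator applied to every pixel.

    This is the earlier dark-branch-everywhere scheme the two-branch method
    improves on; it over-brightens the neighbourhood of specular areas.
    Blending and clipping follow ``params.combine_mode`` exactly as in
    :func:`enhance_pm`, so the two are directly comparable.
    """
    params = params or EnhanceParams()
    arr = _validate_image(image)
    hwb_out = hwb_stage(arr)
    all_dark = RegionMasks(
        darker=np.ones(arr.shape[:2], dtype=bool),
        brighter=np.zeros(arr.shape[:2], dtype=bool),
        threshold_used=params.threshold,
    )
    return combine_pm(arr, hwb_out, hwb_out, all_dark, params)
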