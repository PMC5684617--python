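"""Synthetic capsule-endoscopy test frames with ground-truth masks.

Real capsule frames cannot ship with the package, so this module renders
frames that reproduce the image properties the enhancement pipeline reacts
to: a reddish mucosa base color, radial illumination falloff toward a dark
"distant lumen" region, thin curvilinear vessels darker than the surrounding
tissue, small saturated specular highlights from the capsule's LEDs, and
sensor noise.  Every scene comes with ground-truth masks (dark region,
specular spots, vessels) computed from the noiseless render, so tests can
reason about regions exactly.

The render is deliberately *achromatic-decomposable*: every pixel has the
form ``base_color * L + c * (1, 1, 1)`` with scalar fields ``L`` (shading)
and ``c`` (specular blend plus luminance noise).  Any positive channel-shared
linear combination of such pixels keeps that form, which makes exact hue
preservation by the enhancement operators a testable property rather than an
approximation.  See ``docs/methods.md`` for what this does not model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from numpy.typing import NDArray
from scipy import interpolate, ndimage

from .exceptions import GeometryError

__all__ = ["SceneParams", "SceneTruth", "generate_scene", "make_ramp"]

#: V threshold used to label the ground-truth dark region.
DARK_TRUTH_THRESHOLD = 0.4
#: V threshold used to label the ground-truth specular region.
SPECULAR_TRUTH_THRESHOLD = 0.95


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic frame.

    Defaults follow the larger of the two frame-size categories of typical
    capsule recordings (288x288); 180x180 is the common small category.
    """

    height: int = 288
    width: int = 288
    base_color: Tuple[float, float, float] = (0.75, 0.35, 0.30)
    vignette_strength: float = 0.9
    vessel_count: int = 4
    vessel_width: float = 2.5
    vessel_depth: float = 0.55
    specular_count: int = 3
    specular_radius: float = 4.0
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise GeometryError(
                f"scene must be at least 16x16, got "
                f"{self.height}x{self.width}")
        if min(self.vessel_count, self.specular_count) < 0:
            raise GeometryError("feature counts must be non-negative")
        if not 0.0 <= self.vignette_strength <= 1.0:
            raise GeometryError("vignette_strength must lie in [0, 1]")
        short = min(self.height, self.width)
        if self.specular_count and 4.0 * self.specular_radius >= short:
            raise GeometryError(
                f"specular radius {self.specular_radius} too large for a "
                f"{self.height}x{self.width} scene")
        if self.vessel_count and 8.0 * self.vessel_width >= short:
            raise GeometryError(
                f"vessel width {self.vessel_width} too large for a "
                f"{self.height}x{self.width} scene")


@dataclass(frozen=True)
class SceneTruth:
    """Ground-truth masks of a scene, computed on the noiseless render."""

    dark_mask: NDArray[np.bool_]
    specular_mask: NDArray[np.bool_]
    vessel_mask: NDArray[np.bool_]


def _vessel_attenuation(params: SceneParams,
                        rng: np.random.Generator) -> NDArray[np.float64]:
    """Multiplicative attenuation field of the vessel network, in [0, 1]."""
    h, w = params.height, params.width
    on_curve = np.zeros((h, w), dtype=bool)
    for _ in range(params.vessel_count):
        # A smooth random curve through 5 control points spanning the frame.
        ctrl_r = rng.uniform(0.05 * h, 0.95 * h, size=5)
        ctrl_c = rng.uniform(0.05 * w, 0.95 * w, size=5)
        tck, _ = interpolate.splprep([ctrl_r, ctrl_c], s=0, k=3)
        t = np.linspace(0.0, 1.0, 4 * (h + w))
        rr, cc = interpolate.splev(t, tck)
        rr = np.clip(np.round(rr).astype(int), 0, h - 1)
        cc = np.clip(np.round(cc).astype(int), 0, w - 1)
        on_curve[rr, cc] = True
    if not on_curve.any():
        return np.ones((h, w))
    dist = ndimage.distance_transform_edt(~on_curve)
    profile = params.vessel_depth * np.exp(-((dist / params.vessel_width) ** 2))
    return 1.0 - profile


def _specular_blend(params: SceneParams,
                    rng: np.random.Generator) -> NDArray[np.float64]:
    """Blend-toward-white field a(p) in [0, 1]: 1 inside each spot core."""
    h, w = params.height, params.width
    a = np.zeros((h, w))
    if params.specular_count == 0:
        return a
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    margin = 2.0 * params.specular_radius + 2.0
    for _ in range(params.specular_count):
        # Spots land in the central region, i.e. on well-lit nearby tissue.
        cy = rng.uniform(0.25 * h, 0.75 * h)
        cx = rng.uniform(0.25 * w, 0.75 * w)
        cy = float(np.clip(cy, margin, h - margin))
        cx = float(np.clip(cx, margin, w - margin))
        dist = np.hypot(rows - cy, cols - cx) / params.specular_radius
        # Saturated core (dist <= 1) with a short soft shoulder to 1.6 r.
        spot = np.clip((1.6 - dist) / 0.6, 0.0, 1.0)
        a = np.maximum(a, spot)
    return a


def generate_scene(params: SceneParams | None = None
                   ) -> tuple[NDArray[np.float64], SceneTruth]:
    """Render one synthetic capsule frame and its ground-truth masks.

    The render composes, in order: base color times a radial vignette,
    multiplicative vessel darkening, specular blend toward pure white, and
    achromatic gaussian noise clipped per pixel so no channel leaves [0, 1].
    Identical ``params`` (including ``seed``) give bit-identical output; the
    truth masks are computed before noise is added.
    """
    params = params or SceneParams()
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    rows, cols = np.mgrid[0:h, 0:w].astype(float)

    # Radial illumination falloff, its center jittered off-frame-center the
    # way the lumen direction wanders in real recordings.
    cy = (0.5 + rng.uniform(-0.08, 0.08)) * (h - 1)
    cx = (0.5 + rng.uniform(-0.08, 0.08)) * (w - 1)
    corner = max(np.hypot(r - cy, c - cx)
                 for r in (0.0, h - 1.0) for c in (0.0, w - 1.0))
    dn = np.hypot(rows - cy, cols - cx) / corner
    shading = 1.0 - params.vignette_strength * dn ** 2
    shading = np.clip(shading, 0.02, 1.0)

    atten = _vessel_attenuation(params, rng)
    shading = shading * atten
    base = np.asarray(params.base_color, dtype=np.float64)
    image = base[None, None, :] * shading[:, :, None]

    blend = _specular_blend(params, rng)
    image = (1.0 - blend[:, :, None]) * image + blend[:, :, None]

    vmap = image.max(axis=2)
    truth = SceneTruth(
        dark_mask=vmap < DARK_TRUTH_THRESHOLD,
        specular_mask=vmap >= SPECULAR_TRUTH_THRESHOLD,
        vessel_mask=(1.0 - atten) > params.vessel_depth / 2.0,
    )

    if params.noise_sigma > 0.0:
        noise = rng.normal(0.0, params.noise_sigma, size=(h, w))
        # Achromatic (luminance) noise, clipped per pixel so that adding the
        # same offset to all three channels never leaves [0, 1].
        noise = np.clip(noise, -image.min(axis=2), 1.0 - image.max(axis=2))
        image = image + noise[:, :, None]
    return image, truth


def make_ramp(height: int, width: int) -> NDArray[np.float64]:
    """Achromatic horizontal ramp from 0 (left) to 1 (right).

    Columns are constant; the V channel of the ramp equals its own gray
    value, which makes it the canonical fixture for branch-boundary
    continuity checks.
    """
    if width < 8:
        raise GeometryError(f"ramp width must be >= 8, got {width}")
    ramp = np.linspace(0.0, 1.0, width)
    return np.broadcast_to(
        ramp[None, :, None], (height, width, 3)).copy()
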