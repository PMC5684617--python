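"""Raster image reading/writing and configuration loading.

Images travel through the package as float arrays in [0, 1]; this module
owns the conversions to and from integer raster files (PNG, TIFF, JPEG in;
PNG, TIFF out) and the plain-text YAML configuration surface for
:class:`~capsenhance.core.EnhanceParams`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from numpy.typing import NDArray

from .core import EnhanceParams
from .exceptions import ConfigError, FormatError, ParameterError

__all__ = ["read_image", "write_image", "load_config"]

logger = logging.getLogger(__name__)

_READ_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
_WRITE_EXTENSIONS = {".png", ".tif", ".tiff"}
_CONFIG_KEYS = {"threshold", "beta", "omega", "combine_mode"}


def read_image(path: str | Path) -> NDArray[np.float64]:
    """Read an RGB raster file as a float array in [0, 1].

    8-bit images are divided by 255, 16-bit by 65535.  Grayscale inputs are
    rejected (the enhancement is defined on RGB); an alpha channel is dropped
    with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = iio.imread(path)
    if raw.ndim != 3 or raw.shape[2] not in (3, 4):
        raise FormatError(
            f"{path.name}: expected an RGB(A) image, got shape {raw.shape}")
    if raw.shape[2] == 4:
        logger.warning("%s: dropping alpha channel", path.name)
        raw = raw[:, :, :3]
    if raw.dtype == np.uint8:
        scale = 255.0
    elif raw.dtype == np.uint16:
        scale = 65535.0
    else:
        raise FormatError(
            f"{path.name}: unsupported sample type {raw.dtype}; "
            "expected 8-bit or 16-bit integers")
    return raw.astype(np.float64) / scale


def write_image(image: NDArray, path: str | Path, *,
                bit_depth: int = 8) -> None:
    """Write a [0, 1] float image to PNG or TIFF at the given bit depth.

    Values are rescaled to the integer range and rounded half away from
    zero, so 0.5 stores as 128 at 8 bits.
    """
    path = Path(path)
    if path.suffix.lower() not in _WRITE_EXTENSIONS:
        raise FormatError(
            f"unsupported output extension {path.suffix!r}; "
            f"use one of {sorted(_WRITE_EXTENSIONS)}")
    arr = np.asarray(image, dtype=np.float64)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ParameterError("image values must lie in [0, 1] before writing")
    if bit_depth == 8:
        scale, dtype = 255.0, np.uint8
    elif bit_depth == 16:
        scale, dtype = 65535.0, np.uint16
    else:
        raise FormatError(f"unsupported bit depth {bit_depth}")
    quantized = np.floor(arr * scale + 0.5).astype(dtype)
    iio.imwrite(path, quantized)


def load_config(path: str | Path) -> EnhanceParams:
    """Load enhancement parameters from a YAML file.

    Recognised keys: ``threshold``, ``beta``, ``omega``, ``combine_mode``.
    Unknown keys and out-of-range values raise :class:`ConfigError` before
    any image is touched.
    """
    path = Path(path)
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path.name}: config must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(
            f"{path.name}: unknown config keys {sorted(unknown)}")
    try:
        return EnhanceParams(**data)
    except (ParameterError, ConfigError) as exc:
        raise ConfigError(f"{path.name}: {exc}") from exc
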