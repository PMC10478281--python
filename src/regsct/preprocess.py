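"""Hounsfield-unit windowing, normalisation, and grid resampling.

CT intensities are clipped to a fixed window (default [-1000, 2000] HU, wide
enough for air through dense bone) and mapped affinely onto [-1, 1] for the
networks; the inverse map restores HU so image metrics are always reported
on the calibrated scale.  Resampling is bilinear, matching the warping
operator's interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .errors import ConfigurationError, ShapeError

__all__ = [
    "HU_WINDOW", "HUImage", "NormalizedImage",
    "clip_hu", "normalize", "denormalize", "resample_to",
]

#: Default intensity window (HU).
HU_WINDOW = (-1000.0, 2000.0)

#: Default in-plane pixel spacing in mm (typical head-and-neck planning CT).
DEFAULT_SPACING = (0.977, 0.977)


@dataclass
class HUImage:
    """A 2-D image in Hounsfield units with its pixel spacing (mm)."""

    values: np.ndarray
    spacing: tuple[float, float] = DEFAULT_SPACING

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ShapeError(f"HUImage expects a 2-D array, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("HUImage contains non-finite values")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ConfigurationError("pixel spacing must be positive")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class NormalizedImage:
    """A 2-D image mapped onto [-1, 1], remembering the HU window used."""

    values: np.ndarray
    window: tuple[float, float] = HU_WINDOW
    spacing: tuple[float, float] = DEFAULT_SPACING

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        lo, hi = self.window
        if lo >= hi:
            raise ConfigurationError(f"window lo must be < hi, got {self.window}")
        if self.values.min() < -1.0 - 1e-6 or self.values.max() > 1.0 + 1e-6:
            raise ConfigurationError("normalized values must lie in [-1, 1]")


def clip_hu(image: HUImage, lo: float = HU_WINDOW[0], hi: float = HU_WINDOW[1]) -> HUImage:
    """Clamp intensities to [lo, hi] HU."""
    if lo >= hi:
        raise ConfigurationError(f"clip window requires lo < hi, got ({lo}, {hi})")
    return HUImage(np.clip(image.values, lo, hi), image.spacing)


def normalize(image: HUImage, window: tuple[float, float] = HU_WINDOW) -> NormalizedImage:
    """Affine map of a window-clipped image onto [-1, 1]."""
    lo, hi = window
    if lo >= hi:
        raise ConfigurationError(f"window lo must be < hi, got {window}")
    v = image.values
    if v.min() < lo or v.max() > hi:
        raise ConfigurationError(
            f"values outside window [{lo}, {hi}]; apply clip_hu first")
    scaled = 2.0 * (v.astype(np.float64) - lo) / (hi - lo) - 1.0
    return NormalizedImage(scaled.astype(np.float32), (lo, hi), image.spacing)


def denormalize(image: NormalizedImage) -> HUImage:
    """Exact affine inverse of :func:`normalize`."""
    lo, hi = image.window
    hu = (image.values.astype(np.float64) + 1.0) / 2.0 * (hi - lo) + lo
    return HUImage(hu.astype(np.float32), image.spacing)


def resample_to(image: HUImage, size: int) -> HUImage:
    """Bilinear resampling onto a size x size grid; spacing rescaled."""
    if size < 8:
        raise ConfigurationError(f"target size must be >= 8, got {size}")
    h, w = image.values.shape
    if (h, w) == (size, size):
        return HUImage(image.values.copy(), image.spacing)
    out = resize(image.values, (size, size), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    spacing = (image.spacing[0] * h / size, image.spacing[1] * w / size)
    return HUImage(out.astype(np.float32), spacing)
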