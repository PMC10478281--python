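"""Dense displacement fields and the differentiable warping operator.

A deformation field stores one (row, col) displacement vector per pixel, in
pixel units, as a (2, H, W) array.  Warping resamples the input with
bilinear interpolation at ``p + field(p)``; samples outside the grid clamp
to the border.  A zero field is an exact identity and the operator is
linear in the image, which the loss definitions rely on.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ShapeError

__all__ = ["warp", "warp_tensor", "as_field", "field_magnitude"]


def as_field(values: np.ndarray) -> np.ndarray:
    """Validate and return a (2, H, W) float displacement field."""
    f = np.asarray(values, dtype=np.float32)
    if f.ndim != 3 or f.shape[0] != 2:
        raise ShapeError(f"deformation field must be (2, H, W), got {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ShapeError("deformation field contains non-finite values")
    return f


def field_magnitude(field: np.ndarray) -> np.ndarray:
    f = as_field(field)
    return np.sqrt(f[0] ** 2 + f[1] ** 2)


def warp_tensor(image: Tensor, field: Tensor) -> Tensor:
    """Warp an (N, C, H, W) tensor by an (N, 2, H, W) displacement tensor."""
    return ad.grid_sample(image, field)


def warp(image: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Warp a 2-D array by a (2, H, W) field; forward computation only."""
    img = np.asarray(image)
    f = as_field(field)
    if img.ndim != 2:
        raise ShapeError(f"expected a 2-D image, got shape {img.shape}")
    if f.shape[1:] != img.shape:
        raise ShapeError(f"field spatial shape {f.shape[1:]} != image shape {img.shape}")
    out = ad.grid_sample(Tensor(img.astype(np.float32)[None, None]),
                         Tensor(f[None]))
    return out.data[0, 0].astype(img.dtype, copy=False)
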