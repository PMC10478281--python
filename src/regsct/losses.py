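"""The loss system: correction, smoothness, and adversarial terms.

The training objective treats the misaligned reference image as a noisy
label: the generator output is first spatially corrected by the
registration network's displacement field, and only then compared to the
reference under L1.  A squared-gradient penalty keeps the field smooth, and
a least-squares patch-adversarial term sharpens the output.  With a
zero-initialised registration head the correction loss reduces exactly to
plain L1 at the first step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigurationError, ShapeError
from .warp import warp_tensor

__all__ = [
    "LossWeights", "correction_loss", "smoothness_loss",
    "adversarial_terms", "total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Weights of the three loss terms (printed objective: unweighted sum)."""

    w_corr: float = 1.0
    w_smooth: float = 1.0
    w_adv: float = 1.0

    def validate(self) -> None:
        if self.w_corr < 0 or self.w_smooth < 0 or self.w_adv < 0:
            raise ConfigurationError("loss weights must be non-negative")
        if self.w_corr == 0 and self.w_smooth == 0 and self.w_adv == 0:
            raise ConfigurationError("at least one loss weight must be positive")


def _as4d(x) -> Tensor:
    if isinstance(x, Tensor):
        if x.data.ndim == 4:
            return x
        if x.data.ndim == 2 and not (x.requires_grad or x._parents):
            return Tensor(x.data[None, None])
        raise ShapeError(f"expected a 2-D or (N, C, H, W) tensor, got shape {x.data.shape}")
    arr = np.asarray(x, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, None]
    if arr.ndim != 4:
        raise ShapeError(f"expected a 2-D or 4-D array, got shape {arr.shape}")
    return Tensor(arr)


def _as_field4d(x) -> Tensor:
    if isinstance(x, Tensor):
        if x.data.ndim == 4:
            return x
        if x.data.ndim == 3 and not (x.requires_grad or x._parents):
            return Tensor(x.data[None])
        raise ShapeError(f"expected a (2, H, W) or (N, 2, H, W) field, got {x.data.shape}")
    arr = np.asarray(x, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    return Tensor(arr)


def correction_loss(noisy_label, generated, field) -> Tensor:
    """Mean L1 between the noisy label and the warped generator output."""
    y = _as4d(noisy_label)
    g = _as4d(generated)
    f = _as_field4d(field)
    if y.data.shape != g.data.shape:
        raise ShapeError(f"label shape {y.data.shape} != generated shape {g.data.shape}")
    warped = warp_tensor(g, f)
    return ad.mean(ad.absolute(y - warped))


def smoothness_loss(field) -> Tensor:
    """Squared forward-difference penalty on the displacement field.

    Sum over the two displacement components and two spatial directions of
    the mean squared forward difference, so a unit-slope component scores
    exactly 1.
    """
    f = _as_field4d(field)
    if f.data.ndim != 4 or f.data.shape[1] != 2:
        raise ShapeError(f"field must be (N, 2, H, W), got {f.data.shape}")
    return ad.gradient_sq_penalty(f)


def adversarial_terms(score_real, score_fake) -> tuple[Tensor, Tensor]:
    """Least-squares GAN terms (real = 1, fake = 0).

    Returns ``(g_term, d_term)``: the generator is rewarded when fakes score
    1; the discriminator when reals score 1 and fakes 0.
    """
    sr = score_real if isinstance(score_real, Tensor) else Tensor(np.asarray(score_real, dtype=np.float32))
    sf = score_fake if isinstance(score_fake, Tensor) else Tensor(np.asarray(score_fake, dtype=np.float32))
    if sr.data.shape != sf.data.shape:
        raise ShapeError(f"score map shapes differ: {sr.data.shape} vs {sf.data.shape}")
    g_term = ad.mean(ad.square(sf - 1.0))
    d_term = ad.add(ad.mul(ad.mean(ad.square(sr - 1.0)), 0.5),
                    ad.mul(ad.mean(ad.square(sf)), 0.5))
    return g_term, d_term


def total_loss(components, weights: LossWeights) -> Tensor:
    """Weighted sum of (correction, smoothness, adversarial-G) terms."""
    weights.validate()
    corr, smooth, adv_g = components
    out = None
    for w, term in ((weights.w_corr, corr), (weights.w_smooth, smooth), (weights.w_adv, adv_g)):
        if not isinstance(term, Tensor):
            term = Tensor(np.asarray(term, dtype=np.float32))
        if not np.all(np.isfinite(term.data)):
            raise ConfigurationError("non-finite loss component")
        piece = ad.mul(term, float(w))
        out = piece if out is None else ad.add(out, piece)
    return out
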