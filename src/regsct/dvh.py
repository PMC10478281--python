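"""Cumulative dose-volume histograms and PTV dose statistics.

D_p denotes the dose received by at least p% of the masked volume (the
standard radiotherapy reading: D95 is the dose covering the coldest-excluded
95% — i.e. the hottest 95% — of the target).  The difference rate
Dr = (D_sCT - D_pCT) / D_pCT quantifies the relative discrepancy between a
dose metric computed on the synthetic CT plan and on the planning-CT plan,
and pass rates count cases with |Dr| within a clinical threshold (e.g. 1%
or 3% on D95).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ShapeError

__all__ = [
    "DVHCurve", "DVHMetrics", "cumulative_dvh", "dose_at_volume",
    "dvh_metrics", "difference_rate", "pass_rate",
]


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of volume receiving at least each dose."""

    dose_levels: np.ndarray  # Gy, ascending
    volume_fraction: np.ndarray  # in [0, 1], non-increasing


@dataclass
class DVHMetrics:
    dmin: float
    dmax: float
    dmean: float
    d2: float
    d50: float
    d95: float
    d98: float

    def __post_init__(self):
        ordered = [self.dmin, self.d98, self.d95, self.d50, self.d2, self.dmax]
        for lo, hi in zip(ordered, ordered[1:]):
            if lo > hi + 1e-9:
                raise ConfigurationError(
                    "DVH ordering violated: require dmin <= d98 <= d95 <= d50 <= d2 <= dmax")


def _masked_doses(dose: np.ndarray, mask: np.ndarray) -> np.ndarray:
    dose = np.asarray(dose, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if dose.shape != mask.shape:
        raise ShapeError(f"dose shape {dose.shape} != mask shape {mask.shape}")
    if not mask.any():
        raise ConfigurationError("mask selects no voxels")
    vals = dose[mask]
    if (vals < 0).any() or not np.all(np.isfinite(vals)):
        raise ConfigurationError("dose values must be finite and non-negative")
    return vals


def cumulative_dvh(dose: np.ndarray, mask: np.ndarray, bins: int = 1000) -> DVHCurve:
    """Cumulative DVH of the masked voxels over ``bins`` dose levels."""
    if bins < 2:
        raise ConfigurationError("need at least 2 bins")
    vals = _masked_doses(dose, mask)
    dmax = vals.max()
    levels = np.linspace(0.0, dmax if dmax > 0 else 1.0, bins)
    frac = (vals[None, :] >= levels[:, None]).mean(axis=1)
    return DVHCurve(levels, frac)


def dose_at_volume(curve: DVHCurve, p: float) -> float:
    """Largest dose d with at least p% of the volume receiving >= d.

    Linear interpolation between the bracketing dose levels.  ``p`` must lie
    strictly inside (0, 100); use dmin/dmax for the endpoints.
    """
    if not 0 < p < 100:
        raise ConfigurationError(f"p must be in (0, 100), got {p}")
    target = p / 100.0
    frac = curve.volume_fraction
    levels = curve.dose_levels
    idx = np.nonzero(frac >= target)[0]
    if idx.size == 0:
        return float(levels[0])
    i = idx[-1]  # last level still covering >= target of the volume
    if i == len(levels) - 1 or frac[i] == target:
        return float(levels[i])
    f0, f1 = frac[i], frac[i + 1]
    if f0 == f1:
        return float(levels[i])
    t = (f0 - target) / (f0 - f1)
    return float(levels[i] + t * (levels[i + 1] - levels[i]))


def dvh_metrics(dose: np.ndarray, mask: np.ndarray, bins: int = 1000) -> DVHMetrics:
    """Dmin/Dmax/Dmean directly from voxels; D2/D50/D95/D98 from the curve."""
    vals = _masked_doses(dose, mask)
    curve = cumulative_dvh(dose, mask, bins)
    dmin, dmax = float(vals.min()), float(vals.max())

    def dv(p):  # curve resolution can under/overshoot the voxel extremes
        return float(np.clip(dose_at_volume(curve, p), dmin, dmax))

    return DVHMetrics(
        dmin=dmin,
        dmax=dmax,
        dmean=float(vals.mean()),
        d2=dv(2),
        d50=dv(50),
        d95=dv(95),
        d98=dv(98),
    )


def difference_rate(d_sct: float, d_pct: float) -> float:
    """Signed relative dose difference (D_sCT - D_pCT) / D_pCT.

    Returns NaN (the undefined flag) when the reference dose is not
    positive.
    """
    if d_pct <= 0:
        return math.nan
    return (d_sct - d_pct) / d_pct


def pass_rate(dr_values, threshold: float) -> float:
    """Fraction of cases whose |Dr| does not exceed ``threshold``."""
    vals = np.asarray(list(dr_values), dtype=np.float64)
    if vals.size == 0:
        raise ConfigurationError("pass_rate requires at least one Dr value")
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    return float((np.abs(vals) <= threshold).mean())
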