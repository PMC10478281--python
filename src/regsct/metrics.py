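"""Image-quality metrics, restricted-range HU histograms, and group tests.

MAE, MSE, PSNR and SSIM are computed in Hounsfield units with the planning
CT as the gold standard.  SSIM defaults to the single-window (global
statistics) form — means, variances and cross-covariance over the whole
image — with c1 = (0.01 L)^2, c2 = (0.03 L)^2 for an intensity range L; a
conventional 11x11 windowed variant is available for comparison with other
reports.  HU histograms discard values outside [-500, 500] before binning,
which removes the dominant air peak and leaves the soft-tissue range where
modality differences live.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity as _skimage_ssim
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ShapeError
from .preprocess import HU_WINDOW, HUImage

__all__ = [
    "mae", "mse", "psnr", "ssim", "hu_histogram", "HUHistogram",
    "evaluate_dataset", "compare_groups",
]

#: Intensity range L used for the default SSIM constants: the HU window span.
SSIM_RANGE = HU_WINDOW[1] - HU_WINDOW[0]


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, HUImage) else np.asarray(x, dtype=np.float64)


def _check_shapes(a, b) -> tuple[np.ndarray, np.ndarray]:
    av, bv = _values(a).astype(np.float64), _values(b).astype(np.float64)
    if av.shape != bv.shape:
        raise ShapeError(f"image shapes differ: {av.shape} vs {bv.shape}")
    return av, bv


def mae(a, b) -> float:
    """Mean absolute difference (HU)."""
    av, bv = _check_shapes(a, b)
    return float(np.abs(av - bv).mean())


def mse(a, b) -> float:
    """Mean squared difference (HU^2)."""
    av, bv = _check_shapes(a, b)
    return float(((av - bv) ** 2).mean())


def psnr(a, b, peak: float | str = "auto") -> float:
    """Peak signal-to-noise ratio, 10*log10(peak^2 / MSE), in dB.

    ``peak`` defaults to the maximum pixel value of the reference image
    ``a``; pass a number to pin it (e.g. the HU window span).  Identical
    images yield ``inf`` rather than raising.
    """
    av, bv = _check_shapes(a, b)
    err = ((av - bv) ** 2).mean()
    pk = float(av.max()) if peak == "auto" else float(peak)
    if pk <= 0:
        raise ConfigurationError(f"PSNR peak must be positive, got {pk}")
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(pk * pk / err))


def ssim(a, b, constants: tuple[float, float] | None = None,
         data_range: float = SSIM_RANGE, windowed: bool = False) -> float:
    """Structural similarity.

    Default is the global-statistics form
    ``(2 mu_a mu_b + c1)(2 cov_ab + c2) /
    ((mu_a^2 + mu_b^2 + c1)(var_a + var_b + c2))``
    with c1 = (0.01 L)^2, c2 = (0.03 L)^2, L = ``data_range``.
    ``windowed=True`` switches to the conventional 11x11 Gaussian-windowed
    mean-pooled variant.
    """
    av, bv = _check_shapes(a, b)
    if windowed:
        return float(_skimage_ssim(av, bv, data_range=data_range,
                                   gaussian_weights=True, sigma=1.5,
                                   use_sample_covariance=False))
    if constants is None:
        c1, c2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
    else:
        c1, c2 = constants
    mu_a, mu_b = av.mean(), bv.mean()
    var_a, var_b = av.var(), bv.var()
    cov = ((av - mu_a) * (bv - mu_b)).mean()
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
    return float(num / den)


@dataclass
class HUHistogram:
    """Normalised histogram over a restricted HU range."""

    bin_edges: np.ndarray
    counts: np.ndarray
    empty: bool

    def peak_hu(self) -> float:
        if self.empty:
            raise ConfigurationError("histogram is empty; no peak")
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return float(centers[int(np.argmax(self.counts))])


def hu_histogram(image, lo: float = -500.0, hi: float = 500.0,
                 bins: int = 100) -> HUHistogram:
    """Histogram of in-range voxels only, normalised to sum to 1."""
    if bins < 2:
        raise ConfigurationError(f"need at least 2 bins, got {bins}")
    v = _values(image).ravel()
    v = v[(v >= lo) & (v <= hi)]
    edges = np.linspace(lo, hi, bins + 1)
    if v.size == 0:
        return HUHistogram(edges, np.zeros(bins), empty=True)
    counts, _ = np.histogram(v, bins=edges)
    return HUHistogram(edges, counts / counts.sum(), empty=False)


def evaluate_dataset(samples, translator) -> pd.DataFrame:
    """Per-case image-quality table: CBCT-vs-pCT and sCT-vs-pCT rows.

    ``translator`` is either a trained checkpoint or a callable mapping an
    :class:`HUImage` CBCT slice to an sCT :class:`HUImage` (e.g. identity
    for a degradation baseline).  Returns a tidy DataFrame; aggregate with
    :func:`aggregate_report`.
    """
    if not callable(translator):
        from .training import translate  # deferred: training imports metrics
        checkpoint = translator
        translator = lambda img: translate(img, checkpoint)  # noqa: E731
    rows = []
    for i, s in enumerate(samples):
        sct = translator(s.cbct)
        for comparison, img in (("cbct_vs_pct", s.cbct), ("sct_vs_pct", sct)):
            rows.append({
                "case": i,
                "profile": s.profile_name,
                "comparison": comparison,
                "mae": mae(img, s.pct),
                "mse": mse(img, s.pct),
                "psnr": psnr(s.pct, img),
                "ssim": ssim(img, s.pct),
            })
    return pd.DataFrame(rows)


def aggregate_report(report: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of each metric per (profile, comparison) group."""
    return (report.groupby(["profile", "comparison"])[["mae", "mse", "psnr", "ssim"]]
            .agg(["mean", "std"]))


def compare_groups(report: pd.DataFrame, metric: str,
                   comparison: str = "sct_vs_pct", alpha: float = 0.05) -> dict:
    """Kruskal-Wallis across profile groups plus Holm-corrected pairwise tests.

    A thin wrapper over scipy/statsmodels routines, returning the H
    statistic, its p-value, and a pairwise Mann-Whitney table.
    """
    sub = report[report["comparison"] == comparison]
    groups = {name: g[metric].to_numpy() for name, g in sub.groupby("profile")}
    if len(groups) < 2:
        raise ConfigurationError("need at least 2 groups to compare")
    if any(len(v) < 3 for v in groups.values()):
        raise ConfigurationError("need at least 3 cases per group")
    names = sorted(groups)
    stat, pvalue = stats.kruskal(*(groups[n] for n in names))
    pairs = list(itertools.combinations(names, 2))
    raw = [stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
           for a, b in pairs]
    corrected = multipletests(raw, alpha=alpha, method="holm")[1] if pairs else []
    pairwise = pd.DataFrame({
        "group_a": [a for a, _ in pairs],
        "group_b": [b for _, b in pairs],
        "p_raw": raw,
        "p_corrected": corrected,
    })
    return {"statistic": float(stat), "pvalue": float(pvalue), "pairwise": pairwise}
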