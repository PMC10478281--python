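"""Head-and-neck-like digital phantoms with accelerator-specific CBCT degradation.

Real paired planning-CT / cone-beam-CT data cannot ship with the package, so
this module manufactures study conditions with known ground truth: a
piecewise-constant anatomy slice (air background, soft-tissue ellipse, bone
ring, optional air cavities), and a CBCT counterpart produced by warping the
planning image with a random smooth deformation field (the "label noise" the
registration network must absorb) followed by intensity degradation — blur,
a global HU shift, a radial cupping bias, and additive noise — mimicking
the qualitative differences between on-board imagers.  The ``synergy``
profile is deliberately the most degraded: clinically its CBCT soft-tissue
peak sits near -220 HU against the planning CT's ~70 HU, so its default
shift is the largest.

Everything is a pure function of its seed, and each sample of a dataset can
be regenerated in isolation from the recorded per-sample seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, ShapeError
from .preprocess import HU_WINDOW, HUImage
from .warp import warp

__all__ = [
    "PhantomSpec", "DegradationProfile", "PairedSample", "DEFAULT_PROFILES",
    "generate_phantom", "random_deformation", "degrade_to_cbct",
    "make_dataset", "synthetic_dose", "sample_seed",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue intensities of the synthetic anatomy slice."""

    grid_size: int = 256
    tissue_hu: float = 40.0
    bone_hu: float = 800.0
    air_hu: float = -1000.0
    shape_jitter: float = 0.05
    n_air_cavities: int = 3

    def validate(self) -> None:
        if self.grid_size < 32:
            raise ConfigurationError(f"grid_size must be >= 32, got {self.grid_size}")
        if self.air_hu < -1000:
            raise ConfigurationError(f"air_hu must be >= -1000, got {self.air_hu}")
        if self.bone_hu > 2000:
            raise ConfigurationError(f"bone_hu must be <= 2000, got {self.bone_hu}")
        if self.n_air_cavities < 0:
            raise ConfigurationError("n_air_cavities must be non-negative")
        if self.shape_jitter < 0:
            raise ConfigurationError("shape_jitter must be non-negative")


@dataclass(frozen=True)
class DegradationProfile:
    """Intensity and geometric corruption applied to make a CBCT-like slice.

    Units: ``hu_shift`` and ``cupping_amplitude`` in HU, ``noise_sd`` in HU,
    ``blur_sigma`` / ``deform_amplitude`` / ``deform_smoothness`` in pixels.
    """

    name: str
    hu_shift: float = 0.0
    cupping_amplitude: float = 0.0
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    deform_amplitude: float = 0.0
    deform_smoothness: float = 8.0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.deform_amplitude < 0:
            raise ConfigurationError("deform_amplitude must be non-negative")
        if self.deform_smoothness <= 0:
            raise ConfigurationError("deform_smoothness must be positive")
        for fname in ("hu_shift", "cupping_amplitude", "noise_sd", "blur_sigma",
                      "deform_amplitude", "deform_smoothness"):
            if not np.isfinite(getattr(self, fname)):
                raise ConfigurationError(f"{fname} must be finite")


#: Named degradation profiles, ordered mild to severe.  ``synergy`` is the
#: outlier by design (largest HU shift), mirroring its clinical behaviour.
DEFAULT_PROFILES: dict[str, DegradationProfile] = {
    "halcyon": DegradationProfile("halcyon", hu_shift=-40.0, cupping_amplitude=25.0,
                                  noise_sd=20.0, blur_sigma=0.8, deform_amplitude=2.0),
    "trilogy": DegradationProfile("trilogy", hu_shift=-60.0, cupping_amplitude=30.0,
                                  noise_sd=25.0, blur_sigma=1.0, deform_amplitude=2.0),
    "vitalbeam": DegradationProfile("vitalbeam", hu_shift=-55.0, cupping_amplitude=25.0,
                                    noise_sd=22.0, blur_sigma=0.9, deform_amplitude=2.0),
    "synergy": DegradationProfile("synergy", hu_shift=-290.0, cupping_amplitude=40.0,
                                  noise_sd=45.0, blur_sigma=1.3, deform_amplitude=3.0),
}


@dataclass
class PairedSample:
    """One training/evaluation case with known ground-truth misalignment."""

    pct: HUImage
    cbct: HUImage
    true_field: np.ndarray  # (2, H, W) displacement, pixels
    profile_name: str
    seed: int

    def __post_init__(self):
        if self.pct.shape != self.cbct.shape:
            raise ShapeError("pct and cbct must share a grid shape")
        if self.true_field.shape != (2,) + self.pct.shape:
            raise ShapeError("true_field must hold one 2-vector per pixel")


def _ellipse_mask(size: int, center, semi_axes) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    return (((rr - center[0]) / semi_axes[0]) ** 2
            + ((cc - center[1]) / semi_axes[1]) ** 2) <= 1.0


def generate_phantom(spec: PhantomSpec, seed: int) -> HUImage:
    """A head-like slice: air background, bone ring, soft tissue, cavities."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.grid_size
    jit = spec.shape_jitter

    center = np.array([n / 2.0, n / 2.0])
    center += jit * n * 0.1 * rng.uniform(-1, 1, 2)
    outer = np.array([0.42 * n, 0.36 * n]) * (1.0 + jit * rng.uniform(-1, 1, 2))
    inner = outer * (1.0 - 0.08 * (1.0 + jit * rng.uniform(-1, 1)))

    img = np.full((n, n), spec.air_hu, dtype=np.float32)
    img[_ellipse_mask(n, center, outer)] = spec.bone_hu
    tissue = _ellipse_mask(n, center, inner)
    img[tissue] = spec.tissue_hu

    for _ in range(spec.n_air_cavities):
        offset = rng.uniform(-0.45, 0.45, 2) * inner
        radii = rng.uniform(0.02, 0.07, 2) * n
        cav = _ellipse_mask(n, center + offset, np.maximum(radii, 1.0))
        img[cav & tissue] = spec.air_hu

    np.clip(img, HU_WINDOW[0], HU_WINDOW[1], out=img)
    return HUImage(img)


def random_deformation(shape, amplitude: float, smoothness: float, seed: int) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to a given peak displacement.

    Returns a (2, H, W) field whose maximum displacement magnitude equals
    ``amplitude`` pixels (exactly zero everywhere if ``amplitude`` is 0).
    """
    if smoothness <= 0:
        raise ConfigurationError("smoothness must be positive")
    if amplitude < 0:
        raise ConfigurationError("amplitude must be non-negative")
    h, w = shape
    if amplitude == 0:
        return np.zeros((2, h, w), dtype=np.float32)
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((2, h, w))
    smooth = np.stack([gaussian_filter(raw[i], smoothness) for i in range(2)])
    mag = np.sqrt(smooth[0] ** 2 + smooth[1] ** 2)
    peak = mag.max()
    if peak == 0:  # pathological but possible at extreme smoothing
        return np.zeros((2, h, w), dtype=np.float32)
    return (smooth * (amplitude / peak)).astype(np.float32)


def _cupping_bias(shape, amplitude: float) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    r2 = (rr - (h - 1) / 2.0) ** 2 + (cc - (w - 1) / 2.0) ** 2
    rmax2 = (min(h, w) / 2.0) ** 2
    return (amplitude * r2 / rmax2).astype(np.float32)


def degrade_to_cbct(pct: HUImage, profile: DegradationProfile,
                    seed: int) -> tuple[HUImage, np.ndarray]:
    """Degrade a planning-CT slice into its CBCT counterpart.

    Order: warp by a fresh random deformation (spatial "label noise"), then
    blur, global HU shift, radial cupping bias, additive noise, and a final
    clip to the HU window.  Returns the degraded image and the field used.
    The all-zero profile is a bit-exact identity.
    """
    profile.validate()
    v = pct.values
    if v.min() < HU_WINDOW[0] or v.max() > HU_WINDOW[1]:
        raise ConfigurationError("pct values must lie within the HU window; clip first")
    field = random_deformation(v.shape, profile.deform_amplitude,
                               profile.deform_smoothness, seed)
    out = warp(v, field)
    if profile.blur_sigma > 0:
        out = gaussian_filter(out, profile.blur_sigma)
    if profile.hu_shift:
        out = out + np.float32(profile.hu_shift)
    if profile.cupping_amplitude:
        out = out + _cupping_bias(v.shape, profile.cupping_amplitude)
    if profile.noise_sd > 0:
        noise_rng = np.random.default_rng(seed + 1)
        out = out + noise_rng.normal(0.0, profile.noise_sd, v.shape).astype(np.float32)
    out = np.clip(out, HU_WINDOW[0], HU_WINDOW[1])
    return HUImage(out.astype(np.float32), pct.spacing), field


def sample_seed(master_seed: int, index: int) -> int:
    """Deterministic per-sample seed: SeedSequence([master, index]) mod 2^31."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2 ** 31))


def make_dataset(n: int, spec: PhantomSpec, profiles, seed: int) -> list[PairedSample]:
    """n paired samples cycling over the given degradation profiles."""
    if n < 1:
        raise ConfigurationError(f"dataset size must be >= 1, got {n}")
    profiles = list(profiles)
    if not profiles:
        raise ConfigurationError("at least one degradation profile is required")
    for p in profiles:
        p.validate()
    spec.validate()
    samples = []
    for i in range(n):
        profile = profiles[i % len(profiles)]
        s = sample_seed(seed, i)
        pct = generate_phantom(spec, s)
        cbct, true_field = degrade_to_cbct(pct, profile, s + 1)
        samples.append(PairedSample(pct, cbct, true_field, profile.name, s))
    return samples


def synthetic_dose(shape, kind: str, params: dict | None = None) -> np.ndarray:
    """Analytic non-negative dose grids (Gy) for DVH testing.

    Kinds: ``uniform`` (params: dose), ``linear_gradient`` (low, high, axis),
    ``gaussian_blob`` (peak, sigma, center).
    """
    params = dict(params or {})
    h, w = shape
    if kind == "uniform":
        dose = float(params.get("dose", 60.0))
        if dose < 0:
            raise ConfigurationError("dose must be non-negative")
        return np.full((h, w), dose, dtype=np.float64)
    if kind == "linear_gradient":
        low = float(params.get("low", 0.0))
        high = float(params.get("high", 60.0))
        axis = int(params.get("axis", 1))
        if low < 0 or high < 0:
            raise ConfigurationError("dose bounds must be non-negative")
        ramp = np.linspace(low, high, shape[axis])
        return (np.broadcast_to(ramp, (h, w)) if axis == 1
                else np.broadcast_to(ramp[:, None], (h, w))).astype(np.float64).copy()
    if kind == "gaussian_blob":
        peak = float(params.get("peak", 70.0))
        sigma = float(params.get("sigma", min(h, w) / 6.0))
        center = params.get("center", (h // 2, w // 2))
        if peak < 0:
            raise ConfigurationError("peak must be non-negative")
        rr, cc = np.mgrid[0:h, 0:w]
        r2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
        return peak * np.exp(-r2 / (2.0 * sigma ** 2))
    raise ConfigurationError(f"unknown dose kind {kind!r}; "
                             "use uniform | linear_gradient | gaussian_blob")
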