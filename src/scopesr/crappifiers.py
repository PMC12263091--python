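"""Semi-synthetic image degradation ("crappification").

High-resolution images are turned into realistic low-resolution
counterparts by block-average downsampling followed by noise injection.
The operation order matters: injecting noise *before* downsampling lets
adjacent noise values average out, shrinking the per-pixel noise
variance by roughly the square of the scale factor and producing
unrealistically clean training inputs.  :func:`crappify` therefore
always downsamples first; :func:`crappify_legacy_order` implements the
older noise-first order for comparison.

Noise intensity is drawn independently per image from a uniform
interval, so a training set spans a range of input qualities.

Poisson parameterization: intensity ``I >= 0`` acts as an inverse photon
budget.  A pixel value ``x`` on [0, 1] is replaced by
``Poisson(x * G / I) * I / G`` with photon gain ``G`` (default 255), so
the mean is preserved while the variance ``x * I / G`` grows with both
the pixel value and the intensity.  ``I = 0`` is the deterministic
(noiseless) limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["CrappifierSpec", "DegradationResult", "downsample",
           "sample_intensity", "add_poisson_noise", "add_gaussian_noise",
           "crappify", "crappify_legacy_order", "register_crappifier",
           "get_noise_fn"]

DEFAULT_GAIN = 255.0


@dataclass(frozen=True)
class CrappifierSpec:
    """A degradation model: noise family, per-image intensity interval,
    photon gain (Poisson only) and clipping policy."""

    family: str = "poisson"
    intensity_low: float = 0.0
    intensity_high: float = 0.0
    gain: float = DEFAULT_GAIN
    clip: bool = True

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown crappifier family {self.family!r}; "
                f"registered: {sorted(_FAMILIES)}")
        if self.intensity_low < 0 or self.intensity_high < 0:
            raise ValueError("intensities must be non-negative")
        if self.intensity_low > self.intensity_high:
            raise ValueError(
                f"intensity_low {self.intensity_low} exceeds "
                f"intensity_high {self.intensity_high}")
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    @property
    def midpoint_intensity(self) -> float:
        return 0.5 * (self.intensity_low + self.intensity_high)


@dataclass(frozen=True)
class DegradationResult:
    """A degraded image plus the provenance needed to reproduce it."""

    lr_image: np.ndarray
    intensity_used: float
    rng_state_tag: str


def downsample(image: np.ndarray, scale: int) -> np.ndarray:
    """Block-average (area) downsampling by an integer factor.

    Models acquisition with ``scale``-times larger pixels.  If the image
    sides are not divisible by ``scale`` the bottom/right remainder is
    cropped (with a logged warning) so HR/LR geometry stays exact.
    """
    if not isinstance(scale, (int, np.integer)) or scale < 1:
        raise ValueError(f"scale must be a positive integer, got {scale}")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if scale == 1:
        return image.copy()
    h, w = image.shape
    rh, rw = h % scale, w % scale
    if rh or rw:
        logger.warning("cropping %dx%d remainder pixels before downsampling",
                       rh, rw)
        image = image[:h - rh or None, :w - rw or None]
        h, w = image.shape
    return image.reshape(h // scale, scale, w // scale, scale).mean(axis=(1, 3))


def sample_intensity(spec: CrappifierSpec, rng: np.random.Generator) -> float:
    """Draw one per-image noise intensity, uniform on the spec interval."""
    if spec.intensity_low == spec.intensity_high:
        return float(spec.intensity_low)
    return float(rng.uniform(spec.intensity_low, spec.intensity_high))


def add_poisson_noise(image: np.ndarray, intensity: float,
                      gain: float = DEFAULT_GAIN,
                      rng: np.random.Generator | None = None,
                      clip: bool = False) -> np.ndarray:
    """Mean-preserving shot noise whose variance grows with both the
    pixel value and the intensity (see module docstring)."""
    if intensity < 0:
        raise ValueError(f"intensity must be non-negative, got {intensity}")
    if gain <= 0:
        raise ValueError(f"gain must be positive, got {gain}")
    image = np.asarray(image, dtype=np.float64)
    if intensity == 0:
        return image.copy()
    if rng is None:
        raise ValueError("a seeded Generator is required when intensity > 0")
    lam = np.clip(image, 0.0, None) * gain / intensity
    out = rng.poisson(lam).astype(np.float64) * intensity / gain
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out


def add_gaussian_noise(image: np.ndarray, sigma: float,
                       rng: np.random.Generator | None = None,
                       clip: bool = False) -> np.ndarray:
    """Additive i.i.d. zero-mean Gaussian noise on the [0, 1] scale."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    image = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return image.copy()
    if rng is None:
        raise ValueError("a seeded Generator is required when sigma > 0")
    out = image + rng.normal(0.0, sigma, size=image.shape)
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out


# noise family registry: name -> (image, intensity, gain, rng, clip) -> image
_FAMILIES: dict[str, Callable] = {
    "poisson": lambda img, i, g, rng, clip: add_poisson_noise(img, i, g, rng, clip),
    "additive_gaussian": lambda img, i, g, rng, clip: add_gaussian_noise(img, i, rng, clip),
}


def get_noise_fn(family: str) -> Callable:
    try:
        return _FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown crappifier family {family!r}; "
                         f"registered: {sorted(_FAMILIES)}") from None


def register_crappifier(name: str, fn: Callable[[np.ndarray, float, np.random.Generator], np.ndarray],
                        check: bool = True) -> None:
    """Register a user-defined noise family.

    ``fn(image, intensity, rng) -> image``.  The zero-intensity-identity
    contract (``fn(x, 0, rng) == x``) is checked at registration.
    """
    if check:
        probe = np.linspace(0.0, 1.0, 16).reshape(4, 4)
        out = fn(probe, 0.0, np.random.default_rng(0))
        if not np.array_equal(np.asarray(out), probe):
            raise ValueError(
                f"crappifier {name!r} violates the zero-intensity-identity "
                f"contract")
    _FAMILIES[name] = lambda img, i, g, rng, clip: (
        np.clip(fn(img, i, rng), 0.0, 1.0) if clip else np.asarray(fn(img, i, rng)))


def _apply_noise(image: np.ndarray, spec: CrappifierSpec, intensity: float,
                 rng: np.random.Generator) -> np.ndarray:
    return get_noise_fn(spec.family)(image, intensity, spec.gain, rng, spec.clip)


def crappify(hr: np.ndarray, spec: CrappifierSpec, scale: int,
             rng: np.random.Generator,
             intensity: float | None = None) -> DegradationResult:
    """Degrade an HR image: downsample first, then inject noise.

    The intensity is drawn fresh from the spec interval unless given
    explicitly (validation uses the interval midpoint for stability).
    """
    tag = repr(rng.bit_generator.state.get("state", ""))
    if intensity is None:
        intensity = sample_intensity(spec, rng)
    lr = downsample(np.asarray(hr, dtype=np.float64), scale)
    lr = _apply_noise(lr, spec, intensity, rng)
    return DegradationResult(lr_image=lr, intensity_used=intensity,
                             rng_state_tag=tag)


def crappify_legacy_order(hr: np.ndarray, spec: CrappifierSpec, scale: int,
                          rng: np.random.Generator,
                          intensity: float | None = None) -> DegradationResult:
    """The older noise-then-downsample order, kept for comparison: the
    downsampling average suppresses the injected noise variance."""
    tag = repr(rng.bit_generator.state.get("state", ""))
    if intensity is None:
        intensity = sample_intensity(spec, rng)
    noisy = _apply_noise(np.asarray(hr, dtype=np.float64), spec, intensity, rng)
    lr = downsample(noisy, scale)
    if spec.clip:
        lr = np.clip(lr, 0.0, 1.0)
    return DegradationResult(lr_image=lr, intensity_used=intensity,
                             rng_state_tag=tag)
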