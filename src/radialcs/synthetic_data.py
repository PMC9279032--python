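"""Ground-truth phantoms and additive noise families.

Every downstream stage (k-space simulation, patch grouping, the ADMM
reconstruction) is exercised on images produced here, so real MR data are
never required.  Phantoms are piecewise-smooth 2-D images on the 8-bit
intensity scale [0, 255].  Noise is always applied in the image domain as
``y = x + n`` and the result is deliberately *not* clipped back to
[0, 255]: clipping would corrupt the additive model the solver assumes,
so it is deferred to display/export time.

Four noise families are supported:

``gaussian``
    i.i.d. zero-mean Gaussian with standard deviation ``sigma``.
``rayleigh``
    Rayleigh-distributed noise with scale ``sigma``, mean-centred by
    subtracting ``sigma * sqrt(pi / 2)`` so that ``E[y] = x``.
``nonuniform_gaussian``
    Zero-mean Gaussian whose standard deviation varies per pixel; each
    pixel's sigma is drawn once from ``Uniform(sigma_range)``.
``salt_pepper``
    A fraction ``density`` of pixels replaced by 0 or 255 with equal
    probability.
"""

from __future__ import annotations

import enum
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, default_rng
from skimage.data import shepp_logan_phantom
from skimage.transform import resize

__all__ = [
    "PhantomKind",
    "PhantomSpec",
    "NoiseFamily",
    "NoiseModel",
    "make_phantom",
    "add_noise",
    "child_rng",
]

#: Smallest phantom side length for which the generators are defined.
MIN_SIDE = 32


def child_rng(seed: int, role: str) -> Generator:
    """Derive an independent, reproducible generator for one use of a seed.

    A single top-level seed governs phantom synthesis, noise, mask
    rotation and probe vectors.  Each consumer names its *role* (e.g.
    ``"noise"``); the (seed, crc32(role)) pair feeds a ``SeedSequence`` so
    streams for different roles never collide yet remain bit-reproducible.
    """
    return default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(role.encode("utf-8"))])


class PhantomKind(str, enum.Enum):
    SHEPP_LOGAN = "shepp_logan"
    PIECEWISE_TEXTURE = "piecewise_texture"


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a deterministic test phantom.

    The same ``(kind, side_length, seed)`` always reproduces the identical
    image bit-for-bit.
    """

    side_length: int
    kind: PhantomKind = PhantomKind.SHEPP_LOGAN
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", PhantomKind(self.kind))
        if self.side_length < MIN_SIDE:
            raise ValueError(
                f"side_length must be >= {MIN_SIDE}, got {self.side_length}"
            )


class NoiseFamily(str, enum.Enum):
    GAUSSIAN = "gaussian"
    RAYLEIGH = "rayleigh"
    NONUNIFORM_GAUSSIAN = "nonuniform_gaussian"
    SALT_PEPPER = "salt_pepper"


@dataclass(frozen=True)
class NoiseModel:
    """Parameters of one additive noise realization.

    ``sigma`` is the Gaussian standard deviation or the Rayleigh scale;
    ``sigma_range`` bounds the per-pixel sigma of nonuniform Gaussian
    noise; ``density`` is the corrupted-pixel fraction for salt-and-pepper.
    """

    family: NoiseFamily = NoiseFamily.GAUSSIAN
    sigma: float = 20.0
    sigma_range: tuple[float, float] = (1.0, 100.0)
    density: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", NoiseFamily(self.family))
        if self.family in (NoiseFamily.GAUSSIAN, NoiseFamily.RAYLEIGH):
            if not self.sigma > 0:
                raise ValueError(f"{self.family.value} noise requires sigma > 0")
        if self.family is NoiseFamily.NONUNIFORM_GAUSSIAN:
            lo, hi = self.sigma_range
            if not (0 <= lo < hi):
                raise ValueError(f"sigma_range must satisfy 0 <= lo < hi, got {self.sigma_range}")
        if self.family is NoiseFamily.SALT_PEPPER:
            if not 0 <= self.density <= 1:
                raise ValueError(f"density must lie in [0, 1], got {self.density}")

    @property
    def variance(self) -> float:
        """Nominal per-pixel noise variance, used by the adaptive grouping rule."""
        if self.family is NoiseFamily.GAUSSIAN:
            return self.sigma**2
        if self.family is NoiseFamily.RAYLEIGH:
            return (2 - math.pi / 2) * self.sigma**2
        if self.family is NoiseFamily.NONUNIFORM_GAUSSIAN:
            lo, hi = self.sigma_range
            # E[sigma_ij^2] for sigma_ij ~ Uniform(lo, hi)
            return (lo * lo + lo * hi + hi * hi) / 3.0
        # salt-and-pepper: variance of the replaced-pixel process at mid grey
        return self.density * 127.5**2


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate a piecewise-smooth phantom on [0, 255].

    ``shepp_logan`` is the standard 10-ellipse head phantom rescaled to the
    requested side length; ``piecewise_texture`` is a seeded arrangement of
    constant-intensity ellipses plus one oscillatory (sinusoidal) texture
    band, so that texture-area behaviour of the reconstruction can be
    exercised.
    """
    n = spec.side_length
    if spec.kind is PhantomKind.SHEPP_LOGAN:
        base = shepp_logan_phantom()  # 400 x 400 in [0, 1]
        img = resize(base, (n, n), order=1, anti_aliasing=True)
        img = img * 255.0
    else:
        img = _piecewise_texture(n, spec.seed)
    return np.clip(img, 0.0, 255.0)


def _piecewise_texture(n: int, seed: int) -> np.ndarray:
    rng = child_rng(seed, "phantom")
    img = np.full((n, n), 30.0)
    yy, xx = np.mgrid[0:n, 0:n].astype(float) / n
    # overlapping constant ellipses give >= 3 distinct intensity regions
    for _ in range(6):
        cy, cx = rng.uniform(0.15, 0.85, size=2)
        ay, ax = rng.uniform(0.08, 0.35, size=2)
        level = rng.uniform(60.0, 230.0)
        inside = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        img[inside] = level
    # one oscillatory texture band in the lower-right quadrant
    band = (yy > 0.55) & (yy < 0.9) & (xx > 0.55) & (xx < 0.9)
    freq = rng.uniform(6.0, 10.0)
    texture = 40.0 * np.sin(2 * np.pi * freq * xx) * np.sin(2 * np.pi * freq * yy)
    img[band] = np.clip(img[band] + texture[band], 0.0, 255.0)
    return img


def _nonuniform_sigmas(shape: tuple[int, int], sigma_range: tuple[float, float],
                       rng: Generator) -> np.ndarray:
    """Per-pixel standard deviations for nonuniform Gaussian noise."""
    lo, hi = sigma_range
    return rng.uniform(lo, hi, size=shape)


def add_noise(img: np.ndarray, model: NoiseModel) -> np.ndarray:
    """Apply one noise realization to an image per ``y = x + n``.

    The input must lie on [0, 255]; the output is not clipped.
    The realization is a pure function of ``model.seed``.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("input intensities must lie in [0, 255]")
    rng = child_rng(model.seed, "noise")
    fam = model.family
    if fam is NoiseFamily.GAUSSIAN:
        return img + rng.normal(0.0, model.sigma, size=img.shape)
    if fam is NoiseFamily.RAYLEIGH:
        n = rng.rayleigh(model.sigma, size=img.shape)
        return img + (n - model.sigma * math.sqrt(math.pi / 2))
    if fam is NoiseFamily.NONUNIFORM_GAUSSIAN:
        sigmas = _nonuniform_sigmas(img.shape, model.sigma_range, rng)
        return img + rng.normal(0.0, 1.0, size=img.shape) * sigmas
    # salt and pepper
    out = img.copy()
    corrupted = rng.random(img.shape) < model.density
    salt = rng.random(img.shape) < 0.5
    out[corrupted & salt] = 255.0
    out[corrupted & ~salt] = 0.0
    return out
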