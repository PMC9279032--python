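"""Pseudo-radial k-space sampling and the measurement operator.

The measurement operator is the partial Fourier transform
``Phi = M o F`` where ``F`` is the unitary 2-D DFT (DC at the array
centre) and ``M`` a boolean sampling mask.  Radial acquisition is
emulated by rasterizing equispaced diameters through the k-space centre
onto the Cartesian grid; the true non-Cartesian trajectory would require
gridding interpolation, which the reconstruction itself never needs —
only the set of sampled Cartesian locations matters to the solver.

Unitary normalization makes ``Phi`` a partial isometry
(``Phi^T Phi`` has eigenvalues in {0, 1}), so penalty-parameter scales
transfer unchanged across image sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synthetic_data import child_rng

__all__ = [
    "GradientSetting",
    "SamplingMask",
    "KSpaceObservation",
    "gradient_magnitude_angle",
    "full_spoke_count",
    "make_radial_mask",
    "encode",
    "adjoint",
]

#: Requested-vs-achieved sensing-rate tolerance of the mask generator.
RATE_TOL = 0.02


@dataclass(frozen=True)
class GradientSetting:
    """Readout gradient components (arbitrary units) of one radial spoke."""

    gx: float
    gy: float

    def __post_init__(self) -> None:
        if self.gx == 0 and self.gy == 0:
            raise ValueError("gradient vector must not be zero")


def gradient_magnitude_angle(g: GradientSetting) -> tuple[float, float]:
    """Total gradient magnitude and spoke angle (radians, quadrant-resolved)."""
    return math.hypot(g.gx, g.gy), math.atan2(g.gy, g.gx)


def full_spoke_count(n: int) -> int:
    """Number of spokes needed to satisfy Nyquist spacing on an n x n grid.

    With ``round(pi * n / 2)`` diameters the maximum gap between adjacent
    spokes at the grid edge stays below one k-space step; this serves as
    the full-sampling reference.  Rounding is half away from zero (the
    value ``pi*n/2`` is never exactly half-integral in floating point).
    """
    if n < 2:
        raise ValueError(f"grid side must be >= 2, got {n}")
    return int(math.floor(math.pi * n / 2 + 0.5))


@dataclass(frozen=True)
class SamplingMask:
    """Boolean k-space sampling pattern (True = sampled), DC-centred layout.

    ``sensing_rate`` is the *achieved* fraction of sampled positions and
    always matches ``mask.mean()`` exactly.
    """

    mask: np.ndarray
    sensing_rate: float
    n_spokes: int
    seed: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if abs(self.sensing_rate - m.mean()) > 1e-12:
            raise ValueError("sensing_rate does not match the mask")


@dataclass(frozen=True)
class KSpaceObservation:
    """Sampled k-space data ``y`` (zeros at unsampled positions) plus its mask."""

    data: np.ndarray
    mask: SamplingMask

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=complex)
        object.__setattr__(self, "data", data)
        if data.shape != self.mask.shape:
            raise ValueError(
                f"data shape {data.shape} does not match mask shape {self.mask.shape}"
            )
        if np.any(data[~self.mask.mask] != 0):
            raise ValueError("k-space data must be zero at unsampled positions")


def _rasterize_spokes(n: int, n_spokes: int, seed: int) -> np.ndarray:
    """Union of ``n_spokes`` equispaced diameters, nearest-pixel rasterized.

    A seed-controlled global angular offset avoids privileging the pixel
    axes; the DC position is always included.
    """
    mask = np.zeros((n, n), dtype=bool)
    c = n // 2  # DC position of the centred FFT layout
    offset = child_rng(seed, "mask-angle").uniform(0.0, math.pi)
    t = np.arange(-n, n + 0.5, 0.5)  # fine parametric sampling of a diameter
    for k in range(n_spokes):
        theta = offset + math.pi * k / n_spokes
        rows = np.rint(c + t * math.sin(theta)).astype(int)
        cols = np.rint(c + t * math.cos(theta)).astype(int)
        ok = (rows >= 0) & (rows < n) & (cols >= 0) & (cols < n)
        mask[rows[ok], cols[ok]] = True
    mask[c, c] = True
    # enforce exact DFT conjugate symmetry (index i <-> (n - i) mod n):
    # geometric reflection about the centre pixel misses the wrap of the
    # boundary row/column, and a real image needs a symmetric sampled set
    # for Phi^T Phi to be an exact projector
    mask |= np.roll(mask[::-1, ::-1], (1, 1), axis=(0, 1))
    return mask


def make_radial_mask(
    shape: tuple[int, int],
    sensing_rate: float | None = None,
    n_spokes: int | None = None,
    seed: int = 0,
) -> SamplingMask:
    """Pseudo-radial sampling mask at a requested rate or spoke count.

    Exactly one of ``sensing_rate`` / ``n_spokes`` must be given.  When a
    rate is requested, the spoke count is found by bisection so that the
    achieved rate is within 0.02 of the request; ``sensing_rate=1.0``
    returns the all-True mask.
    """
    rows, cols = shape
    if rows != cols:
        raise ValueError(f"mask must be square, got {shape}")
    n = rows
    if (sensing_rate is None) == (n_spokes is None):
        raise ValueError("give exactly one of sensing_rate or n_spokes")

    if n_spokes is not None:
        if n_spokes < 1:
            raise ValueError("n_spokes must be positive")
        m = _rasterize_spokes(n, n_spokes, seed)
        return SamplingMask(m, float(m.mean()), n_spokes, seed)

    if not 0 < sensing_rate <= 1:
        raise ValueError(f"sensing_rate must lie in (0, 1], got {sensing_rate}")
    if sensing_rate == 1.0:
        m = np.ones((n, n), dtype=bool)
        return SamplingMask(m, 1.0, full_spoke_count(n), seed)

    rate_of = lambda s: _rasterize_spokes(n, s, seed).mean()
    lo, lo_rate = 1, rate_of(1)
    if sensing_rate < lo_rate - RATE_TOL:
        raise ValueError(
            f"sensing_rate {sensing_rate} unreachable: one spoke already covers "
            f"{lo_rate:.4f} of k-space (achievable range [{lo_rate:.4f}, 1])"
        )
    hi = 4 * full_spoke_count(n)
    hi_rate = rate_of(hi)
    if sensing_rate > hi_rate + RATE_TOL:
        raise ValueError(
            f"sensing_rate {sensing_rate} unreachable: spokes saturate at "
            f"{hi_rate:.4f} (achievable range [{lo_rate:.4f}, {hi_rate:.4f}]; "
            "use sensing_rate=1.0 for full sampling)"
        )
    # sensing rate is nondecreasing in the spoke count -> bisection
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if rate_of(mid) < sensing_rate:
            lo = mid
        else:
            hi = mid
    best = min((lo, hi), key=lambda s: abs(rate_of(s) - sensing_rate))
    m = _rasterize_spokes(n, best, seed)
    achieved = float(m.mean())
    if abs(achieved - sensing_rate) > RATE_TOL:
        raise ValueError(
            f"could not match sensing_rate {sensing_rate} within {RATE_TOL}: "
            f"closest achievable is {achieved:.4f} with {best} spokes"
        )
    return SamplingMask(m, achieved, best, seed)


def _fft2c(img: np.ndarray) -> np.ndarray:
    """Unitary 2-D FFT with DC at the array centre."""
    return np.fft.fftshift(np.fft.fft2(img, norm="ortho"))


def _ifft2c(ksp: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(np.fft.ifftshift(ksp), norm="ortho")


def encode(img: np.ndarray, mask: SamplingMask) -> KSpaceObservation:
    """Apply the measurement operator: ``y = M o F(x)``."""
    img = np.asarray(img, dtype=float)
    if img.shape != mask.shape:
        raise ValueError(f"image shape {img.shape} does not match mask {mask.shape}")
    data = _fft2c(img)
    data[~mask.mask] = 0
    return KSpaceObservation(data, mask)


def adjoint(obs: KSpaceObservation) -> np.ndarray:
    """Adjoint operator ``Phi^T y``: the zero-filled reconstruction.

    Returns the real part of the inverse unitary transform of the masked
    data; with a full mask this inverts :func:`encode` to machine
    precision.
    """
    return np.real(_ifft2c(np.asarray(obs.data)))
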