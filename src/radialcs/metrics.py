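"""Image-quality indexes: MSE, PSNR and global SSIM.

PSNR assumes an 8-bit peak of 255 and is reported in dB:
``10 log10(255^2 / MSE)`` with MSE in mean form, so the two indexes obey
the exact inverse identity ``MSE = 255^2 * 10^(-PSNR/10)``.  SSIM is the
global (whole-image) universal-quality-index form

    4 u_x u_y sigma_xy / ((u_x^2 + u_y^2)(sigma_x^2 + sigma_y^2)),

computed from whole-image moments rather than a sliding window; tiny
stabilizers (1e-8) are added to each denominator factor to avoid 0/0 on
degenerate inputs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["QualityReport", "mse", "psnr", "ssim", "evaluate"]

PEAK = 255.0
_STABILIZER = 1e-8


@dataclass(frozen=True)
class QualityReport:
    mse: float
    psnr_db: float
    ssim: float

    def to_dict(self) -> dict:
        return asdict(self)


def _pair(x, xhat):
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    return x, xhat


def mse(x: np.ndarray, xhat: np.ndarray, sum_form: bool = False) -> float:
    """Mean squared error; ``sum_form=True`` returns the raw squared sum."""
    x, xhat = _pair(x, xhat)
    sq = (x - xhat) ** 2
    return float(sq.sum()) if sum_form else float(sq.mean())


def psnr(x: np.ndarray, xhat: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB (+inf for identical images)."""
    err = mse(x, xhat)
    if err == 0:
        return math.inf
    return 10.0 * math.log10(PEAK**2 / err)


def ssim(x: np.ndarray, xhat: np.ndarray) -> float:
    """Global structural-similarity index (<= 1, 1 iff identical up to
    the negligible stabilizers)."""
    x, xhat = _pair(x, xhat)
    ux, uy = x.mean(), xhat.mean()
    vx, vy = x.var(), xhat.var()
    cov = float(((x - ux) * (xhat - uy)).mean())
    num = 4.0 * ux * uy * cov
    den = (ux**2 + uy**2 + _STABILIZER) * (vx + vy + _STABILIZER)
    return float(num / den)


def evaluate(x: np.ndarray, xhat: np.ndarray) -> QualityReport:
    """All three indexes for one (reference, reconstruction) pair."""
    return QualityReport(mse=mse(x, xhat), psnr_db=psnr(x, xhat), ssim=ssim(x, xhat))
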