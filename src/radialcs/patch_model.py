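"""Nonlocal similar-patch groups for low-rank regularization.

For each anchor patch on a regular grid, the patches inside a ``W x W``
search window are ranked by squared Euclidean distance to the anchor and
the closest ones are stacked column-wise into a group matrix ``L_i`` of
shape ``(f^2, S_i)``.  Groups of mutually similar patches are
approximately low-rank, which is what the LogDet shrinkage of the solver
exploits.

The group size ``S_i`` is adaptive: the number of candidates whose
distance does not exceed ``c * f^2 * sigma^2`` (so the threshold tracks
the expected distance between two noisy copies of the same patch),
clipped to the bounds ``[s_min, s_max] = [10, 60]``.  Patch size and
window size follow the noise level: ``f = 7, W = 21`` below noise
variance 30 and ``f = 9, W = 31`` at or above it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "GroupingParams",
    "PatchGroup",
    "params_for_noise",
    "build_groups",
    "extract_groups",
    "aggregate",
]

_ALLOWED_PATCH_SIZES = (6, 7, 8, 9)


@dataclass(frozen=True)
class GroupingParams:
    """Patch-grouping configuration.

    ``stride`` defaults to ``patch_size - 1`` (anchors overlap by one
    pixel), which keeps full coverage while bounding the number of groups;
    ``noise_variance`` is the per-pixel noise variance on the scale of the
    image handed to :func:`build_groups`.
    """

    patch_size: int = 8
    window_size: int = 25
    s_min: int = 10
    s_max: int = 60
    stride: int | None = None
    similarity_tolerance: float = 3.0
    noise_variance: float = 0.0

    def __post_init__(self) -> None:
        if self.patch_size not in _ALLOWED_PATCH_SIZES:
            raise ValueError(f"patch_size must be one of {_ALLOWED_PATCH_SIZES}")
        if self.window_size % 2 == 0 or self.window_size <= self.patch_size:
            raise ValueError("window_size must be odd and larger than patch_size")
        if not 10 <= self.s_min <= self.s_max <= 60:
            raise ValueError("group-size bounds must satisfy 10 <= s_min <= s_max <= 60")
        if self.stride is None:
            object.__setattr__(self, "stride", self.patch_size - 1)
        if self.stride < 1:
            raise ValueError("stride must be positive")
        if self.similarity_tolerance < 0:
            raise ValueError("similarity_tolerance must be >= 0")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")


@dataclass
class PatchGroup:
    """One group of vectorized mutually similar patches.

    ``matrix`` has shape ``(f^2, s_i)``; the first column is always the
    anchor patch itself.  ``member_coords`` holds the top-left (row, col)
    of every member, anchor first.
    """

    matrix: np.ndarray
    anchor: tuple[int, int]
    member_coords: np.ndarray  # (s_i, 2) int
    s_i: int


def params_for_noise(noise_variance: float) -> GroupingParams:
    """Patch and window sizes adapted to the noise level.

    Below variance 30 small patches suffice (f=7, W=21); at or above 30
    larger patches stabilise the distance ranking (f=9, W=31).
    """
    if noise_variance < 0:
        raise ValueError(f"noise variance must be >= 0, got {noise_variance}")
    if noise_variance < 30:
        return GroupingParams(patch_size=7, window_size=21,
                              noise_variance=noise_variance)
    return GroupingParams(patch_size=9, window_size=31,
                          noise_variance=noise_variance)


def _anchor_positions(extent: int, stride: int) -> np.ndarray:
    """Regular anchor grid, forcing the last valid position for coverage."""
    pos = list(range(0, extent + 1, stride))
    if pos[-1] != extent:
        pos.append(extent)
    return np.asarray(pos, dtype=int)


def build_groups(img: np.ndarray, params: GroupingParams,
                 _chunk: int = 256) -> list[PatchGroup]:
    """Group similar patches around every anchor of a regular grid.

    Candidates are ranked by squared Euclidean distance to the anchor
    patch; ties are broken by raster order of the candidate position.
    The anchor is always the first member regardless of ties.
    """
    img = np.asarray(img, dtype=float)
    f, W = params.patch_size, params.window_size
    H, Wimg = img.shape
    if H <= W or Wimg <= W:
        raise ValueError(
            f"image of shape {img.shape} must be larger than the {W}x{W} search window"
        )
    nr, nc = H - f + 1, Wimg - f + 1
    patches = sliding_window_view(img, (f, f)).reshape(nr, nc, f * f)

    ar = _anchor_positions(H - f, params.stride)
    ac = _anchor_positions(Wimg - f, params.stride)
    anchors = np.stack(np.meshgrid(ar, ac, indexing="ij"), axis=-1).reshape(-1, 2)

    h = (W - f) // 2
    offs = np.arange(-h, h + 1)
    # candidate offsets enumerated row-major == raster order inside the window
    d_off = np.stack(np.meshgrid(offs, offs, indexing="ij"), axis=-1).reshape(-1, 2)
    threshold = params.similarity_tolerance * f * f * params.noise_variance

    groups: list[PatchGroup] = []
    for start in range(0, len(anchors), _chunk):
        a = anchors[start:start + _chunk]  # (A, 2)
        cand = a[:, None, :] + d_off[None, :, :]  # (A, C, 2)
        valid = (
            (cand[..., 0] >= 0) & (cand[..., 0] < nr)
            & (cand[..., 1] >= 0) & (cand[..., 1] < nc)
        )
        cr = np.clip(cand[..., 0], 0, nr - 1)
        cc = np.clip(cand[..., 1], 0, nc - 1)
        diff = patches[cr, cc] - patches[a[:, 0], a[:, 1]][:, None, :]
        dist = np.einsum("acp,acp->ac", diff, diff)
        dist[~valid] = np.inf
        is_anchor = (cand[..., 0] == a[:, None, 0]) & (cand[..., 1] == a[:, None, 1])
        dist[is_anchor] = -1.0  # anchor sorts first unconditionally
        order = np.argsort(dist, axis=1, kind="stable")  # ties: raster order
        n_valid = valid.sum(axis=1)
        n_close = (dist <= threshold).sum(axis=1)
        s = np.clip(n_close, params.s_min, params.s_max)
        s = np.minimum(s, n_valid)
        for j in range(len(a)):
            sel = order[j, : s[j]]
            coords = np.column_stack((cr[j, sel], cc[j, sel]))
            groups.append(
                PatchGroup(
                    matrix=patches[coords[:, 0], coords[:, 1]].T.copy(),
                    anchor=(int(a[j, 0]), int(a[j, 1])),
                    member_coords=coords,
                    s_i=int(s[j]),
                )
            )
    return groups


def extract_groups(img: np.ndarray, groups: list[PatchGroup]) -> list[PatchGroup]:
    """Re-extract the group matrices ``R_i x`` from ``img`` at fixed coordinates.

    Used by the solver to refresh groups from the current iterate without
    repeating the similarity search.
    """
    img = np.asarray(img, dtype=float)
    if not groups:
        return []
    f = int(round(np.sqrt(groups[0].matrix.shape[0])))
    nr, nc = img.shape[0] - f + 1, img.shape[1] - f + 1
    patches = sliding_window_view(img, (f, f)).reshape(nr, nc, f * f)
    out = []
    for g in groups:
        mats = patches[g.member_coords[:, 0], g.member_coords[:, 1]].T.copy()
        out.append(replace_matrix(g, mats))
    return out


def replace_matrix(group: PatchGroup, matrix: np.ndarray) -> PatchGroup:
    return PatchGroup(matrix=matrix, anchor=group.anchor,
                      member_coords=group.member_coords, s_i=group.s_i)


def aggregate(groups: list[PatchGroup],
              shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Scatter group columns back to the image: per-pixel uniform average.

    Returns ``(average, coverage)`` where ``coverage`` counts how many
    member patches contain each pixel.  Raises if any pixel is uncovered.
    This is the (normalized) transpose ``sum_i R_i^T L_i`` of the patch
    extraction used in the solver's image update.
    """
    if not groups:
        raise ValueError("no groups to aggregate")
    f2 = groups[0].matrix.shape[0]
    f = int(round(np.sqrt(f2)))
    H, Wimg = shape
    nr, nc = H - f + 1, Wimg - f + 1
    coords = np.concatenate([g.member_coords for g in groups])
    vals = np.concatenate([g.matrix.T for g in groups])  # (total, f^2)
    flat = coords[:, 0] * nc + coords[:, 1]
    acc_p = np.zeros((nr * nc, f2))
    np.add.at(acc_p, flat, vals)
    cnt_p = np.bincount(flat, minlength=nr * nc).astype(float)
    acc = np.zeros(shape)
    cov = np.zeros(shape)
    acc_p = acc_p.reshape(nr, nc, f, f)
    cnt_p = cnt_p.reshape(nr, nc)
    for di in range(f):
        for dj in range(f):
            acc[di:di + nr, dj:dj + nc] += acc_p[:, :, di, dj]
            cov[di:di + nr, dj:dj + nc] += cnt_p
    uncovered = np.argwhere(cov == 0)
    if len(uncovered):
        raise ValueError(
            f"{len(uncovered)} pixels not covered by any patch, e.g. "
            f"{[tuple(c) for c in uncovered[:5]]}"
        )
    return acc / cov, cov
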