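"""Gray-level texture matrices, computed in-plane and merged across slices.

All five families (GLCM, GLRLM, GLSZM, GLDM, NGTDM) use 2D neighbourhoods
within axial slices only; raw counts are accumulated over slices (and, for
GLCM/GLRLM, over the 4 in-plane directions) before normalization, which
makes the derived features invariant to in-plane 90-degree rotations and
axis flips.

Conventions. Levels are integers 1..Ng inside the mask, 0 outside (0 breaks
runs/zones/neighbourhoods). GLCM: distance 1, 4 angles, symmetric. GLRLM:
rows indexed by level, columns by run length. GLSZM: zones are 8-connected
in-plane. GLDM: dependence at Chebyshev distance 1 with gray-level
tolerance alpha; the dependence index j counts the centre voxel plus its
dependent neighbours (j = 1..9). NGTDM: matrix columns are the level count
n_i, probability p_i and summed absolute deviation s_i from the mean of the
8-neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import DiscretizedImage

__all__ = ["TextureMatrix", "build_texture_matrix", "FAMILIES"]

FAMILIES = ("glcm", "glrlm", "glszm", "gldm", "ngtdm")

_OFFSETS_4 = ((0, 1), (1, 0), (1, 1), (1, -1))  # unique in-plane directions
_OFFSETS_8 = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass
class TextureMatrix:
    family: str
    matrix: np.ndarray  # raw counts; rows = gray level 1..Ng
    n_levels: int
    n_voxels: int  # masked voxels contributing
    extras: dict = field(default_factory=dict)


def _runs_1d(arr: np.ndarray, out: np.ndarray) -> None:
    """Accumulate runs of equal positive values of ``arr`` into ``out[level-1, len-1]``."""
    n = arr.size
    if n == 0:
        return
    change = np.nonzero(np.diff(arr) != 0)[0]
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))
    vals = arr[starts]
    keep = vals > 0
    if not keep.any():
        return
    lengths = (ends - starts + 1)[keep]
    np.add.at(out, (vals[keep] - 1, lengths - 1), 1)


def _shear(sl: np.ndarray, anti: bool) -> np.ndarray:
    """Place (anti-)diagonals of ``sl`` into columns of a zero-padded array."""
    nr, nc = sl.shape
    out = np.zeros((nr, nc + nr - 1), dtype=sl.dtype)
    for i in range(nr):
        off = i if anti else (nr - 1 - i)
        out[i, off : off + nc] = sl[i]
    return out


def _glcm(d: DiscretizedImage) -> np.ndarray:
    ng = d.n_levels
    C = np.zeros((ng, ng), dtype=np.int64)
    lev = d.levels
    for k in range(lev.shape[2]):
        sl = lev[:, :, k]
        for dr, dc in _OFFSETS_4:
            r0, r1 = max(dr, 0), sl.shape[0] + min(dr, 0)
            c0, c1 = max(dc, 0), sl.shape[1] + min(dc, 0)
            a = sl[r0:r1, c0:c1]
            b = sl[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
            ok = (a > 0) & (b > 0)
            if ok.any():
                np.add.at(C, (a[ok] - 1, b[ok] - 1), 1)
    return (C + C.T)  # symmetric co-occurrence


def _glrlm(d: DiscretizedImage) -> np.ndarray:
    lev = d.levels
    nr, nc = lev.shape[:2]
    R = np.zeros((d.n_levels, max(nr, nc)), dtype=np.int64)
    for k in range(lev.shape[2]):
        sl = lev[:, :, k]
        # horizontal: zero column separates rows
        _runs_1d(np.hstack([sl, np.zeros((nr, 1), dtype=sl.dtype)]).ravel(), R)
        # vertical
        _runs_1d(np.hstack([sl.T, np.zeros((nc, 1), dtype=sl.dtype)]).ravel(), R)
        # diagonals via shear: columns of the sheared array are diagonals
        for anti in (False, True):
            sh = _shear(sl, anti).T
            _runs_1d(
                np.hstack([sh, np.zeros((sh.shape[0], 1), dtype=sl.dtype)]).ravel(), R
            )
    # trim trailing all-zero run-length columns
    used = np.nonzero(R.sum(axis=0))[0]
    return R[:, : used[-1] + 1] if used.size else R[:, :1]


def _glszm(d: DiscretizedImage) -> np.ndarray:
    lev = d.levels
    counts: dict[tuple[int, int], int] = {}
    max_size = 1
    for k in range(lev.shape[2]):
        sl = lev[:, :, k]
        for g in np.unique(sl[sl > 0]):
            lab, n = ndimage.label(sl == g, structure=_STRUCT_8)
            if n == 0:
                continue
            sizes = np.bincount(lab.ravel())[1:]
            for s in sizes:
                counts[(int(g), int(s))] = counts.get((int(g), int(s)), 0) + 1
                max_size = max(max_size, int(s))
    Z = np.zeros((d.n_levels, max_size), dtype=np.int64)
    for (g, s), c in counts.items():
        Z[g - 1, s - 1] = c
    return Z


def _gldm(d: DiscretizedImage, alpha: int = 0) -> np.ndarray:
    lev = d.levels
    ng = d.n_levels
    D = np.zeros((ng, 9), dtype=np.int64)  # dependence j = 1..9 (centre + <=8)
    for k in range(lev.shape[2]):
        sl = lev[:, :, k]
        inm = sl > 0
        dep = np.zeros(sl.shape, dtype=np.int64)
        for dr, dc in _OFFSETS_8:
            r0, r1 = max(dr, 0), sl.shape[0] + min(dr, 0)
            c0, c1 = max(dc, 0), sl.shape[1] + min(dc, 0)
            a = sl[r0:r1, c0:c1]
            b = sl[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
            dep[r0:r1, c0:c1] += ((b > 0) & (np.abs(a - b) <= alpha)).astype(np.int64)
        ok = inm
        np.add.at(D, (sl[ok] - 1, dep[ok]), 1)
    return D


def _ngtdm(d: DiscretizedImage) -> tuple[np.ndarray, np.ndarray]:
    """Return (n_i, s_i) over levels; voxels with no in-mask neighbour excluded."""
    lev = d.levels
    ng = d.n_levels
    n_i = np.zeros(ng, dtype=np.int64)
    s_i = np.zeros(ng, dtype=float)
    for k in range(lev.shape[2]):
        sl = lev[:, :, k].astype(float)
        inm = sl > 0
        nsum = np.zeros(sl.shape)
        ncnt = np.zeros(sl.shape)
        for dr, dc in _OFFSETS_8:
            r0, r1 = max(dr, 0), sl.shape[0] + min(dr, 0)
            c0, c1 = max(dc, 0), sl.shape[1] + min(dc, 0)
            b = sl[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
            nsum[r0:r1, c0:c1] += np.where(b > 0, b, 0.0)
            ncnt[r0:r1, c0:c1] += (b > 0).astype(float)
        ok = inm & (ncnt > 0)
        if not ok.any():
            continue
        dev = np.abs(sl[ok] - nsum[ok] / ncnt[ok])
        g = lev[:, :, k][ok]
        np.add.at(n_i, g - 1, 1)
        np.add.at(s_i, g - 1, dev)
    return n_i, s_i


def build_texture_matrix(
    d: DiscretizedImage, family: str, alpha: int = 0
) -> TextureMatrix:
    """Build the requested family's matrix from a discretized image."""
    if family not in FAMILIES:
        raise ValueError(f"unknown texture family {family!r}")
    n_vox = int(np.count_nonzero(d.levels))
    if n_vox == 0:
        raise ValueError("empty mask: no discretized voxels")
    if family == "glcm":
        M = _glcm(d)
    elif family == "glrlm":
        M = _glrlm(d)
    elif family == "glszm":
        M = _glszm(d)
    elif family == "gldm":
        M = _gldm(d, alpha=alpha)
    else:  # ngtdm
        n_i, s_i = _ngtdm(d)
        return TextureMatrix(
            "ngtdm",
            np.column_stack([n_i.astype(float), s_i]),
            d.n_levels,
            n_vox,
            extras={"n_i": n_i, "s_i": s_i},
        )
    return TextureMatrix(family, M.astype(float), d.n_levels, n_vox)
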