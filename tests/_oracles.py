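"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plain nested loops over voxels, independent of
the vectorized code under test.
"""

from __future__ import annotations

import numpy as np

OFFSETS_4 = ((0, 1), (1, 0), (1, 1), (1, -1))
OFFSETS_8 = tuple((dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0))


def opening_2d_bruteforce(mask2d: np.ndarray) -> np.ndarray:
    """Erosion then dilation with a full 3x3 structuring element, by enumeration."""
    m = mask2d.astype(bool)
    nr, nc = m.shape
    er = np.zeros_like(m)
    for i in range(nr):
        for j in range(nc):
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < nr and 0 <= jj < nc and m[ii, jj]):
                        ok = False
            er[i, j] = ok
    di_ = np.zeros_like(m)
    for i in range(nr):
        for j in range(nc):
            hit = False
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nr and 0 <= jj < nc and er[ii, jj]:
                        hit = True
            di_[i, j] = hit
    return di_


def glcm_bruteforce(lev: np.ndarray, ng: int) -> np.ndarray:
    """Symmetric in-plane GLCM, distance 1, 4 angles, summed over slices."""
    C = np.zeros((ng, ng), dtype=np.int64)
    nr, nc, ns = lev.shape
    for k in range(ns):
        for i in range(nr):
            for j in range(nc):
                a = lev[i, j, k]
                if a == 0:
                    continue
                for dr, dc in OFFSETS_4:
                    ii, jj = i + dr, j + dc
                    if 0 <= ii < nr and 0 <= jj < nc:
                        b = lev[ii, jj, k]
                        if b > 0:
                            C[a - 1, b - 1] += 1
                            C[b - 1, a - 1] += 1
    return C


def glrlm_bruteforce(lev: np.ndarray, ng: int) -> np.ndarray:
    """Run lengths over 4 in-plane directions, summed over slices."""
    nr, nc, ns = lev.shape
    R = np.zeros((ng, max(nr, nc)), dtype=np.int64)

    def scan(line):
        i = 0
        while i < len(line):
            v = line[i]
            if v == 0:
                i += 1
                continue
            j = i
            while j < len(line) and line[j] == v:
                j += 1
            R[v - 1, (j - i) - 1] += 1
            i = j

    for k in range(ns):
        sl = lev[:, :, k]
        for i in range(nr):
            scan(list(sl[i, :]))
        for j in range(nc):
            scan(list(sl[:, j]))
        for off in range(-nr + 1, nc):
            scan(list(np.diagonal(sl, off)))
            scan(list(np.diagonal(sl[::-1, :], off)))
    return R


def glszm_bruteforce(lev: np.ndarray, ng: int) -> dict[tuple[int, int], int]:
    """8-connected in-plane zones; returns {(level, size): count}."""
    nr, nc, ns = lev.shape
    zones: dict[tuple[int, int], int] = {}
    for k in range(ns):
        sl = lev[:, :, k]
        seen = np.zeros((nr, nc), dtype=bool)
        for i in range(nr):
            for j in range(nc):
                if sl[i, j] == 0 or seen[i, j]:
                    continue
                g = sl[i, j]
                stack = [(i, j)]
                seen[i, j] = True
                size = 0
                while stack:
                    r, c = stack.pop()
                    size += 1
                    for dr, dc in OFFSETS_8:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nr and 0 <= cc < nc and not seen[rr, cc] and sl[rr, cc] == g:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                zones[(int(g), size)] = zones.get((int(g), size), 0) + 1
    return zones


def gldm_bruteforce(lev: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts (centre + neighbours within alpha); columns j=1..9."""
    nr, nc, ns = lev.shape
    D = np.zeros((ng, 9), dtype=np.int64)
    for k in range(ns):
        for i in range(nr):
            for j in range(nc):
                a = lev[i, j, k]
                if a == 0:
                    continue
                dep = 0
                for dr, dc in OFFSETS_8:
                    ii, jj = i + dr, j + dc
                    if 0 <= ii < nr and 0 <= jj < nc:
                        b = lev[ii, jj, k]
                        if b > 0 and abs(int(a) - int(b)) <= alpha:
                            dep += 1
                D[a - 1, dep] += 1
    return D


def ngtdm_bruteforce(lev: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray]:
    """Level counts n_i and summed deviations s_i from 8-neighbour means."""
    nr, nc, ns = lev.shape
    n_i = np.zeros(ng, dtype=np.int64)
    s_i = np.zeros(ng, dtype=float)
    for k in range(ns):
        for i in range(nr):
            for j in range(nc):
                a = lev[i, j, k]
                if a == 0:
                    continue
                neigh = []
                for dr, dc in OFFSETS_8:
                    ii, jj = i + dr, j + dc
                    if 0 <= ii < nr and 0 <= jj < nc and lev[ii, jj, k] > 0:
                        neigh.append(int(lev[ii, jj, k]))
                if not neigh:
                    continue
                n_i[a - 1] += 1
                s_i[a - 1] += abs(int(a) - sum(neigh) / len(neigh))
    return n_i, s_i


def boxcox_loglik_grid(x: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Profile log-likelihood of the Box-Cox exponent on a grid."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = np.empty(len(lams))
    logx = np.log(x)
    for i, lam in enumerate(lams):
        y = np.log(x) if lam == 0 else (x**lam - 1) / lam
        out[i] = -n / 2 * np.log(y.var()) + (lam - 1) * logx.sum()
    return out
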