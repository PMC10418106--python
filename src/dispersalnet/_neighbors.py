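"""Grid-based neighbour kernels for the continuous-space simulator.

Competition (local density) and mate search share a Gaussian kernel of scale
sigma truncated at 3*sigma.  Individuals are bucketed into square cells of
width >= 3*sigma so every query is a 3x3-cell scan; pair weights are
computed once (i < j), cached in CSR form, and reused for both the density
sums and the weighted mate draw, which keeps the cost manageable even when
the truncation radius spans the whole habitat.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["build_grid", "density_and_mates"]


def build_grid(pos: np.ndarray, width: float, sigma: float):
    """Bucket individuals into square cells of width >= 3*sigma.

    Returns (order, cell_start, ncell, cell_width): ``order`` lists individual
    indices sorted by cell id and ``cell_start`` delimits each cell's slice.
    """
    ncell = max(1, int(width / (3.0 * sigma)))
    cellw = width / ncell
    cx = np.clip((pos[:, 0] / cellw).astype(np.int64), 0, ncell - 1)
    cy = np.clip((pos[:, 1] / cellw).astype(np.int64), 0, ncell - 1)
    cid = cx * ncell + cy
    order = np.argsort(cid, kind="stable")
    counts = np.bincount(cid, minlength=ncell * ncell)
    cell_start = np.zeros(ncell * ncell + 1, dtype=np.int64)
    np.cumsum(counts, out=cell_start[1:])
    return order, cell_start, ncell, cellw


@njit(cache=True)
def _count_neighbors(pos, r2max, order, cell_start, ncell, cellw):
    n = pos.shape[0]
    deg = np.zeros(n, np.int64)
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        cx = min(int(xi / cellw), ncell - 1)
        cy = min(int(yi / cellw), ncell - 1)
        for dx in range(-1, 2):
            ax = cx + dx
            if ax < 0 or ax >= ncell:
                continue
            for dy in range(-1, 2):
                ay = cy + dy
                if ay < 0 or ay >= ncell:
                    continue
                c = ax * ncell + ay
                for t in range(cell_start[c], cell_start[c + 1]):
                    j = order[t]
                    if j <= i:
                        continue
                    ddx = pos[j, 0] - xi
                    ddy = pos[j, 1] - yi
                    if ddx * ddx + ddy * ddy <= r2max:
                        deg[i] += 1
                        deg[j] += 1
    return deg


@njit(cache=True)
def _fill_weights(pos, sigma, r2max, order, cell_start, ncell, cellw, row_ptr):
    n = pos.shape[0]
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    total = row_ptr[n]
    nbr = np.empty(total, np.int64)
    wgt = np.empty(total, np.float64)
    fill = row_ptr[:n].copy()
    wsum = np.zeros(n)
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        cx = min(int(xi / cellw), ncell - 1)
        cy = min(int(yi / cellw), ncell - 1)
        for dx in range(-1, 2):
            ax = cx + dx
            if ax < 0 or ax >= ncell:
                continue
            for dy in range(-1, 2):
                ay = cy + dy
                if ay < 0 or ay >= ncell:
                    continue
                c = ax * ncell + ay
                for t in range(cell_start[c], cell_start[c + 1]):
                    j = order[t]
                    if j <= i:
                        continue
                    ddx = pos[j, 0] - xi
                    ddy = pos[j, 1] - yi
                    d2 = ddx * ddx + ddy * ddy
                    if d2 <= r2max:
                        w = np.exp(-d2 * inv2s2)
                        nbr[fill[i]] = j
                        wgt[fill[i]] = w
                        fill[i] += 1
                        nbr[fill[j]] = i
                        wgt[fill[j]] = w
                        fill[j] += 1
                        wsum[i] += w
                        wsum[j] += w
    return nbr, wgt, wsum


@njit(cache=True)
def _draw_mates(nbr, wgt, wsum, row_ptr, u_mate):
    n = wsum.shape[0]
    mate = np.full(n, -1, np.int64)
    for i in range(n):
        s = wsum[i]
        if s <= 0.0 or row_ptr[i] == row_ptr[i + 1]:
            continue
        thr = u_mate[i] * s
        acc = 0.0
        chosen = nbr[row_ptr[i + 1] - 1]  # numerical slack: default to last
        for t in range(row_ptr[i], row_ptr[i + 1]):
            acc += wgt[t]
            if acc >= thr:
                chosen = nbr[t]
                break
        mate[i] = chosen
    return mate


def density_and_mates(pos, sigma, u_mate, order, cell_start, ncell, cellw):
    """Per individual: truncated-Gaussian neighbour weight sum and a mate.

    The mate is drawn with probability proportional to exp(-d^2 / 2 sigma^2)
    among neighbours within 3*sigma (self excluded), using the pre-drawn
    uniform ``u_mate[i]`` as an inverse-CDF threshold so the draw is
    deterministic given the random stream.  ``mate[i] == -1`` means no
    candidate in range.
    """
    r2max = 9.0 * sigma * sigma
    deg = _count_neighbors(pos, r2max, order, cell_start, ncell, cellw)
    row_ptr = np.zeros(pos.shape[0] + 1, np.int64)
    np.cumsum(deg, out=row_ptr[1:])
    nbr, wgt, wsum = _fill_weights(pos, sigma, r2max, order, cell_start, ncell, cellw, row_ptr)
    mate = _draw_mates(nbr, wgt, wsum, row_ptr, u_mate)
    return wsum, mate
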