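"""Numba cell-list kernels for neighbor-limited interactions.

Competition sums and mate search are the O(N^2) hot spots of the simulation;
both are restricted to the interaction radius R, so a uniform grid of cells
with side >= R reduces each query to a 3x3 cell neighborhood.

Neighbor contributions are accumulated in ascending individual-index order
(candidates are sorted before summation), which makes the results bitwise
identical to a brute-force pairwise loop that scans indices in ascending
order — floating-point addition is order-dependent, and a canonical order
keeps the optimized path exactly reproducible and directly checkable
against an exhaustive oracle.
"""

from __future__ import annotations

import numba
import numpy as np
from numba import njit


@njit(cache=True)
def _cell_of(x, y, cell_size, ncx, ncy):
    cx = int(x / cell_size)
    if cx >= ncx:
        cx = ncx - 1
    if cx < 0:
        cx = 0
    cy = int(y / cell_size)
    if cy >= ncy:
        cy = ncy - 1
    if cy < 0:
        cy = 0
    return cx, cy


@njit(cache=True)
def build_cell_list(x, y, cell_size, ncx, ncy):
    """Counting sort of individuals into grid cells.

    Returns (start, order): `order[start[c]:start[c+1]]` lists the indices in
    cell c in ascending order (the sort is stable over ascending input).
    """
    n = x.size
    ncells = ncx * ncy
    counts = np.zeros(ncells + 1, np.int64)
    cell_id = np.empty(n, np.int64)
    for i in range(n):
        cx, cy = _cell_of(x[i], y[i], cell_size, ncx, ncy)
        c = cx * ncy + cy
        cell_id[i] = c
        counts[c + 1] += 1
    start = np.cumsum(counts)
    fill = np.zeros(ncells, np.int64)
    order = np.empty(n, np.int64)
    for i in range(n):
        c = cell_id[i]
        order[start[c] + fill[c]] = i
        fill[c] += 1
    return start, order


@njit(cache=True)
def competition_sums(x, y, target_idx, R, sigma, cell_size, ncx, ncy,
                     start, order):
    """Summed Gaussian competition weight at each target individual.

    Every individual within distance R (self excluded) contributes
    exp(-d^2 / (2 sigma^2)).  Contributions are added in ascending
    neighbor-index order.
    """
    R2 = R * R
    two_sig2 = 2.0 * sigma * sigma
    nt = target_idx.size
    out = np.zeros(nt, np.float64)
    buf = np.empty(x.size, np.int64)
    for t in range(nt):
        i = target_idx[t]
        xi = x[i]
        yi = y[i]
        cx, cy = _cell_of(xi, yi, cell_size, ncx, ncy)
        m = 0
        for dcx in range(-1, 2):
            ccx = cx + dcx
            if ccx < 0 or ccx >= ncx:
                continue
            for dcy in range(-1, 2):
                ccy = cy + dcy
                if ccy < 0 or ccy >= ncy:
                    continue
                c = ccx * ncy + ccy
                for k in range(start[c], start[c + 1]):
                    j = order[k]
                    if j == i:
                        continue
                    dx = xi - x[j]
                    dy = yi - y[j]
                    d2 = dx * dx + dy * dy
                    if d2 <= R2:
                        buf[m] = j
                        m += 1
        sub = buf[:m]
        sub.sort()
        total = 0.0
        for k in range(m):
            j = sub[k]
            dx = xi - x[j]
            dy = yi - y[j]
            d2 = dx * dx + dy * dy
            total += np.exp(-d2 / two_sig2)
        out[t] = total
    return out


@njit(cache=True)
def choose_mates(fx, fy, mx, my, R, cell_size, ncx, ncy, start, order, u):
    """For each female position, pick a uniform random male within R.

    `start`/`order` index the *male* arrays.  `u` holds one uniform draw per
    female.  Returns the male-array index of the chosen mate, or -1 when no
    male lies within the home range.  Candidates are sorted ascending so the
    uniform draw maps to a canonical ordering.
    """
    R2 = R * R
    nf = fx.size
    chosen = np.full(nf, -1, np.int64)
    buf = np.empty(mx.size, np.int64)
    for f in range(nf):
        xi = fx[f]
        yi = fy[f]
        cx, cy = _cell_of(xi, yi, cell_size, ncx, ncy)
        m = 0
        for dcx in range(-1, 2):
            ccx = cx + dcx
            if ccx < 0 or ccx >= ncx:
                continue
            for dcy in range(-1, 2):
                ccy = cy + dcy
                if ccy < 0 or ccy >= ncy:
                    continue
                c = ccx * ncy + ccy
                for k in range(start[c], start[c + 1]):
                    j = order[k]
                    dx = xi - mx[j]
                    dy = yi - my[j]
                    if dx * dx + dy * dy <= R2:
                        buf[m] = j
                        m += 1
        if m == 0:
            continue
        sub = buf[:m]
        sub.sort()
        pick = int(u[f] * m)
        if pick >= m:
            pick = m - 1
        chosen[f] = sub[pick]
    return chosen


def grid_spec(side: float, R: float) -> tuple[float, int, int]:
    """Cell size (>= R) and cell counts for a square arena of given side."""
    ncx = max(1, int(side / R))
    cell_size = side / ncx
    return cell_size, ncx, ncx
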