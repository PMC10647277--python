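"""Low-level lattice routines: the sweep kernel and wound-area measures.

The sweep kernel consumes pre-drawn random numbers (visit order, one action
draw and one target draw per visited cell, one refill draw per boundary site)
so that it is a deterministic function of its inputs; all randomness is
produced by the caller from a single numpy Generator.
"""

import numpy as np
from numba import njit
from scipy import ndimage

__all__ = ["sweep_inplace", "wound_runs", "wound_component_sites"]

#: Target selection modes: BLOCK draws one site uniformly from the
#: bias-reduced 3x3 block (self included) and acts only when it is empty;
#: EMPTY draws uniformly from the empty candidate sites only.
TARGET_BLOCK = 0
TARGET_EMPTY = 1

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@njit(cache=True)
def sweep_inplace(
    grid,
    order_rows,
    order_cols,
    lambdas,
    choice_u,
    pm,
    bias_enabled,
    center_col,
    ex0r,
    ex0c,
    ex1r,
    ex1c,
    target_mode,
    prolif_enabled,
):
    """One asynchronous sweep, mutating ``grid`` in place.

    ``order_rows``/``order_cols`` list the sites occupied at the start of the
    sweep in a random visit order.  For the k-th visited cell, ``lambdas[k]``
    decides migrate-vs-proliferate and ``choice_u[k]`` picks the target site
    (fixed row-major enumeration).  With ``target_mode`` = TARGET_BLOCK the
    draw is over the whole bias-reduced 3x3 block (including the cell's own
    site) and nothing happens when the drawn site is not vacant -- transport
    is then an excluded random walk; with TARGET_EMPTY the draw is over the
    empty candidates only, which makes fronts advance ballistically.
    ``(ex0r, ex0c)`` / ``(ex1r, ex1c)`` are the two bias-excluded offsets in
    the frame of a cell LEFT of the wound center (backward = negative column
    offset); the column component is mirrored for cells right of center.
    Rows wrap periodically; columns do not (the lattice edge is the
    reservoir); reservoir refill is applied by the caller after the sweep.
    """
    nrows, ncols = grid.shape
    cand_r = np.empty(9, np.int64)
    cand_c = np.empty(9, np.int64)
    n = order_rows.size
    for k in range(n):
        r = order_rows[k]
        c = order_cols[k]
        side = 0
        if bias_enabled:
            if c < center_col:
                side = 1
            elif c > center_col:
                side = -1
        m = 0
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    if target_mode == TARGET_BLOCK:
                        cand_r[m] = r
                        cand_c[m] = c
                        m += 1
                    continue
                if side != 0:
                    edc = dc if side == 1 else -dc
                    if (dr == ex0r and edc == ex0c) or (dr == ex1r and edc == ex1c):
                        continue
                cc = c + dc
                if cc < 0 or cc >= ncols:
                    continue
                rr = r + dr
                if rr < 0:
                    rr += nrows
                elif rr >= nrows:
                    rr -= nrows
                if target_mode == TARGET_BLOCK or grid[rr, cc] == 0:
                    cand_r[m] = rr
                    cand_c[m] = cc
                    m += 1
        if m == 0:
            continue  # quiescent: contact inhibition
        t = int(choice_u[k] * m)
        if t >= m:
            t = m - 1
        tr = cand_r[t]
        tc = cand_c[t]
        if grid[tr, tc] != 0:
            continue  # blocked draw (occupied site or self): no action
        if lambdas[k] < pm:
            grid[r, c] = 0
            grid[tr, tc] = 1
        elif prolif_enabled:
            grid[tr, tc] = 1


def wound_component_sites(grid, band_start, band_end, min_size=2):
    """Number of empty sites in 8-connected empty components that intersect
    the wound-band columns ``[band_start, band_end)``.

    Components smaller than ``min_size`` sites are ignored: an isolated
    vacancy is smaller than one cell and is invisible to an image-based
    wound-edge detector, so it does not count as cell-free wound area.
    """
    empty = grid == 0
    labels, n_labels = ndimage.label(empty, structure=_EIGHT_CONNECTED)
    if n_labels == 0:
        return 0
    counts = np.bincount(labels.ravel())
    in_band = np.zeros(n_labels + 1, dtype=bool)
    in_band[labels[:, band_start:band_end].ravel()] = True
    in_band[0] = False
    return int(counts[in_band & (counts >= min_size)].sum())


@njit(cache=True)
def wound_runs(grid, center_col):
    """Total length (in sites) of per-row maximal empty runs through
    ``center_col``; a row contributes 0 when its center site is occupied."""
    nrows, ncols = grid.shape
    total = 0
    for r in range(nrows):
        if grid[r, center_col] != 0:
            continue
        left = center_col
        while left > 0 and grid[r, left - 1] == 0:
            left -= 1
        right = center_col
        while right < ncols - 1 and grid[r, right + 1] == 0:
            right += 1
        total += right - left + 1
    return total
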