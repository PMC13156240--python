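"""Depression filling and D8 flow routing."""

from __future__ import annotations

import heapq

import numpy as np

from ..raster_core import Grid

__all__ = ["fill_depressions", "d8_flow", "D8_OFFSETS"]

#: D8 neighbor offsets indexed by direction code 0..7 (N, NE, E, SE, S, SW, W, NW).
D8_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]

#: Direction code meaning "drains off the grid edge (outlet)".
OUTLET = -1


def fill_depressions(dem: Grid, epsilon: float = 1e-4) -> Grid:
    """Priority-flood depression filling with an epsilon gradient.

    Every cell is raised to at least ``epsilon`` above the pour point of
    its depression, so a monotone downslope path to the grid edge exists
    from every cell.  Nodata cells are left untouched and act as holes.
    """
    z = dem.values.astype(float).copy()
    valid = dem.valid()
    nr, nc = z.shape
    closed = ~valid  # nodata never processed
    heap: list[tuple[float, int, int]] = []
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            edge = r in (0, nr - 1) or c in (0, nc - 1)
            if not edge:
                # cells beside nodata holes also drain out
                edge = any(
                    0 <= r + dr < nr and 0 <= c + dc < nc and not valid[r + dr, c + dc]
                    for dr, dc in D8_OFFSETS
                )
            if edge:
                heapq.heappush(heap, (z[r, c], r, c))
                closed[r, c] = True
    while heap:
        zv, r, c = heapq.heappop(heap)
        for dr, dc in D8_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not closed[rr, cc]:
                closed[rr, cc] = True
                z[rr, cc] = max(z[rr, cc], zv + epsilon)
                heapq.heappush(heap, (z[rr, cc], rr, cc))
    out = z
    out[~valid] = dem.nodata
    return dem.copy_with(out, kind="continuous")


def d8_flow(dem: Grid, fill: bool = True) -> tuple[Grid, Grid]:
    """D8 flow direction and accumulation.

    Depressions are filled first (priority flood) so the drainage network
    is continuous.  Each cell drains to its steepest-descent 8-neighbor
    (drop divided by center distance); cells with no lower neighbor drain
    off-grid and get direction code ``-1``.  Accumulation counts strictly
    upstream cells — the cell itself is excluded.

    Returns
    -------
    (direction, accumulation)
        ``direction`` is a categorical grid of codes 0..7 / -1;
        ``accumulation`` a continuous grid of upstream cell counts.
    """
    filled = fill_depressions(dem) if fill else dem
    z = filled.values.astype(float)
    valid = filled.valid()
    nr, nc = z.shape
    direction = np.full((nr, nc), OUTLET, dtype=np.int64)
    for code, (dr, dc) in enumerate(D8_OFFSETS):
        dist = np.hypot(dr, dc)
        shifted = np.full_like(z, np.inf)
        src_r = slice(max(0, dr), nr + min(0, dr))
        src_c = slice(max(0, dc), nc + min(0, dc))
        dst_r = slice(max(0, -dr), nr + min(0, -dr))
        dst_c = slice(max(0, -dc), nc + min(0, -dc))
        shifted[dst_r, dst_c] = np.where(
            valid[src_r, src_c], z[src_r, src_c], np.inf
        )
        grad = (z - shifted) / dist
        if code == 0:
            best = grad.copy()
            direction = np.where(grad > 0, 0, OUTLET)
        else:
            better = grad > np.maximum(best, 0)
            direction = np.where(better, code, direction)
            best = np.maximum(best, grad)
    direction[~valid] = OUTLET

    # accumulate in decreasing-elevation order (filled DEM is acyclic)
    acc = np.zeros((nr, nc), dtype=np.int64)
    order = np.argsort(z, axis=None)[::-1]
    rows, cols = np.unravel_index(order, z.shape)
    for r, c in zip(rows, cols):
        if not valid[r, c]:
            continue
        d = direction[r, c]
        if d == OUTLET:
            continue
        rr, cc = r + D8_OFFSETS[d][0], c + D8_OFFSETS[d][1]
        if 0 <= rr < nr and 0 <= cc < nc and valid[rr, cc]:
            acc[rr, cc] += acc[r, c] + 1
        else:
            direction[r, c] = OUTLET
    dir_grid = filled.copy_with(direction, kind="categorical")
    dir_grid.nodata = -99
    acc_out = acc.astype(float)
    acc_out[~valid] = filled.nodata
    acc_grid = filled.copy_with(acc_out, kind="continuous")
    return dir_grid, acc_grid
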