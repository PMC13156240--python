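"""Slope, topographic position, and landform classification."""

from __future__ import annotations

import numpy as np

from ..raster_core import Grid, focal_stat

__all__ = ["slope", "tpi", "geomorphons", "LANDFORM_CLASSES", "VALLEY_CLASSES"]

#: Landform class codes produced by :func:`geomorphons`.
LANDFORM_CLASSES = {
    1: "Flat",
    2: "Peak",
    3: "Ridge",
    4: "Shoulder",
    5: "Spur",
    6: "Slope",
    7: "Hollow",
    8: "Footslope",
    9: "Valley",
    10: "Pit",
}

#: Classes 6-10: slopes, hollows, footslopes, valleys, pits — the concave /
#: low positions where stream channels can form.
VALLEY_CLASSES = frozenset({6, 7, 8, 9, 10})

_FL, _PK, _RI, _SH, _SP, _SL, _HL, _FS, _VL, _PT = range(1, 11)

# Ternary-pattern lookup indexed by [n_minus][n_plus], where a '+' direction
# has terrain rising above the flatness angle and a '-' direction has terrain
# dropping below it.  8 pluses = surrounded by higher ground = Pit; 8 minuses
# = Peak.  Standard 10-class table of the ternary-pattern landform method.
_LOOKUP = -np.ones((9, 9), dtype=np.int64)
for _nm, _row in enumerate(
    [
        [_FL, _FL, _FL, _FS, _FS, _VL, _VL, _VL, _PT],
        [_FL, _FL, _FS, _FS, _FS, _VL, _VL, _VL],
        [_FL, _SH, _SL, _SL, _HL, _VL, _VL],
        [_SH, _SH, _SL, _SL, _SL, _HL],
        [_SH, _SH, _SL, _SL, _HL],
        [_RI, _RI, _SP, _SL],
        [_RI, _RI, _SP],
        [_RI, _RI],
        [_PK],
    ]
):
    for _np_, _cls in enumerate(_row):
        _LOOKUP[_nm, _np_] = _cls

_DIRS8 = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def slope(dem: Grid, radius: float | None = 120.0) -> Grid:
    """Slope in degrees (Horn 3×3 finite differences), focal-meaned.

    ``radius=None`` skips the neighborhood averaging step.  Adding a
    constant to the DEM leaves the result unchanged.
    """
    z = dem.values.astype(float)
    bad = ~dem.valid()
    work = z.copy()
    if bad.any():
        # fill nodata with nearest valid value so gradients stay finite
        from scipy import ndimage

        idx = ndimage.distance_transform_edt(
            bad, return_distances=False, return_indices=True
        )
        work = work[tuple(idx)]
    zp = np.pad(work, 1, mode="edge")
    a = zp[:-2, :-2]
    b = zp[:-2, 1:-1]
    c = zp[:-2, 2:]
    d = zp[1:-1, :-2]
    f = zp[1:-1, 2:]
    g = zp[2:, :-2]
    h = zp[2:, 1:-1]
    i = zp[2:, 2:]
    cs = dem.cell_size
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cs)
    deg = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    deg[bad] = dem.nodata
    out = dem.copy_with(deg, kind="continuous")
    if radius is not None:
        out = focal_stat(out, radius, "mean")
    return out


def tpi(dem: Grid, radius: float = 120.0) -> Grid:
    """Topographic position index: elevation minus circular focal mean.

    Positive on ridges, negative in valleys; invariant to adding a
    constant to the DEM.
    """
    mean = focal_stat(dem, radius, "mean")
    out = np.full(dem.shape, dem.nodata, dtype=float)
    ok = dem.valid() & (mean.values != mean.nodata)
    out[ok] = dem.values[ok].astype(float) - mean.values[ok]
    return dem.copy_with(out, kind="continuous")


def geomorphons(
    dem: Grid,
    search_cells: int = 10,
    skip_cells: int = 3,
    flat_deg: float = 1.0,
) -> Grid:
    """Classify each cell into one of 10 landform classes.

    For each of the 8 compass directions the line-of-sight elevation angle
    is evaluated at every cell between ``skip_cells`` (exclusive) and
    ``search_cells`` (inclusive) steps away; the direction's symbol is '+'
    if the strongest angle rises above ``flat_deg``, '-' if it drops below
    ``-flat_deg``, and '0' otherwise.  The (n+, n-) counts index the
    standard ternary-pattern lookup table.  Windows are truncated at grid
    edges.
    """
    if not search_cells > skip_cells >= 0:
        raise ValueError("need search_cells > skip_cells >= 0")
    z = dem.values.astype(float)
    nr, nc = z.shape
    cs = dem.cell_size
    n_plus = np.zeros_like(z, dtype=np.int64)
    n_minus = np.zeros_like(z, dtype=np.int64)
    for dr, dc in _DIRS8:
        step = np.hypot(dr, dc) * cs
        best = np.full_like(z, -np.inf)  # max line-of-sight angle
        worst = np.full_like(z, np.inf)  # min line-of-sight angle
        seen = np.zeros_like(z, dtype=bool)
        for k in range(skip_cells + 1, search_cells + 1):
            rr = dr * k
            cc = dc * k
            shifted = np.full_like(z, np.nan)
            src_r = slice(max(0, rr), nr + min(0, rr))
            src_c = slice(max(0, cc), nc + min(0, cc))
            dst_r = slice(max(0, -rr), nr + min(0, -rr))
            dst_c = slice(max(0, -cc), nc + min(0, -cc))
            shifted[dst_r, dst_c] = z[src_r, src_c]
            ang = np.degrees(np.arctan((shifted - z) / (k * step)))
            ok = np.isfinite(ang)
            best[ok] = np.maximum(best[ok], ang[ok])
            worst[ok] = np.minimum(worst[ok], ang[ok])
            seen |= ok
        # dominant angle: whichever of rise/drop has larger magnitude
        dom = np.zeros_like(z)
        dom[seen] = np.where(
            np.abs(best[seen]) >= np.abs(worst[seen]), best[seen], worst[seen]
        )
        n_plus += (seen & (dom > flat_deg)).astype(np.int64)
        n_minus += (seen & (dom < -flat_deg)).astype(np.int64)
    codes = _LOOKUP[n_minus, n_plus]
    codes[~dem.valid()] = -1
    out = dem.copy_with(codes, kind="categorical")
    out.nodata = -1
    return out
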