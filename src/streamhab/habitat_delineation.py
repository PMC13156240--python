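"""Refinement of the continuous suitability surface into a habitat model.

The cascade: binarize at the equal-sensitivity/specificity threshold,
keep the upper Jenks class, drop tiny isolated patches, drop cells
embedded in urban-dominated neighborhoods, then extend the surviving
breeding habitat with qualifying terrestrial cover within 500 m.
Each refinement step is a pure shrinking filter, so the cascade is
monotone and idempotent.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import landcover as lc
from .raster_core import Grid, Mask, area_km2, buffer_mask, _disk_footprint

__all__ = [
    "binarize",
    "jenks_break",
    "jenks_upper",
    "drop_isolated",
    "drop_urban_embedded",
    "extend_terrestrial",
    "refine",
    "HabitatModel",
]


def binarize(cloglog: Grid, threshold: float) -> Mask:
    """Cells with suitability at or above ``threshold``."""
    vals = cloglog.values
    return Mask((vals >= threshold) & cloglog.valid(), cloglog)


def jenks_break(values: np.ndarray) -> float:
    """Optimal two-class break: the value below which the lower class ends.

    Exact minimization of within-class sum of squared deviations over all
    n−1 possible splits of the sorted values (prefix-sum scan, so O(n log n)
    in the sort).  Returns the midpoint between the two boundary values.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if len(x) < 2 or x[0] == x[-1]:
        raise ValueError("need at least 2 distinct values")
    csum = np.cumsum(x)
    csq = np.cumsum(x**2)
    n = len(x)
    idx = np.arange(1, n)  # lower class = x[:i]
    ssd_lo = csq[idx - 1] - csum[idx - 1] ** 2 / idx
    sum_hi = csum[-1] - csum[idx - 1]
    sq_hi = csq[-1] - csq[idx - 1]
    ssd_hi = sq_hi - sum_hi**2 / (n - idx)
    best = int(idx[np.argmin(ssd_lo + ssd_hi)])
    return float((x[best - 1] + x[best]) / 2)


def jenks_upper(cloglog: Grid, mask: Mask) -> Mask:
    """Within ``mask``, keep only cells in the upper of the two Jenks
    classes of the suitability values."""
    vals = cloglog.values[mask.values]
    brk = jenks_break(vals)
    return Mask(mask.values & (cloglog.values > brk), cloglog)


def drop_isolated(
    mask: Mask, max_cells: int = 2, isolation: float = 1000.0
) -> Mask:
    """Remove 8-connected components of ≤ ``max_cells`` cells that lie
    farther than ``isolation`` (center-to-center) from any larger patch."""
    labels, n = ndimage.label(mask.values, structure=np.ones((3, 3)))
    if n == 0:
        return Mask(mask.values.copy(), mask.grid)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    large = np.isin(labels, np.nonzero(sizes > max_cells)[0] + 1)
    small_ids = np.nonzero(sizes <= max_cells)[0] + 1
    if len(small_ids) == 0:
        return Mask(mask.values.copy(), mask.grid)
    if not large.any():
        return Mask(large, mask.grid)  # nothing to anchor small patches
    dist = ndimage.distance_transform_edt(~large) * mask.cell_size
    keep = mask.values.copy()
    for sid in small_ids:
        cells = labels == sid
        if dist[cells].min() > isolation:
            keep[cells] = False
    return Mask(keep, mask.grid)


def drop_urban_embedded(
    mask: Mask,
    landcover_grid: Grid,
    radius: float = 500.0,
    frac: float = 0.5,
) -> Mask:
    """Remove habitat cells whose circular neighborhood is more than
    ``frac`` developed or barren."""
    dev = np.isin(landcover_grid.values, list(lc.DEVELOPED_OR_BARREN)).astype(float)
    fp = _disk_footprint(radius, mask.cell_size).astype(float)
    dev_sum = ndimage.correlate(dev, fp, mode="constant", cval=0.0)
    cnt = ndimage.correlate(np.ones_like(dev), fp, mode="constant", cval=0.0)
    dev_frac = dev_sum / cnt
    return Mask(mask.values & ~(dev_frac > frac), mask.grid)


@dataclasses.dataclass
class HabitatModel:
    """Final habitat model: disjoint breeding and terrestrial components."""

    breeding: Mask
    terrestrial: Mask
    combined: Mask
    breeding_km2: float
    terrestrial_km2: float
    combined_km2: float

    @staticmethod
    def from_masks(breeding: Mask, terrestrial: Mask) -> "HabitatModel":
        terrestrial = terrestrial.difference(breeding)
        combined = breeding | terrestrial
        return HabitatModel(
            breeding=breeding,
            terrestrial=terrestrial,
            combined=combined,
            breeding_km2=area_km2(breeding),
            terrestrial_km2=area_km2(terrestrial),
            combined_km2=area_km2(combined),
        )

    def areas(self) -> dict[str, float]:
        return {
            "breeding_km2": self.breeding_km2,
            "terrestrial_km2": self.terrestrial_km2,
            "combined_km2": self.combined_km2,
        }

    def save(self, directory: str | Path) -> None:
        from .raster_core import write_ascii

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_ascii(self.breeding.grid, directory / "breeding.asc")
        write_ascii(self.terrestrial.grid, directory / "terrestrial.asc")
        write_ascii(self.combined.grid, directory / "combined.asc")
        (directory / "areas.json").write_text(json.dumps(self.areas(), indent=2))


def extend_terrestrial(
    breeding: Mask,
    landcover_grid: Grid,
    canopy: Grid,
    radius: float = 500.0,
) -> HabitatModel:
    """Add terrestrial habitat: open-canopy (< 50%) evergreen/shrub/grass
    cells within ``radius`` of breeding habitat, excluding breeding cells."""
    if breeding.count() == 0:
        raise ValueError("breeding mask is empty")
    buf = buffer_mask(breeding, radius)
    qualifying = np.isin(landcover_grid.values, list(lc.TERRESTRIAL_CLASSES)) & (
        canopy.values < 50
    )
    terrestrial = Mask(buf.values & qualifying & ~breeding.values, breeding.grid)
    return HabitatModel.from_masks(breeding, terrestrial)


def refine(
    cloglog: Grid,
    threshold: float,
    landcover_grid: Grid,
    max_cells: int = 2,
    isolation: float = 1000.0,
    urban_radius: float = 500.0,
    urban_frac: float = 0.5,
) -> Mask:
    """Full breeding-habitat refinement cascade (threshold → Jenks upper
    class → isolated-patch filter → urban-embedded filter)."""
    m = binarize(cloglog, threshold)
    m = jenks_upper(cloglog, m)
    m = drop_isolated(m, max_cells=max_cells, isolation=isolation)
    m = drop_urban_embedded(m, landcover_grid, radius=urban_radius, frac=urban_frac)
    return m
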