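"""Protected-area coverage, adjacent land-use exposure, and projected
urbanization threat of the final habitat model."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import landcover as lc
from .raster_core import Grid, Mask, area_km2
from .habitat_delineation import HabitatModel

__all__ = [
    "protected_coverage",
    "adjacency_exposure",
    "urbanization_threat",
    "gap_summary",
    "GapReport",
]

TOTAL_REGION = "total"


def _region_masks(habitat: Mask, regions: Grid | None) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {TOTAL_REGION: np.ones(habitat.shape, dtype=bool)}
    if regions is not None:
        for code in np.unique(regions.values[regions.valid()]):
            out[str(int(code))] = regions.values == code
    return out


def protected_coverage(
    habitat: Mask, protected: Mask, regions: Grid | None = None
) -> pd.DataFrame:
    """Per-region habitat area, protected overlap, and percent protected."""
    cell_km2 = habitat.cell_size**2 / 1e6
    rows = []
    for name, rmask in _region_masks(habitat, regions).items():
        hab = habitat.values & rmask
        prot = hab & protected.values
        hab_km2 = hab.sum() * cell_km2
        prot_km2 = prot.sum() * cell_km2
        rows.append(
            {
                "region": name,
                "habitat_km2": hab_km2,
                "protected_km2": prot_km2,
                "protected_pct": 100.0 * prot_km2 / hab_km2 if hab_km2 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def adjacency_exposure(
    habitat: Mask,
    landcover_grid: Grid,
    plantations: Mask | None = None,
    buffer: float = 60.0,
    regions: Grid | None = None,
) -> pd.DataFrame:
    """Exposure to development, agriculture, and plantations in the one-cell
    ring around habitat.

    Reported both as percent of habitat area (the headline numbers) and as
    percent of the ring itself.  The ring is a Chebyshev (square) dilation:
    a one-pixel buffer includes diagonal neighbors.
    """
    k = max(1, int(round(buffer / habitat.cell_size)))
    ring = ndimage.binary_dilation(
        habitat.values, structure=np.ones((2 * k + 1, 2 * k + 1), dtype=bool)
    ) & ~habitat.values
    dev = np.isin(landcover_grid.values, list(lc.DEVELOPED_INTENSITY))
    agr = np.isin(landcover_grid.values, list(lc.AGRICULTURE))
    pla = plantations.values if plantations is not None else np.zeros_like(dev)
    cell_km2 = habitat.cell_size**2 / 1e6
    rows = []
    for name, rmask in _region_masks(habitat, regions).items():
        hab_km2 = (habitat.values & rmask).sum() * cell_km2
        ring_r = ring & rmask
        ring_km2 = ring_r.sum() * cell_km2
        for label, m in (("development", dev), ("agriculture", agr), ("plantation", pla)):
            exp_km2 = (ring_r & m).sum() * cell_km2
            rows.append(
                {
                    "region": name,
                    "category": label,
                    "adjacent_km2": exp_km2,
                    "pct_of_habitat": 100.0 * exp_km2 / hab_km2 if hab_km2 else 0.0,
                    "pct_of_ring": 100.0 * exp_km2 / ring_km2 if ring_km2 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def urbanization_threat(
    habitat: Mask,
    protected: Mask,
    sleuth: Grid,
    regions: Grid | None = None,
    split: float = 50.0,
) -> pd.DataFrame:
    """Unprotected habitat overlapped by projected development.

    ``sleuth`` holds per-cell development probabilities on [0, 100] (or
    [0, 1], auto-rescaled).  Projections inside protected areas are
    nulled before intersection.  Classes: p < ``split``, p ≥ ``split``,
    and their union (total); percentages are against the region's
    habitat area.
    """
    prob = sleuth.values.astype(float).copy()
    valid = sleuth.valid()
    if np.nanmax(np.where(valid, prob, 0)) <= 1.0:
        prob = prob * 100.0
    prob[~valid] = np.nan
    prob[protected.values] = np.nan  # omit projections inside protected areas
    projected = np.isfinite(prob) & (prob > 0)
    unprot_hab = habitat.values & ~protected.values
    cell_km2 = habitat.cell_size**2 / 1e6
    rows = []
    for name, rmask in _region_masks(habitat, regions).items():
        hab_km2 = (habitat.values & rmask).sum() * cell_km2
        unprot_km2 = (unprot_hab & rmask).sum() * cell_km2
        low = (unprot_hab & rmask & projected & (prob < split)).sum() * cell_km2
        high = (unprot_hab & rmask & projected & (prob >= split)).sum() * cell_km2
        total = low + high
        for label, km2 in (("p<50", low), ("p>=50", high), ("total", total)):
            rows.append(
                {
                    "region": name,
                    "class": label,
                    "projected_km2": km2,
                    "pct_of_habitat": 100.0 * km2 / hab_km2 if hab_km2 else 0.0,
                    "pct_of_unprotected": (
                        100.0 * km2 / unprot_km2 if unprot_km2 else 0.0
                    ),
                }
            )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class GapReport:
    """Assembled gap-analysis tables for one habitat component set."""

    protection: pd.DataFrame
    adjacency: pd.DataFrame
    threat: pd.DataFrame

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.protection.to_csv(directory / "protection.csv", index=False)
        self.adjacency.to_csv(directory / "adjacency.csv", index=False)
        self.threat.to_csv(directory / "threat.csv", index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "protection": self.protection.to_dict(orient="records"),
                    "adjacency": self.adjacency.to_dict(orient="records"),
                    "threat": self.threat.to_dict(orient="records"),
                },
                indent=2,
            )
        )


def gap_summary(
    model: HabitatModel,
    protected: Mask,
    landcover_grid: Grid,
    sleuth: Grid,
    plantations: Mask | None = None,
    regions: Grid | None = None,
    tolerance_pct: float = 0.5,
) -> dict[str, GapReport]:
    """Full gap report per habitat component (breeding / terrestrial /
    combined), with internal arithmetic cross-checks.

    Raises ``ValueError`` if component areas disagree with the combined
    area by more than ``tolerance_pct`` percent.
    """
    parts = {
        "breeding": model.breeding,
        "terrestrial": model.terrestrial,
        "combined": model.combined,
    }
    mism = abs(
        area_km2(model.breeding) + area_km2(model.terrestrial) - area_km2(model.combined)
    )
    if model.combined_km2 and 100.0 * mism / model.combined_km2 > tolerance_pct:
        raise ValueError("breeding + terrestrial areas do not add up to combined")
    out: dict[str, GapReport] = {}
    for name, mask in parts.items():
        prot = protected_coverage(mask, protected, regions)
        adj = adjacency_exposure(mask, landcover_grid, plantations, regions=regions)
        thr = urbanization_threat(mask, protected, sleuth, regions)
        # cross-check: protected + unprotected = habitat; class areas partition
        for _, row in prot.iterrows():
            if row["habitat_km2"]:
                if not 0.0 <= row["protected_pct"] <= 100.0 + tolerance_pct:
                    raise ValueError("protected percentage out of range")
        t = thr[thr["region"] == TOTAL_REGION].set_index("class")["projected_km2"]
        if abs(t["p<50"] + t["p>=50"] - t["total"]) > 1e-9:
            raise ValueError("projected-development classes do not partition the total")
        out[name] = GapReport(prot, adj, thr)
    return out
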