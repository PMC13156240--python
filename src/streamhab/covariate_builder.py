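"""Covariate stack assembly, collinearity screening, focal-radius selection,
and land-cover change accounting.

The stack holds the 12 model covariates: three topographic layers (slope,
TPI, landform), three soil layers, two distance layers, two catchment-scale
land-use percentages, and two climate layers.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import landcover as lc
from .raster_core import Grid, Mask, distance_to, focal_stat, write_ascii, read_ascii
from .terrain_hydrology import slope as slope_op, tpi as tpi_op, geomorphons
from .terrain_hydrology.network import FlowlineNetwork

__all__ = [
    "CovariateStack",
    "LAYER_NAMES",
    "build_stack",
    "collinearity_screen",
    "correlation_ratio",
    "select_radius",
    "information_value",
    "landcover_change",
    "change_table_from_areas",
    "occurrence_change_flags",
]

LAYER_NAMES = [
    "slope",
    "tpi",
    "landform",
    "conductivity",
    "ph",
    "pct_sand",
    "dist_stream",
    "dist_terrestrial",
    "pct_developed",
    "pct_agriculture",
    "temp_march",
    "precip_march",
]

CATEGORICAL_LAYERS = {"landform"}

#: Layers built with a circular focal neighborhood (radius-dependent).
NEIGHBORHOOD_LAYERS = ["slope", "tpi", "conductivity", "ph", "pct_sand"]


@dataclasses.dataclass
class CovariateStack:
    """Named, geometry-aligned covariate layers."""

    layers: dict[str, Grid]

    def __post_init__(self) -> None:
        missing = [n for n in LAYER_NAMES if n not in self.layers]
        if missing:
            raise ValueError(f"missing covariate layers: {missing}")
        ref = self.layers[LAYER_NAMES[0]]
        for name, g in self.layers.items():
            if not g.same_geometry(ref):
                raise ValueError(f"layer {name!r} geometry differs from {LAYER_NAMES[0]!r}")

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    @property
    def names(self) -> list[str]:
        return list(LAYER_NAMES)

    def continuous_names(self) -> list[str]:
        return [n for n in LAYER_NAMES if n not in CATEGORICAL_LAYERS]

    def sample(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Per-point covariate values as a DataFrame (one column per layer)."""
        data = {
            name: self.layers[name].values[rows, cols] for name in LAYER_NAMES
        }
        return pd.DataFrame(data)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, g in self.layers.items():
            write_ascii(g, directory / f"{name}.asc")
        manifest = {
            "layers": LAYER_NAMES,
            "categorical": sorted(CATEGORICAL_LAYERS),
            "cell_size": self.layers["slope"].cell_size,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @staticmethod
    def load(directory: str | Path) -> "CovariateStack":
        directory = Path(directory)
        layers = {}
        for name in LAYER_NAMES:
            kind = "categorical" if name in CATEGORICAL_LAYERS else "continuous"
            layers[name] = read_ascii(directory / f"{name}.asc", kind=kind)
        return CovariateStack(layers)


def _watershed_class_pct(
    landcover_grid: Grid, watersheds: Grid, codes: frozenset[int]
) -> Grid:
    """Percent of each watershed covered by ``codes``, painted onto cells."""
    ws = watersheds.values
    valid = watersheds.valid() & landcover_grid.valid()
    out = np.full(ws.shape, landcover_grid.nodata, dtype=float)
    member = np.isin(landcover_grid.values, list(codes))
    for wid in np.unique(ws[valid]):
        sel = valid & (ws == wid)
        total = sel.sum()
        if total:
            out[sel] = 100.0 * member[sel].sum() / total
    return landcover_grid.copy_with(out, kind="continuous")


def build_stack(
    dem: Grid,
    landcover_grid: Grid,
    canopy: Grid,
    soils: dict[str, Grid],
    climate: dict[str, Grid],
    net: FlowlineNetwork,
    watersheds: Grid,
    radius: float = 120.0,
    landform: Grid | None = None,
) -> CovariateStack:
    """Derive the 12-layer covariate stack at a given focal radius.

    ``soils`` must provide conductivity/ph/pct_sand and ``climate``
    temp_march/precip_march.  ``landform`` may be passed in to avoid
    recomputing geomorphons when several radii are explored.
    """
    for key in ("conductivity", "ph", "pct_sand"):
        if key not in soils:
            raise ValueError(f"missing soil layer: {key}")
    for key in ("temp_march", "precip_march"):
        if key not in climate:
            raise ValueError(f"missing climate layer: {key}")

    layers: dict[str, Grid] = {}
    layers["slope"] = slope_op(dem, radius)
    layers["tpi"] = tpi_op(dem, radius)
    layers["landform"] = landform if landform is not None else geomorphons(dem)
    for key in ("conductivity", "ph", "pct_sand"):
        layers[key] = focal_stat(soils[key], radius, "mean")

    stream_mask = net.cell_mask()
    layers["dist_stream"] = distance_to(stream_mask)

    terrestrial = np.isin(landcover_grid.values, list(lc.TERRESTRIAL_CLASSES)) & (
        canopy.values < 50
    )
    if terrestrial.any():
        layers["dist_terrestrial"] = distance_to(Mask(terrestrial, landcover_grid))
    else:
        warnings.warn("no qualifying terrestrial cells; dist_terrestrial set to nodata")
        layers["dist_terrestrial"] = landcover_grid.copy_with(
            np.full(landcover_grid.shape, landcover_grid.nodata, dtype=float),
            kind="continuous",
        )

    layers["pct_developed"] = _watershed_class_pct(
        landcover_grid, watersheds, lc.DEVELOPED_INTENSITY
    )
    layers["pct_agriculture"] = _watershed_class_pct(
        landcover_grid, watersheds, lc.AGRICULTURE
    )
    layers["temp_march"] = climate["temp_march"]
    layers["precip_march"] = climate["precip_march"]
    return CovariateStack(layers)


# ---------------------------------------------------------------------------
# collinearity


def correlation_ratio(categories: np.ndarray, values: np.ndarray) -> float:
    """η — square root of (between-class variance / total variance)."""
    values = np.asarray(values, dtype=float)
    total_var = values.var()
    if total_var == 0:
        return 0.0
    grand = values.mean()
    between = 0.0
    for cat in np.unique(categories):
        sub = values[categories == cat]
        between += len(sub) * (sub.mean() - grand) ** 2
    return float(np.sqrt(between / (len(values) * total_var)))


def collinearity_screen(
    stack: CovariateStack,
    rows: np.ndarray,
    cols: np.ndarray,
    threshold: float = 0.70,
) -> pd.DataFrame:
    """Pairwise |Pearson r| (continuous pairs) and η (categorical pairs)
    over a presence+background sample; flags pairs at or above threshold.

    Zero-variance layers are excluded with a warning.
    """
    if len(rows) < 30:
        raise ValueError("need a sample of at least 30 points")
    sample = stack.sample(np.asarray(rows), np.asarray(cols))
    usable = []
    for name in stack.names:
        v = sample[name].to_numpy(float)
        if name not in CATEGORICAL_LAYERS and v.std() == 0:
            warnings.warn(f"layer {name!r} has zero variance in the sample; excluded")
            continue
        usable.append(name)
    out = []
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            a_cat = a in CATEGORICAL_LAYERS
            b_cat = b in CATEGORICAL_LAYERS
            if a_cat and b_cat:
                continue  # no categorical-categorical statistic defined
            if a_cat or b_cat:
                cat, cont = (a, b) if a_cat else (b, a)
                stat = correlation_ratio(
                    sample[cat].to_numpy(), sample[cont].to_numpy(float)
                )
                kind = "eta"
            else:
                stat = abs(
                    float(
                        np.corrcoef(
                            sample[a].to_numpy(float), sample[b].to_numpy(float)
                        )[0, 1]
                    )
                )
                kind = "pearson_r"
            out.append(
                {
                    "var_a": a,
                    "var_b": b,
                    "statistic": kind,
                    "value": stat,
                    "squared": stat**2,
                    "flagged": bool(stat >= threshold),
                }
            )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# focal-radius selection by information value


def information_value(
    presence_values: np.ndarray,
    background_values: np.ndarray,
    n_bins: int = 10,
    smoothing: float = 0.5,
) -> float:
    """Weight-of-evidence information value of one variable.

    Values are decile-binned over the pooled sample; per-bin
    ``WoE = ln((p_i/P)/(b_i/B))`` with ``smoothing`` added to empty cells,
    and ``IV = Σ (p_i/P − b_i/B)·WoE``.  Always ≥ 0; 0 iff the binned
    distributions coincide.
    """
    pres = np.asarray(presence_values, dtype=float)
    back = np.asarray(background_values, dtype=float)
    pooled = np.concatenate([pres, back])
    edges = np.unique(np.quantile(pooled, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        return 0.0
    p_counts, _ = np.histogram(pres, bins=edges)
    b_counts, _ = np.histogram(back, bins=edges)
    p = p_counts.astype(float)
    b = b_counts.astype(float)
    empty = (p == 0) | (b == 0)
    p[empty] += smoothing
    b[empty] += smoothing
    p /= p.sum()
    b /= b.sum()
    woe = np.log(p / b)
    return float(np.sum((p - b) * woe))


def select_radius(
    stacks: dict[float, CovariateStack],
    rows_pres: np.ndarray,
    cols_pres: np.ndarray,
    rows_back: np.ndarray,
    cols_back: np.ndarray,
) -> tuple[float, pd.DataFrame]:
    """Pick the focal radius whose neighborhood-derived variables carry the
    greatest total information value over presence vs. background."""
    if len(stacks) < 2:
        raise ValueError("need at least 2 candidate radii")
    if len(rows_pres) == 0:
        raise ValueError("no presence points supplied")
    records = []
    for radius, stack in sorted(stacks.items()):
        pres = stack.sample(np.asarray(rows_pres), np.asarray(cols_pres))
        back = stack.sample(np.asarray(rows_back), np.asarray(cols_back))
        for name in NEIGHBORHOOD_LAYERS:
            iv = information_value(
                pres[name].to_numpy(float), back[name].to_numpy(float)
            )
            records.append({"radius": radius, "variable": name, "iv": iv})
    table = pd.DataFrame(records)
    totals = table.groupby("radius")["iv"].sum()
    best = float(totals.idxmax())
    return best, table


# ---------------------------------------------------------------------------
# land-cover change


def change_table_from_areas(
    areas_t1: dict[str, float], areas_t2: dict[str, float]
) -> pd.DataFrame:
    """Per-class area change between two epochs.

    ``delta_relpct`` is the change in each class's share of the total
    mapped area, in percentage points:
    ``100·(A_c,t2/ΣA_t2 − A_c,t1/ΣA_t1)``.
    """
    if set(areas_t1) != set(areas_t2):
        raise ValueError("epoch legends differ")
    total1 = sum(areas_t1.values())
    total2 = sum(areas_t2.values())
    rows = []
    for name in areas_t1:
        a1, a2 = areas_t1[name], areas_t2[name]
        rows.append(
            {
                "class": name,
                "area_t1_km2": a1,
                "area_t2_km2": a2,
                "delta_km2": a2 - a1,
                "delta_relpct": 100.0 * (a2 / total2 - a1 / total1),
            }
        )
    return pd.DataFrame(rows)


def landcover_change(lc_t1: Grid, lc_t2: Grid) -> pd.DataFrame:
    """Change table between two co-registered categorical land-cover grids."""
    if not lc_t1.same_geometry(lc_t2):
        raise ValueError("land-cover grids must share geometry")
    cell_km2 = lc_t1.cell_size**2 / 1e6
    v1 = lc_t1.values[lc_t1.valid()]
    v2 = lc_t2.values[lc_t2.valid()]
    codes = sorted(set(np.unique(v1)) | set(np.unique(v2)))
    unknown = [c for c in codes if c not in lc.LEGEND]
    if unknown:
        raise ValueError(f"codes outside the shared legend: {unknown}")
    areas1 = {lc.LEGEND[c]: float((v1 == c).sum()) * cell_km2 for c in codes}
    areas2 = {lc.LEGEND[c]: float((v2 == c).sum()) * cell_km2 for c in codes}
    return change_table_from_areas(areas1, areas2)


def occurrence_change_flags(
    records: pd.DataFrame, lc_epochs: dict[int, Grid]
) -> pd.DataFrame:
    """Per-record land-cover class sequence across epochs + changed flag."""
    if len(lc_epochs) < 2:
        raise ValueError("need at least 2 land-cover epochs")
    years = sorted(lc_epochs)
    out = records.copy()
    seqs = []
    changed = []
    for _, rec in records.iterrows():
        classes = []
        for yr in years:
            g = lc_epochs[yr]
            r, c = g.rowcol_of(rec["x"], rec["y"])
            if 0 <= r < g.nrows and 0 <= c < g.ncols:
                classes.append(lc.LEGEND.get(int(g.values[r, c]), "unknown"))
            else:
                classes.append("outside")
        seqs.append(" -> ".join(classes))
        changed.append(len(set(classes)) > 1)
    out["class_sequence"] = seqs
    out["changed"] = changed
    return out
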