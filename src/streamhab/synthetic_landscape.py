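"""Self-contained synthetic world for end-to-end pipeline testing.

Generates a dissected-ravine landscape — a gently tilted upland plain
incised by dendritic ravine networks — plus every input layer the
pipeline consumes: land cover on the 15-class legend (woody wetlands
along ravine floors), canopy, soils, climate, roads, waterbodies,
protected areas, subwatersheds, projected-urbanization probabilities,
and region labels.  A known logistic suitability truth (steep,
low-lying cells in low-agriculture catchments) drives occurrence
sampling with road bias and a nymph/adult life-stage mix, so parameter
recovery can be tested without any external data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import landcover as lc
from .raster_core import Grid, Mask, write_ascii
from .terrain_hydrology import d8_flow, slope as slope_op, tpi as tpi_op
from .terrain_hydrology.flow import D8_OFFSETS, OUTLET

__all__ = ["WorldConfig", "WorldTruth", "generate_world", "true_suitability", "sample_occurrences", "write_bundle"]


@dataclasses.dataclass
class WorldConfig:
    """Knobs of the synthetic world.  ``seed`` is mandatory."""

    seed: int
    size: int = 400
    cell_size: float = 60.0
    n_ravines: int = 12
    ravine_depth: float = 25.0
    relief: float = 40.0
    road_spacing: int = 40  # mean cells between roads
    protected_fraction: float = 0.2
    agriculture_fraction: float = 0.25
    n_occurrences: int = 150
    nymph_fraction: float = 0.6
    road_bias: float = 0.25  # probability a record is forced near a road
    road_near_m: float = 100.0
    n_cities: int = 3
    # logistic truth: intercept + slope, tpi, pct_agriculture, temp terms
    suit_coefficients: tuple[float, ...] = (-4.0, 0.9, -0.35, -0.08, -0.3)

    def __post_init__(self) -> None:
        for name in ("protected_fraction", "agriculture_fraction", "nymph_fraction", "road_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclasses.dataclass
class WorldTruth:
    """All generated layers plus per-cell generation bookkeeping."""

    cfg: WorldConfig
    dem: Grid
    landcover: Grid
    canopy: Grid
    soils: dict[str, Grid]
    climate: dict[str, Grid]
    roads: Mask
    roads_dist: Grid
    waterbodies: Mask
    protected: Mask
    plantations: Mask
    watersheds: Grid
    regions: Grid
    sleuth: Grid
    carved: Mask  # ravine-incised cells
    ravine_floor: Mask  # the carved skeleton itself
    suitability: Grid | None = None


def _smooth_field(rng: np.random.Generator, n: int, sigma: float, lo: float, hi: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma)
    f = (f - f.min()) / (f.max() - f.min() + 1e-12)
    return lo + f * (hi - lo)


def _carve_skeleton(rng: np.random.Generator, n: int, n_ravines: int) -> np.ndarray:
    """Dendritic ravine skeleton from branching upslope random walks."""
    skel = np.zeros((n, n), dtype=bool)
    # walks start at the low (southern) edge region and wander north
    frontier = [
        (n - 1 - int(rng.integers(0, n // 8)), int(rng.integers(0, n)))
        for _ in range(n_ravines)
    ]
    budget = n * n_ravines  # total walk steps
    steps = 0
    while frontier and steps < budget:
        r, c = frontier.pop(int(rng.integers(len(frontier))))
        length = int(rng.integers(n // 4, (3 * n) // 4))
        for _ in range(length):
            if not (0 <= r < n and 0 <= c < n):
                break
            skel[r, c] = True
            steps += 1
            # drift north with lateral jitter
            r += -1 if rng.random() < 0.75 else int(rng.integers(0, 2))
            c += int(rng.integers(-1, 2))
            if rng.random() < 0.02 and len(frontier) < 4 * n_ravines:
                frontier.append((r, c + int(rng.integers(-2, 3))))
    return skel


def generate_world(cfg: WorldConfig) -> WorldTruth:
    """Build every layer deterministically from ``cfg.seed``."""
    n = cfg.size
    cs = cfg.cell_size
    streams = np.random.SeedSequence(cfg.seed).spawn(12)
    rngs = [np.random.default_rng(s) for s in streams]

    def make_grid(values, kind="continuous", nodata=-9999.0):
        if kind == "categorical":
            values = np.asarray(values, dtype=np.int64)
        return Grid(values=values, nodata=nodata, origin_x=0.0, origin_y=n * cs,
                    cell_size=cs, kind=kind)

    # --- terrain ---------------------------------------------------------
    rows = np.arange(n)[:, None] * np.ones((1, n))
    base = cfg.relief * (1.0 - rows / (n - 1))  # high north, low south
    noise = ndimage.gaussian_filter(rngs[0].standard_normal((n, n)), 6) * 6.0
    skel = _carve_skeleton(rngs[1], n, cfg.n_ravines)
    d_skel = ndimage.distance_transform_edt(~skel)
    carve = cfg.ravine_depth * np.exp(-(d_skel**2) / (2 * 2.0**2))
    dem_vals = base + noise - carve
    dem = make_grid(dem_vals)
    carved = Mask(d_skel <= 2.0, dem)
    floor = Mask(skel, dem)

    # --- watersheds (D8 basin labeling, small basins merged) -------------
    direction, _ = d8_flow(dem)
    dirs = direction.values
    filled_order = np.argsort(dem_vals, axis=None)  # ascending: downstream first
    labels = -np.ones((n, n), dtype=np.int64)
    next_label = 0
    for idx in filled_order:
        r, c = divmod(idx, n)
        d = dirs[r, c]
        if d == OUTLET:
            labels[r, c] = next_label
            next_label += 1
        else:
            rr, cc = r + D8_OFFSETS[d][0], c + D8_OFFSETS[d][1]
            lab = labels[rr, cc]
            if lab < 0:  # downstream not yet labeled (tie plateau); new basin
                lab = next_label
                next_label += 1
                labels[rr, cc] = lab
            labels[r, c] = lab
    # merge small basins into the nearest big one
    counts = np.bincount(labels.ravel())
    big = counts >= max(50, (n * n) // 400)
    if big.any():
        big_mask = big[labels]
        idx = ndimage.distance_transform_edt(
            ~big_mask, return_distances=False, return_indices=True
        )
        labels = labels[tuple(idx)]
    # compact label ids
    _, labels = np.unique(labels, return_inverse=True)
    watersheds = make_grid(labels.reshape(n, n), kind="categorical")

    # --- land cover ------------------------------------------------------
    ag_field = _smooth_field(rngs[2], n, 20, 0, 1)
    ag_cut = np.quantile(ag_field, 1 - cfg.agriculture_fraction)
    veg = _smooth_field(rngs[3], n, 8, 0, 1)
    lc_vals = np.full((n, n), lc.CLASS_CODES["Evergreen Forest"], dtype=np.int64)
    lc_vals[veg < 0.25] = lc.CLASS_CODES["Shrub/Scrub"]
    lc_vals[veg < 0.15] = lc.CLASS_CODES["Herbaceous"]
    lc_vals[veg > 0.85] = lc.CLASS_CODES["Mixed Forest"]
    lc_vals[veg > 0.92] = lc.CLASS_CODES["Deciduous Forest"]
    ag = ag_field >= ag_cut
    lc_vals[ag & (veg < 0.5)] = lc.CLASS_CODES["Cultivated Crops"]
    lc_vals[ag & (veg >= 0.5)] = lc.CLASS_CODES["Hay/Pasture"]
    # wetlands along ravine floors
    lc_vals[carved.values] = lc.CLASS_CODES["Woody Wetlands"]
    wet_field = _smooth_field(rngs[3], n, 4, 0, 1)
    lc_vals[carved.values & (wet_field > 0.9)] = lc.CLASS_CODES[
        "Emergent Herbaceous Wetlands"
    ]
    # waterbodies: a few smoothed blobs at low elevation
    lake_field = _smooth_field(rngs[4], n, 15, 0, 1)
    lakes = (lake_field > np.quantile(lake_field, 0.985)) & (
        dem_vals < np.quantile(dem_vals, 0.5)
    )
    lc_vals[lakes] = lc.CLASS_CODES["Open Water"]

    # cities + development
    city_seeds = np.zeros((n, n), dtype=bool)
    for _ in range(cfg.n_cities):
        city_seeds[int(rngs[5].integers(n)), int(rngs[5].integers(n))] = True
    d_city = ndimage.distance_transform_edt(~city_seeds) * cs
    urban_core = d_city < 900
    urban_fringe = (d_city >= 900) & (d_city < 1800)
    dev_noise = rngs[5].random((n, n))
    lc_vals[urban_core & (dev_noise < 0.6)] = lc.CLASS_CODES["Developed, Medium Intensity"]
    lc_vals[urban_core & (dev_noise < 0.2)] = lc.CLASS_CODES["Developed, High Intensity"]
    lc_vals[urban_core & (dev_noise >= 0.6)] = lc.CLASS_CODES["Developed, Low Intensity"]
    lc_vals[urban_fringe & (dev_noise < 0.25)] = lc.CLASS_CODES["Developed, Open Space"]
    barren = (dev_noise > 0.995) & ~urban_core
    lc_vals[barren] = lc.CLASS_CODES["Barren Land"]
    landcover_grid = make_grid(lc_vals, kind="categorical")
    waterbodies = Mask(lc_vals == lc.CLASS_CODES["Open Water"], dem)

    # --- canopy: dense in forest, open elsewhere -------------------------
    canopy_vals = _smooth_field(rngs[6], n, 5, 0, 100)
    forest = np.isin(lc_vals, [41, 42, 43, 90])
    canopy_vals = np.where(forest, 40 + canopy_vals * 0.6, canopy_vals * 0.45)
    # keep a band of open evergreen/shrub/grass (terrestrial habitat exists)
    canopy = make_grid(canopy_vals)

    # --- plantations: evergreen blocks outside protected areas -----------
    plant_field = _smooth_field(rngs[6], n, 10, 0, 1)
    plantations = Mask(
        (plant_field > np.quantile(plant_field, 0.85)) & (lc_vals == 42), dem
    )

    # --- soils / climate -------------------------------------------------
    soils = {
        "conductivity": make_grid(_smooth_field(rngs[7], n, 10, 0.5, 8.0)),
        "ph": make_grid(_smooth_field(rngs[7], n, 12, 4.0, 7.5)),
        "pct_sand": make_grid(_smooth_field(rngs[7], n, 8, 20.0, 95.0)),
    }
    temp = 14.0 + 4.0 * rows / (n - 1) + ndimage.gaussian_filter(
        rngs[8].standard_normal((n, n)), 20
    )
    precip = _smooth_field(rngs[8], n, 25, 80.0, 160.0)
    climate = {"temp_march": make_grid(temp), "precip_march": make_grid(precip)}

    # --- roads: straight-ish polylines spanning the grid -----------------
    road = np.zeros((n, n), dtype=bool)
    n_roads = max(2, n // cfg.road_spacing)
    for _ in range(n_roads):
        if rngs[9].random() < 0.5:
            r0, r1 = rngs[9].integers(n, size=2)
            pts = np.linspace([r0, 0], [r1, n - 1], 4 * n)
        else:
            c0, c1 = rngs[9].integers(n, size=2)
            pts = np.linspace([0, c0], [n - 1, c1], 4 * n)
        rr = np.clip(np.rint(pts[:, 0]).astype(int), 0, n - 1)
        cc = np.clip(np.rint(pts[:, 1]).astype(int), 0, n - 1)
        road[rr, cc] = True
    roads = Mask(road, dem)
    roads_dist = make_grid(ndimage.distance_transform_edt(~road) * cs)

    # --- protected areas: smooth blobs hitting the target fraction -------
    prot_field = _smooth_field(rngs[10], n, 18, 0, 1)
    protected = Mask(
        prot_field > np.quantile(prot_field, 1 - cfg.protected_fraction), dem
    )

    # --- projected urbanization ------------------------------------------
    sleuth_vals = 100.0 * np.exp(-d_city / 4000.0)
    sleuth_vals += _smooth_field(rngs[11], n, 10, 0, 15)
    sleuth = make_grid(np.clip(sleuth_vals, 0, 100))

    # --- regions: three vertical bands (stand-ins for states) ------------
    regions = make_grid(
        np.repeat(
            np.repeat([[0, 1, 2]], n, axis=0),
            [n - 2 * (n // 3), n // 3, n // 3],
            axis=1,
        ),
        kind="categorical",
    )

    return WorldTruth(
        cfg=cfg,
        dem=dem,
        landcover=landcover_grid,
        canopy=canopy,
        soils=soils,
        climate=climate,
        roads=roads,
        roads_dist=roads_dist,
        waterbodies=waterbodies,
        protected=protected,
        plantations=plantations,
        watersheds=watersheds,
        regions=regions,
        sleuth=sleuth,
        carved=carved,
        ravine_floor=floor,
    )


def true_suitability(world: WorldTruth, coefficients=None) -> Grid:
    """Logistic suitability truth on the generating covariates.

    ``coefficients`` = (intercept, slope°, TPI, %agriculture, centered
    March temperature).  Steep, low-TPI cells in low-agriculture
    catchments score high.
    """
    cfg = world.cfg
    b0, b_slope, b_tpi, b_ag, b_temp = coefficients or cfg.suit_coefficients
    slope_g = slope_op(world.dem, radius=2 * cfg.cell_size)
    tpi_g = tpi_op(world.dem, radius=2 * cfg.cell_size)
    ws = world.watersheds.values
    ag_member = np.isin(world.landcover.values, list(lc.AGRICULTURE))
    pct_ag = np.zeros_like(ws, dtype=float)
    for wid in np.unique(ws):
        sel = ws == wid
        pct_ag[sel] = 100.0 * ag_member[sel].mean()
    temp = world.climate["temp_march"].values
    eta = (
        b0
        + b_slope * slope_g.values
        + b_tpi * tpi_g.values
        + b_ag * pct_ag
        + b_temp * (temp - temp.mean())
    )
    suit = 1.0 / (1.0 + np.exp(-eta))
    grid = world.dem.copy_with(suit, kind="continuous")
    world.suitability = grid
    return grid


def sample_occurrences(
    world: WorldTruth,
    n: int | None = None,
    nymph_frac: float | None = None,
    road_bias: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw occurrence records from the suitability truth.

    Candidate cells are ravine-floor cells; draw weight is proportional
    to true suitability.  With probability ``road_bias`` a record is
    drawn from the near-road candidate subset only (observer bias);
    nymphs stay on the ravine floor, adults are displaced up to 300 m
    to a cell at least as high (they were seen away from the breeding
    reach, upslope).
    """
    cfg = world.cfg
    n = cfg.n_occurrences if n is None else n
    nymph_frac = cfg.nymph_fraction if nymph_frac is None else nymph_frac
    road_bias = cfg.road_bias if road_bias is None else road_bias
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    if world.suitability is None:
        true_suitability(world)
    suit = world.suitability.values
    rows, cols = np.nonzero(world.ravine_floor.values)
    if n > len(rows):
        raise ValueError(f"asked for {n} occurrences but only {len(rows)} candidate cells")
    w = suit[rows, cols]
    w = w / w.sum()
    near_road = world.roads_dist.values[rows, cols] <= cfg.road_near_m
    g = world.dem
    records = []
    chosen: set[int] = set()
    while len(records) < n:
        if road_bias > 0 and near_road.any() and rng.random() < road_bias:
            pool = np.nonzero(near_road)[0]
            pw = w[pool] / w[pool].sum()
            i = int(rng.choice(pool, p=pw))
        else:
            i = int(rng.choice(len(rows), p=w))
        if i in chosen:
            continue
        chosen.add(i)
        r, c = int(rows[i]), int(cols[i])
        x, y = g.xy_of(r, c)
        stage = "nymph" if rng.random() < nymph_frac else "adult"
        if stage == "adult":
            # displace up to 300 m, preferring a not-lower cell
            for _ in range(20):
                ang = rng.random() * 2 * np.pi
                dist = rng.random() * 300.0
                xx = float(x) + dist * np.cos(ang)
                yy = float(y) + dist * np.sin(ang)
                rr, cc = g.rowcol_of(xx, yy)
                if 0 <= rr < g.nrows and 0 <= cc < g.ncols and g.values[rr, cc] >= g.values[r, c]:
                    x, y = xx, yy
                    break
        records.append(
            {
                "x": float(x),
                "y": float(y),
                "year": int(rng.integers(2008, 2025)),
                "life_stage": stage,
                "source": "survey" if stage == "nymph" else "community",
            }
        )
    return pd.DataFrame(records)


def write_bundle(world: WorldTruth, directory: str | Path) -> None:
    """Write the complete input bundle (text rasters + truth JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_ascii(world.dem, directory / "dem.asc")
    write_ascii(world.landcover, directory / "landcover.asc")
    write_ascii(world.canopy, directory / "canopy.asc")
    for name, g in world.soils.items():
        write_ascii(g, directory / f"soil_{name}.asc")
    for name, g in world.climate.items():
        write_ascii(g, directory / f"{name}.asc")
    write_ascii(world.roads_dist, directory / "roads_dist.asc")
    write_ascii(world.watersheds, directory / "watersheds.asc")
    write_ascii(world.regions, directory / "regions.asc")
    write_ascii(world.sleuth, directory / "sleuth.asc")
    for name, mask in (
        ("roads", world.roads),
        ("waterbodies", world.waterbodies),
        ("protected", world.protected),
        ("plantations", world.plantations),
        ("carved", world.carved),
        ("ravine_floor", world.ravine_floor),
    ):
        write_ascii(mask.grid, directory / f"{name}.asc")
    if world.suitability is not None:
        write_ascii(world.suitability, directory / "suitability.asc")
    (directory / "world.json").write_text(
        json.dumps(dataclasses.asdict(world.cfg), indent=2)
    )
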