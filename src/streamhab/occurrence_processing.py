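"""Occurrence record cleaning, stream snapping, and per-reach thinning.

Records travel through the pipeline as a :class:`pandas.DataFrame` with
columns ``x, y, year, life_stage, source, reach_id, status``.  Every drop
is recorded in ``status`` as ``dropped:<reason>`` so filtering is fully
auditable; retained records have ``status == "retained"`` and a reach id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .raster_core import Grid, Mask
from .terrain_hydrology.network import FlowlineNetwork

__all__ = ["clean", "snap_to_network", "thin_per_reach", "nn_summary"]

COLUMNS = ["x", "y", "year", "life_stage", "source", "reach_id", "status"]

RETAINED = "retained"


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    for col, default in (("reach_id", pd.NA), ("status", RETAINED), ("source", "")):
        if col not in df.columns:
            df[col] = default
    bad = ~df["life_stage"].isin(["nymph", "adult"])
    if bad.any():
        raise ValueError(f"unknown life_stage values: {df.loc[bad, 'life_stage'].unique()}")
    return df


def clean(records: pd.DataFrame, study_area: Mask) -> pd.DataFrame:
    """Drop exact duplicates and records outside the study area.

    Duplicates share (x, y, year, life_stage); the first occurrence (after
    a canonical sort, so input order is irrelevant) is kept.
    """
    df = _prepare(records)
    df = df.sort_values(["x", "y", "year", "life_stage", "source"], kind="stable")
    df = df.reset_index(drop=True)
    dup = df.duplicated(subset=["x", "y", "year", "life_stage"], keep="first")
    df.loc[dup, "status"] = "dropped:duplicate"

    active = df["status"] == RETAINED
    inside = np.zeros(len(df), dtype=bool)
    g = study_area.grid
    xs, ys = df["x"].to_numpy(float), df["y"].to_numpy(float)
    within = g.contains(xs, ys)
    rows, cols = g.rowcol_of(xs, ys)
    ok = within.copy()
    ok[within] = study_area.values[rows[within], cols[within]]
    inside[:] = ok
    df.loc[active & ~inside, "status"] = "dropped:out_of_area"
    return df


def snap_to_network(
    records: pd.DataFrame,
    net: FlowlineNetwork,
    dem: Grid,
    max_dist: float = 300.0,
) -> pd.DataFrame:
    """Assign records to stream reaches; move adults downslope onto them.

    Adults are relocated to the nearest network cell within ``max_dist``
    that is not higher than the cell they currently occupy (records of
    flying adults do not mark breeding sites, but the breeding reach lies
    downslope).  Nymphs keep their coordinates and take the nearest reach
    within ``max_dist``.  Records with no qualifying reach are dropped.
    """
    df = records.copy()
    active = df["status"] == RETAINED
    if net.is_empty():
        df.loc[active, "status"] = "dropped:no_reach"
        return df

    cells = []
    seg_ids = []
    for s in net.segments:
        for rc in s.cells:
            cells.append(rc)
            seg_ids.append(s.seg_id)
    cells = np.asarray(cells, dtype=int)
    seg_ids = np.asarray(seg_ids)
    xy = net.cell_xy(cells.astype(float))
    tree = cKDTree(xy)
    cell_elev = dem.values[cells[:, 0], cells[:, 1]].astype(float)

    for i in df.index[active]:
        x, y = float(df.at[i, "x"]), float(df.at[i, "y"])
        idxs = tree.query_ball_point([x, y], r=max_dist)
        if not idxs:
            df.at[i, "status"] = "dropped:no_reach"
            continue
        idxs = np.asarray(idxs)
        d = np.hypot(xy[idxs, 0] - x, xy[idxs, 1] - y)
        if df.at[i, "life_stage"] == "adult":
            r0, c0 = dem.rowcol_of(x, y)
            here = (
                float(dem.values[r0, c0])
                if 0 <= r0 < dem.nrows and 0 <= c0 < dem.ncols
                else np.inf
            )
            ok = cell_elev[idxs] <= here + 1e-9
            if not ok.any():
                df.at[i, "status"] = "dropped:no_reach"
                continue
            idxs, d = idxs[ok], d[ok]
            j = idxs[np.argmin(d)]
            df.at[i, "x"], df.at[i, "y"] = float(xy[j, 0]), float(xy[j, 1])
        else:
            j = idxs[np.argmin(d)]
        df.at[i, "reach_id"] = int(seg_ids[j])
    return df


def thin_per_reach(records: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep one record per reach: nymphs beat adults, remaining ties are
    broken uniformly at random (seeded, after a canonical sort)."""
    df = records.copy()
    active = df["status"] == RETAINED
    if df.loc[active, "reach_id"].isna().any():
        raise ValueError("all retained records must carry a reach_id before thinning")
    rng = np.random.default_rng(seed)
    sub = df.loc[active].sort_values(
        ["reach_id", "x", "y", "year", "life_stage", "source"], kind="stable"
    )
    for reach, group in sub.groupby("reach_id", sort=True):
        nymphs = group[group["life_stage"] == "nymph"]
        pool = nymphs if len(nymphs) else group
        winner = pool.index[rng.integers(len(pool))]
        losers = group.index.difference([winner])
        df.loc[losers, "status"] = "dropped:thinned"
    return df


def nn_summary(records: pd.DataFrame) -> tuple[float, float]:
    """Mean and standard error (sd/√n) of nearest-neighbor distances (m)
    among retained records."""
    pts = records.loc[records["status"] == RETAINED, ["x", "y"]].to_numpy(float)
    if len(pts) < 2:
        raise ValueError("need at least 2 retained records")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    nn = d[:, 1]
    se = float(nn.std(ddof=1) / np.sqrt(len(nn))) if len(nn) > 1 else 0.0
    return float(nn.mean()), se
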