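"""Flowline network extraction, Strahler ordering, and rules-based cleaning."""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from ..raster_core import Grid, Mask
from .flow import D8_OFFSETS, OUTLET
from .terrain import VALLEY_CLASSES

__all__ = [
    "Segment",
    "FlowlineNetwork",
    "extract_flowlines",
    "compute_strahler",
    "clean_flowlines",
    "reference_distance_stats",
]


@dataclasses.dataclass
class Segment:
    """A stream reach: an ordered run of cells between network nodes."""

    seg_id: int
    cells: list[tuple[int, int]]
    length_m: float
    sinuosity: float
    strahler_order: int = 1
    kept: bool = True
    removal_rule: int = 0  # 0 = retained, 1..5 = cleaning rule that removed it

    @staticmethod
    def from_cells(seg_id: int, cells: list[tuple[int, int]], cell_size: float) -> "Segment":
        pts = np.asarray(cells, dtype=float) * cell_size
        if len(pts) > 1:
            steps = np.diff(pts, axis=0)
            length = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
            chord = float(np.hypot(*(pts[-1] - pts[0])))
        else:
            length = 0.0
            chord = 0.0
        if chord == 0.0:
            sinuosity = 1.0 if length == 0.0 else float("inf")
        else:
            sinuosity = length / chord
        return Segment(seg_id, list(cells), length, sinuosity)


class FlowlineNetwork:
    """Collection of stream segments on a shared raster geometry."""

    def __init__(self, segments: list[Segment], like: Grid):
        self.segments = segments
        self.cell_size = like.cell_size
        self.origin_x = like.origin_x
        self.origin_y = like.origin_y
        self.shape = like.shape
        self._like = like

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def is_empty(self) -> bool:
        return not self.segments

    def cells(self) -> np.ndarray:
        """(n, 2) array of all member cells across segments (may repeat nodes)."""
        if not self.segments:
            return np.empty((0, 2), dtype=int)
        return np.vstack([np.asarray(s.cells, dtype=int) for s in self.segments])

    def cell_mask(self) -> Mask:
        m = np.zeros(self.shape, dtype=bool)
        cells = self.cells()
        if len(cells):
            m[cells[:, 0], cells[:, 1]] = True
        return Mask(m, self._like)

    def cell_xy(self, cells: np.ndarray) -> np.ndarray:
        x = self.origin_x + (cells[:, 1] + 0.5) * self.cell_size
        y = self.origin_y - (cells[:, 0] + 0.5) * self.cell_size
        return np.column_stack([x, y])

    def subset(self, keep: list[Segment]) -> "FlowlineNetwork":
        return FlowlineNetwork(keep, self._like)

    # -- serialization (GeoJSON LineStrings, world coordinates) ----------
    def to_geojson(self, path: str | Path) -> None:
        feats = []
        for s in self.segments:
            xy = self.cell_xy(np.asarray(s.cells, dtype=float))
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [[float(x), float(y)] for x, y in xy],
                    },
                    "properties": {
                        "seg_id": s.seg_id,
                        "strahler_order": s.strahler_order,
                        "length_m": round(s.length_m, 3),
                        "sinuosity": (
                            s.sinuosity if np.isfinite(s.sinuosity) else None
                        ),
                        "kept": s.kept,
                        "removal_rule": s.removal_rule,
                    },
                }
            )
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": feats})
        )


def compute_strahler(upstream: dict[int, list[int]]) -> dict[int, int]:
    """Strahler orders for a segment DAG given per-segment upstream lists.

    A segment with no inflows has order 1.  A segment whose two highest
    inflow orders are equal takes that order plus one; otherwise it takes
    the maximum inflow order.
    """
    orders: dict[int, int] = {}

    ready = [s for s, ups in upstream.items() if not ups]
    deps = {s: len(ups) for s, ups in upstream.items()}
    children: dict[int, list[int]] = {s: [] for s in upstream}
    for s, ups in upstream.items():
        for u in ups:
            children[u].append(s)
    while ready:
        s = ready.pop()
        ups = upstream[s]
        if not ups:
            orders[s] = 1
        else:
            vals = sorted((orders[u] for u in ups), reverse=True)
            if len(vals) >= 2 and vals[0] == vals[1]:
                orders[s] = vals[0] + 1
            else:
                orders[s] = vals[0]
        for ch in children[s]:
            deps[ch] -= 1
            if deps[ch] == 0:
                ready.append(ch)
    return orders


def extract_flowlines(
    accumulation: Grid,
    direction: Grid,
    threshold: int = 300,
    max_order: int = 2,
) -> FlowlineNetwork:
    """Trace stream segments from D8 accumulation and direction grids.

    Cells at or above the accumulation ``threshold`` form the stream
    lattice; runs of cells between heads, junctions, and outlets become
    segments.  Strahler orders are assigned on the segment graph and only
    headwater segments (order ≤ ``max_order``) are retained.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    acc = accumulation.values
    valid = accumulation.valid()
    stream = valid & (acc != accumulation.nodata) & (acc >= threshold)
    nr, nc = stream.shape
    dirs = direction.values

    def downstream(r: int, c: int):
        d = dirs[r, c]
        if d == OUTLET:
            return None
        rr, cc = r + D8_OFFSETS[d][0], c + D8_OFFSETS[d][1]
        if 0 <= rr < nr and 0 <= cc < nc and stream[rr, cc]:
            return rr, cc
        return None

    inflow = np.zeros((nr, nc), dtype=np.int64)
    for r, c in zip(*np.nonzero(stream)):
        ds = downstream(r, c)
        if ds is not None:
            inflow[ds] += 1

    # segment start cells: heads (no stream inflow) and junctions (>= 2)
    starts = [
        (r, c)
        for r, c in zip(*np.nonzero(stream))
        if inflow[r, c] == 0 or inflow[r, c] >= 2
    ]
    segments: list[Segment] = []
    seg_of_start: dict[tuple[int, int], int] = {}
    ends: dict[int, tuple[int, int] | None] = {}
    for start in sorted(starts):
        cells = [start]
        cur = start
        while True:
            nxt = downstream(*cur)
            if nxt is None:
                ends[len(segments)] = None
                break
            cells.append(nxt)
            if inflow[nxt] >= 2:  # junction: ends here, next segment starts here
                ends[len(segments)] = nxt
                break
            cur = nxt
        seg = Segment.from_cells(len(segments), cells, accumulation.cell_size)
        seg_of_start[start] = seg.seg_id
        segments.append(seg)

    upstream: dict[int, list[int]] = {s.seg_id: [] for s in segments}
    for s in segments:
        end = ends[s.seg_id]
        if end is not None and end in seg_of_start:
            upstream[seg_of_start[end]].append(s.seg_id)
    orders = compute_strahler(upstream)
    for s in segments:
        s.strahler_order = orders.get(s.seg_id, 1)
    kept = [s for s in segments if s.strahler_order <= max_order]
    return FlowlineNetwork(kept, accumulation)


# ---------------------------------------------------------------------------
# cleaning cascade


def _segment_points(net: FlowlineNetwork, seg: Segment) -> np.ndarray:
    return net.cell_xy(np.asarray(seg.cells, dtype=float))


def reference_distance_stats(
    net: FlowlineNetwork, reference: FlowlineNetwork
) -> tuple[float, float, float]:
    """(mean, sd, mean + 2·sd) of per-segment nearest distances to a reference
    network — the outlier radius used to pick the rule-3 cutoff."""
    if reference.is_empty():
        raise ValueError("reference network is empty")
    tree = cKDTree(reference.cell_xy(reference.cells().astype(float)))
    dists = np.array(
        [tree.query(_segment_points(net, s))[0].min() for s in net.segments]
    )
    mean = float(dists.mean())
    sd = float(dists.std(ddof=1)) if len(dists) > 1 else 0.0
    return mean, sd, mean + 2 * sd


def clean_flowlines(
    net: FlowlineNetwork,
    waterbodies: Mask,
    reference: FlowlineNetwork | None,
    landform: Grid,
    woody_wetland: Mask,
    *,
    min_straight_len: float = 300.0,
    max_sinuosity: float = 1.01,
    reference_dist: float = 3000.0,
    short_len: float = 100.0,
    isolation_dist: float = 1500.0,
) -> FlowlineNetwork:
    """Apply the five artifact-removal rules, in order.

    1. drop segments lying (majority of cells) inside waterbody interiors;
    2. drop long straight artifacts: length ≥ ``min_straight_len`` and
       sinuosity ≤ ``max_sinuosity``;
    3. keep only segments within ``reference_dist`` of the reference
       network (skipped with a warning when no reference is given);
    4. keep segments with a majority of cells in landform classes 6-10 and
       at least one cell 8-adjacent to (or inside) woody wetland;
    5. drop segments shorter than ``short_len`` whose nearest surviving
       neighbor segment is farther than ``isolation_dist`` (iterated to a
       fixpoint so the filter is idempotent).

    The result is a pure subset of the input; removed segments are
    annotated with the rule that removed them (``removal_rule``).
    """
    survivors: list[Segment] = []
    for s in net.segments:
        s.kept = True
        s.removal_rule = 0
        cells = np.asarray(s.cells, dtype=int)
        in_water = waterbodies.values[cells[:, 0], cells[:, 1]]
        if in_water.mean() > 0.5:
            s.kept, s.removal_rule = False, 1
            continue
        if s.length_m >= min_straight_len and s.sinuosity <= max_sinuosity:
            s.kept, s.removal_rule = False, 2
            continue
        survivors.append(s)

    if reference is None or reference.is_empty():
        warnings.warn("empty reference network: rule 3 skipped")
    else:
        tree = cKDTree(reference.cell_xy(reference.cells().astype(float)))
        next_surv = []
        for s in survivors:
            d = tree.query(_segment_points(net, s))[0].min()
            if d <= reference_dist:
                next_surv.append(s)
            else:
                s.kept, s.removal_rule = False, 3
        survivors = next_surv

    wet_adj = ndimage.binary_dilation(
        woody_wetland.values, structure=np.ones((3, 3), dtype=bool)
    )
    next_surv = []
    for s in survivors:
        cells = np.asarray(s.cells, dtype=int)
        lf = landform.values[cells[:, 0], cells[:, 1]]
        majority_valley = np.isin(lf, list(VALLEY_CLASSES)).mean() > 0.5
        touches_wet = wet_adj[cells[:, 0], cells[:, 1]].any()
        if majority_valley and touches_wet:
            next_surv.append(s)
        else:
            s.kept, s.removal_rule = False, 4
    survivors = next_surv

    # rule 5: iterate until stable (dropping one spur can isolate another)
    changed = True
    while changed:
        changed = False
        if len(survivors) > 1:
            trees = {
                s.seg_id: cKDTree(_segment_points(net, s)) for s in survivors
            }
            keep5 = []
            for s in survivors:
                if s.length_m >= short_len:
                    keep5.append(s)
                    continue
                pts = _segment_points(net, s)
                nearest = min(
                    trees[o.seg_id].query(pts)[0].min()
                    for o in survivors
                    if o.seg_id != s.seg_id
                )
                if nearest <= isolation_dist:
                    keep5.append(s)
                else:
                    s.kept, s.removal_rule = False, 5
                    changed = True
            survivors = keep5
        elif len(survivors) == 1 and survivors[0].length_m < short_len:
            survivors[0].kept, survivors[0].removal_rule = False, 5
            survivors = []
            changed = False
    return net.subset(survivors)
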