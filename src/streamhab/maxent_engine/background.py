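"""Bias-matched background sampling.

Presence records cluster in stream-valley landforms and near roads (the
observers drove there), so an unbiased background sample would make the
model learn the observation bias instead of habitat.  Background points
are therefore drawn from the same landform classes the presences occupy
(codes 6-10) with sampling weight decaying exponentially with road
distance, mirroring the bias in the presence data.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..raster_core import Grid
from ..terrain_hydrology.terrain import VALLEY_CLASSES

__all__ = ["sample_background"]


def sample_background(
    landform: Grid,
    roads_dist: Grid,
    n: int = 10000,
    tau: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample background cells from landform classes 6-10.

    Selection weight is ``exp(−d_road/τ)``; ``tau=None`` (or ∞) gives a
    uniform draw.  Sampling is without replacement (weighted reservoir via
    exponential keys); if fewer eligible cells exist than ``n``, all are
    returned with a warning.

    Returns ``(rows, cols)`` arrays of sampled cell indices.
    """
    eligible = np.isin(landform.values, list(VALLEY_CLASSES)) & landform.valid()
    rows, cols = np.nonzero(eligible)
    if len(rows) == 0:
        raise ValueError("no cells in landform classes 6-10")
    rng = np.random.default_rng(seed)
    if len(rows) <= n:
        warnings.warn(
            f"only {len(rows)} eligible cells for {n} background points; using all"
        )
        return rows, cols
    if tau is None or not np.isfinite(tau):
        w = np.ones(len(rows))
    else:
        d = roads_dist.values[rows, cols].astype(float)
        w = np.exp(-d / tau)
        w = np.maximum(w, 1e-300)
    # weighted sampling without replacement: smallest exponential(1/w) keys win
    keys = rng.exponential(1.0, size=len(rows)) / w
    pick = np.argpartition(keys, n)[:n]
    return rows[pick], cols[pick]
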