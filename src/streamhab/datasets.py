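"""Bundled reference datasets."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_landcover_areas"]


def load_landcover_areas() -> pd.DataFrame:
    """Published per-class land-cover areas (km²) of the study region for
    the 2008 / 2019 / 2024 map epochs, on the 15-class legend.

    Columns: ``class, area_2008_km2, area_2019_km2, area_2024_km2``.
    """
    with resources.files("streamhab.data").joinpath(
        "landcover_class_areas.csv"
    ).open() as fh:
        return pd.read_csv(fh)
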