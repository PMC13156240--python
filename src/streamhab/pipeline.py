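"""End-to-end pipeline driver.

Stages are lazy cached properties on :class:`Pipeline`, so any CLI
subcommand can run exactly the prefix of the pipeline it needs.  Every
filtering stage logs its input/output counts.
"""

from __future__ import annotations

import json
import logging
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariate_builder as cov
from . import gap_analysis as gap
from . import habitat_delineation as hab
from . import model_evaluation as ev
from . import occurrence_processing as occ
from .maxent_engine import crossvalidate, sample_background, select_model
from .raster_core import Mask, write_ascii
from .synthetic_landscape import (
    WorldConfig,
    generate_world,
    sample_occurrences,
    true_suitability,
    write_bundle,
)
from .terrain_hydrology import (
    clean_flowlines,
    d8_flow,
    extract_flowlines,
    geomorphons,
)
from .terrain_hydrology.network import FlowlineNetwork, Segment

log = logging.getLogger("streamhab")

DEFAULTS = {
    "seed": 0,
    "out_dir": "streamhab_out",
    "world": {},
    "flow_threshold": 100,
    "radius": 120.0,
    "radius_candidates": [60.0, 120.0, 540.0],
    "background": {"n": 4000, "tau": 1500.0},
    "model": {"classes": "LQHP", "rm": 1.0, "n_hinge": 8, "cv_folds": 5,
              "select": False},
    "snap_max_dist": 300.0,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


class Pipeline:
    def __init__(self, config: dict | None = None):
        self.cfg = _merge(DEFAULTS, config or {})
        self.seed = int(self.cfg["seed"])
        self.out = Path(self.cfg["out_dir"])
        self.out.mkdir(parents=True, exist_ok=True)

    # -- synth ------------------------------------------------------------
    @cached_property
    def world(self):
        wcfg = WorldConfig(seed=self.seed, **self.cfg["world"])
        log.info("generating world: %dx%d cells, seed %d", wcfg.size, wcfg.size, self.seed)
        world = generate_world(wcfg)
        true_suitability(world)
        return world

    def run_synth(self) -> Path:
        d = self.out / "world"
        write_bundle(self.world, d)
        log.info("world bundle written to %s", d)
        return d

    # -- terrain / hydrology ----------------------------------------------
    @cached_property
    def landform(self):
        return geomorphons(self.world.dem)

    @cached_property
    def flow(self):
        return d8_flow(self.world.dem)

    @cached_property
    def raw_network(self):
        direction, acc = self.flow
        net = extract_flowlines(acc, direction, threshold=int(self.cfg["flow_threshold"]))
        log.info("extracted %d headwater segments", len(net))
        return net

    @cached_property
    def reference_network(self):
        # stand-in for a coarse national flowline layer: the true ravine floor
        cells = list(zip(*np.nonzero(self.world.ravine_floor.values)))
        seg = Segment.from_cells(0, cells, self.world.dem.cell_size)
        return FlowlineNetwork([seg], self.world.dem)

    @cached_property
    def network(self):
        woody = Mask(
            self.world.landcover.values == 90, self.world.dem
        )
        net = clean_flowlines(
            self.raw_network,
            self.world.waterbodies,
            self.reference_network,
            self.landform,
            woody,
        )
        log.info("cleaned flowlines: %d -> %d segments", len(self.raw_network), len(net))
        return net

    def run_terrain(self) -> Path:
        direction, acc = self.flow
        write_ascii(self.landform, self.out / "landform.asc")
        write_ascii(acc, self.out / "flow_accumulation.asc")
        self.raw_network.to_geojson(self.out / "flowlines_raw.geojson")
        self.network.to_geojson(self.out / "flowlines_clean.geojson")
        return self.out

    # -- occurrences ------------------------------------------------------
    @cached_property
    def records(self):
        raw = sample_occurrences(self.world, seed=self.seed + 1)
        study = Mask(np.ones(self.world.dem.shape, dtype=bool), self.world.dem)
        cleaned = occ.clean(raw, study)
        snapped = occ.snap_to_network(
            cleaned, self.network, self.world.dem, max_dist=float(self.cfg["snap_max_dist"])
        )
        thinned = occ.thin_per_reach(snapped, seed=self.seed + 2)
        kept = (thinned["status"] == occ.RETAINED).sum()
        log.info("occurrences: %d raw -> %d retained", len(raw), kept)
        return thinned

    def run_occ(self) -> Path:
        path = self.out / "occurrences.csv"
        self.records.to_csv(path, index=False)
        return path

    # -- covariates -------------------------------------------------------
    @cached_property
    def stack(self):
        return cov.build_stack(
            self.world.dem,
            self.world.landcover,
            self.world.canopy,
            self.world.soils,
            self.world.climate,
            self.network,
            self.world.watersheds,
            radius=float(self.cfg["radius"]),
            landform=self.landform,
        )

    def run_covariates(self) -> Path:
        d = self.out / "covariates"
        self.stack.save(d)
        return d

    # -- model fit --------------------------------------------------------
    @cached_property
    def presence_cells(self):
        kept = self.records[self.records["status"] == occ.RETAINED]
        g = self.world.dem
        rows, cols = g.rowcol_of(kept["x"].to_numpy(float), kept["y"].to_numpy(float))
        return rows, cols

    @cached_property
    def background_cells(self):
        bg = self.cfg["background"]
        return sample_background(
            self.landform,
            self.world.roads_dist,
            n=int(bg["n"]),
            tau=bg["tau"],
            seed=self.seed + 3,
        )

    @cached_property
    def samples(self):
        pr, pc = self.presence_cells
        br, bc = self.background_cells
        return self.stack.sample(pr, pc), self.stack.sample(br, bc)

    @cached_property
    def cv(self):
        pres, back = self.samples
        mcfg = self.cfg["model"]
        return crossvalidate(
            mcfg["classes"],
            pres,
            back,
            k=int(mcfg["cv_folds"]),
            rm=float(mcfg["rm"]),
            seed=self.seed + 4,
            n_hinge=int(mcfg["n_hinge"]),
        )

    @cached_property
    def model(self):
        pres, back = self.samples
        mcfg = self.cfg["model"]
        if mcfg.get("select"):
            model, records = select_model(
                pres, back, n_hinge=int(mcfg["n_hinge"])
            )
            log.info("model selection: best rm=%.2g, k=%d", model.rm, model.k)
            return model
        from .maxent_engine import fit, make_features

        pooled = pd.concat([pres, back], ignore_index=True)
        features = make_features(
            pooled, n_presence=len(pres), classes=mcfg["classes"],
            n_hinge=int(mcfg["n_hinge"]),
        )
        return fit(features, pres, back, rm=float(mcfg["rm"]))

    @cached_property
    def suitability_map(self):
        return self.cv.mean_map(self.stack)

    def run_fit(self) -> Path:
        self.model.to_json(self.out / "model.json")
        write_ascii(self.suitability_map, self.out / "suitability.asc")
        return self.out

    # -- evaluation -------------------------------------------------------
    @cached_property
    def report(self):
        pres, back = self.samples
        return ev.evaluate(self.cv, self.model, pres, back, seed=self.seed + 5)

    def run_evaluate(self) -> Path:
        self.report.to_json(self.out / "evaluation.json")
        self.report.importance.to_csv(self.out / "importance.csv", index=False)
        return self.out

    # -- habitat delineation ----------------------------------------------
    @cached_property
    def habitat(self):
        breeding = hab.refine(
            self.suitability_map, self.report.threshold_ess, self.world.landcover
        )
        model = hab.extend_terrestrial(
            breeding, self.world.landcover, self.world.canopy
        )
        log.info(
            "habitat: breeding %.1f km2, terrestrial %.1f km2, combined %.1f km2",
            model.breeding_km2, model.terrestrial_km2, model.combined_km2,
        )
        return model

    def run_delineate(self) -> Path:
        d = self.out / "habitat"
        self.habitat.save(d)
        return d

    # -- gap analysis -----------------------------------------------------
    @cached_property
    def gap_reports(self):
        return gap.gap_summary(
            self.habitat,
            self.world.protected,
            self.world.landcover,
            self.world.sleuth,
            plantations=self.world.plantations,
            regions=self.world.regions,
        )

    def run_gap(self) -> Path:
        d = self.out / "gap"
        d.mkdir(parents=True, exist_ok=True)
        for component, report in self.gap_reports.items():
            report.to_csv(d / component)
            report.to_json(d / f"{component}.json")
        return d

    def run_all(self) -> Path:
        self.run_synth()
        self.run_terrain()
        self.run_occ()
        self.run_covariates()
        self.run_fit()
        self.run_evaluate()
        self.run_delineate()
        self.run_gap()
        summary = {
            "n_occurrences_retained": int((self.records["status"] == occ.RETAINED).sum()),
            "auc_test_mean": self.report.auc_test_mean,
            "tss": self.report.tss,
            "sedi": self.report.sedi,
            "threshold_ess": self.report.threshold_ess,
            **self.habitat.areas(),
        }
        (self.out / "summary.json").write_text(json.dumps(summary, indent=2))
        return self.out
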