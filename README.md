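# streamhab

Multi-scale habitat modeling and conservation gap analysis for
stream-breeding species on gridded landscapes.

The package implements a complete, reproducible pipeline:

1. **Synthetic landscape** (`streamhab.synthetic_landscape`) — generates a
   dissected-ravine world (DEM, 15-class land cover, canopy, soils,
   climate, roads, waterbodies, protected areas, subwatersheds,
   projected-urbanization probabilities) plus occurrence samples drawn
   from a known suitability truth, so every stage is testable without
   external data.
2. **Terrain & hydrology** (`streamhab.terrain_hydrology`) — slope/TPI
   neighborhood statistics, ternary-pattern landform classification
   (10 classes), priority-flood depression filling, D8 flow routing,
   headwater flowline extraction with Strahler ordering, and a five-rule
   flowline-cleaning cascade.
3. **Occurrence processing** (`streamhab.occurrence_processing`) —
   duplicate/out-of-area cleaning, downslope snapping of adult records to
   stream reaches, one-record-per-reach thinning (nymphs preferred),
   nearest-neighbor summaries.
4. **Covariates** (`streamhab.covariate_builder`) — the 12-layer stack
   (topography, soils, distances, catchment land-use percentages,
   climate), Pearson/η collinearity screening, focal-radius selection by
   weight-of-evidence information value, and land-cover change tables.
5. **Maximum-entropy model** (`streamhab.maxent_engine`) — from-scratch
   presence–background estimation with linear/quadratic/product/hinge/
   categorical features, L1 regularization (exact, via split-variable
   bounded L-BFGS), bias-matched background sampling, raw and cloglog
   outputs, AICc model selection, and k-fold cross-validation.
6. **Evaluation** (`streamhab.model_evaluation`) — ROC/AUC
   (Mann–Whitney), equal-sensitivity/specificity thresholding, TSS,
   SEDI, accuracy, permutation importance, percent contribution,
   response curves.
7. **Habitat delineation** (`streamhab.habitat_delineation`) —
   binarization, exact two-class natural-breaks refinement, isolated-
   patch and urban-embedded filters, and terrestrial-habitat extension.
8. **Gap analysis** (`streamhab.gap_analysis`) — protected-area
   coverage, adjacent land-use exposure, and projected-urbanization
   threat per region and habitat component.

Rasters are exchanged as ESRI ASCII grids (plain text, readable by any
GIS); flowline networks as GeoJSON; models as JSON; tables as CSV.

## CLI

Every stage is a subcommand of one driver, configured by a single YAML
file with a global `seed` (see `streamhab.pipeline.DEFAULTS` for keys):

```bash
streamhab -v all --config config.yaml --out outputs/
# or stage by stage:
streamhab synth --seed 7 --out outputs/
streamhab terrain --seed 7 --out outputs/
streamhab fit --seed 7 --out outputs/
streamhab gap --seed 7 --out outputs/
```

Example `config.yaml`:

```yaml
seed: 7
world: {size: 200, n_occurrences: 300}
flow_threshold: 60
radius: 120
background: {n: 4000, tau: 1500.0}
model: {classes: LQHP, rm: 1.0, n_hinge: 8, cv_folds: 10}
```

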