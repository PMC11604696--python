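# isletquant

Quantitative analysis of multiplex immunofluorescence images of pancreatic
islets, with two complementary arms:

- **Whole-islet arm** (`isletquant.isletlevel`): channel alignment,
  illumination correction, Otsu islet detection on the summed endocrine
  marker channels, background subtraction from the islet mask, per-islet
  occupied-area fractions, intensities and thresholded Manders
  co-localisation coefficients.
- **Single-cell arm** (`isletquant.celllevel`): nucleus detection
  (Laplacian-of-Gaussian seeding + watershed), bounded Voronoi cell
  expansion, per-cell mean intensities and morphometry (cytoplasm /
  nucleus areas, N/C ratio), per-batch intensity thresholds with
  combinatorial phenotyping (single/double/triple-positive classes),
  per-cell co-localisation, proinsulin/insulin intensity ratios and
  peri-islet exocrine morphometry.
- **Statistics** (`isletquant.stats`): donor-level aggregation (the donor
  is the statistical unit), normality-gated one-way ANOVA (Tukey) /
  Kruskal–Wallis (Dunn + Holm) comparisons, random-intercept
  mixed-effects contrasts, and phenotype-trajectory tables across
  disease-stage groups.
- **Synthetic generator** (`isletquant.synthgen`): multiplex IF islet
  images with complete per-cell ground truth — islets of ≥ 10 cells
  embedded in exocrine tissue, type-specific morphometry and marker
  models, a granule-sharing co-localisation model with an analytic
  Manders expectation, background, illumination gradients, channel
  misalignment and noise.  Donor-group presets (`ND`, `AAb+`,
  `T1D_recent`, `T1D_long`, `T2D`) encode published group-level effect
  directions and magnitudes.

Two staining panels are modelled: panel A (insulin / proinsulin / PC1/3)
and panel B (glucagon / somatostatin / PC1/3), both with a nuclear
counterstain channel. Images are multi-page TIFF with channel and
pixel-calibration metadata; all tables are CSV.

## CLI

```sh
# render a synthetic two-group cohort with ground truth
isletquant generate --out data --groups ND,T1D_long --panel A \
    --n-donors 3 --islets-per-donor 2 --seed 1

# run one arm on an existing cohort
isletquant analyze-islets --in data --out results
isletquant analyze-cells  --in data --out results

# group statistics on a pipeline summary table
isletquant stats --summaries run/donor_summaries.csv \
    --metric beta_cytoplasm_area_um2 --out stats.csv

# full pipeline (generate -> analyze -> stats -> trajectory) from a YAML config
isletquant run --config pipeline.yaml
```

A pipeline config is a flat YAML mapping of `PipelineConfig` fields
(`seed`, `panel`, `min_cells`, `expansion_um`, threshold overrides, an
optional `generate:` block, …). Every run directory contains the CSV
outputs, a `resolved_config.yaml` snapshot and a plain-text log; re-runs
with the same config and seed are byte-identical.

## Acceptance

The published cohort values were measured on donor images that are not
publicly deposited, so acceptance is property-based: see
`tests/test_acceptance.py` (Otsu oracle equivalence, Manders closed
forms, segmentation/phenotype/morphometry recovery on synthetic truth,
statistical calibration, conservation laws, determinism).

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs an end-to-end health check and writes the (empty) target report —
there are no desk-recomputable published targets.
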