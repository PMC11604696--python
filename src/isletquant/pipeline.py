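"""Configuration-driven orchestration: generate -> analyze-islets ->
analyze-cells -> stats, with a resolved-config snapshot and a plain-text
log for provenance.  Re-running with the same config and seed reproduces
every CSV byte-for-byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import celllevel, isletlevel, stats as statsmod
from .image import MultiChannelImage
from .synthgen import make_group_preset, render_cohort
from .synthgen.config import NUCLEAR_CHANNEL, PANEL_CHANNELS

__all__ = ["PipelineConfig", "PipelineError", "analyze_donor_images", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Resolved parameters for one pipeline run."""

    input_dir: str = ""
    output_dir: str = "run"
    seed: int = 0
    panel: str = "A"
    min_cells: int = 10
    expansion_um: float = 5.0
    expected_nucleus_diameter_um: float = 6.0
    illumination_scale_um: float = 50.0
    align: bool = True
    threshold_overrides: dict[str, float] = field(default_factory=dict)
    manual_cell_thresholds: dict[str, float] = field(default_factory=dict)
    cell_threshold_method: str = "hybrid"   # min(otsu, gmm); both fail high
    exclude_sst_cells: bool = True     # delta cells are islet-level only
    peri_islet_um: float = 20.0
    median_cell_area_um2: float = isletlevel.DEFAULT_MEDIAN_CELL_AREA_UM2
    donor_statistic: str = "mean"
    metrics: list[str] = field(default_factory=list)
    # optional generation stage
    generate: dict | None = None
    manual_corrections: bool = False   # provenance flag: no manual step exists

    def __post_init__(self) -> None:
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")
        if self.panel not in PANEL_CHANNELS:
            raise ValueError(f"panel must be one of {sorted(PANEL_CHANNELS)}")

    @property
    def marker_channels(self) -> list[str]:
        return PANEL_CHANNELS[self.panel]

    @property
    def manders_pairs(self) -> list[tuple[str, str]]:
        # PC1/3 as channel A by convention
        if self.panel == "A":
            return [("pc13", "ins")]
        return [("pc13", "gcg"), ("pc13", "sst")]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# per-donor analysis


def _preprocess(image: MultiChannelImage, config: PipelineConfig) -> MultiChannelImage:
    if config.align:
        image, _ = isletlevel.align_channels(image, NUCLEAR_CHANNEL)
    if config.illumination_scale_um > 0:
        planes = np.stack(
            [
                isletlevel.correct_illumination(
                    p, config.illumination_scale_um, image.pixel_size_um
                )
                for p in image.planes
            ]
        )
        image = image.with_planes(planes)
    return image


def analyze_donor_images(
    images: list[tuple[str, MultiChannelImage]],
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run both quantification arms over one donor's images.

    Returns ``(islet_table, cell_table)``; cell thresholds are derived
    once per donor (the staining batch) from the pooled cell means.
    """
    markers = config.marker_channels
    islet_rows: list[pd.DataFrame] = []
    stash: list[dict] = []
    for image_id, raw in images:
        image = _preprocess(raw, config)
        islet_df, islets, corrected, px_thresholds = isletlevel.measure_image_islets(
            image,
            markers,
            min_cells=config.min_cells,
            threshold_overrides=config.threshold_overrides or None,
            manders_pairs=config.manders_pairs,
            median_cell_area_um2=config.median_cell_area_um2,
        )
        if len(islet_df):
            islet_df.insert(0, "image_id", image_id)
            islet_rows.append(islet_df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nuc_labels, nuc_table = celllevel.detect_nuclei(
                corrected.plane(NUCLEAR_CHANNEL),
                corrected.pixel_size_um,
                expected_diameter_um=config.expected_nucleus_diameter_um,
                islet_masks=islets,
            )
        cell_labels = celllevel.expand_cells(
            nuc_labels,
            nuc_table,
            islets,
            corrected.pixel_size_um,
            max_expansion_um=config.expansion_um,
        )
        cells = celllevel.measure_cells(
            cell_labels, nuc_labels, nuc_table, corrected, islet_masks=islets
        )
        if len(cells):
            cells.insert(0, "image_id", image_id)
        stash.append(
            {
                "image_id": image_id,
                "image": corrected,
                "cell_labels": cell_labels,
                "islets": islets,
                "px_thresholds": px_thresholds,
                "cells": cells,
            }
        )
    islet_table = (
        pd.concat(islet_rows, ignore_index=True) if islet_rows else pd.DataFrame()
    )
    pooled = pd.concat(
        [s["cells"] for s in stash if len(s["cells"])], ignore_index=True
    ) if any(len(s["cells"]) for s in stash) else pd.DataFrame()
    if not len(pooled):
        return islet_table, pooled

    # one threshold per channel per donor (staining batch); estimated from
    # core islet cells so rim exocrine nuclei cannot fake a negative mode
    if "core_islet" in pooled.columns:
        endo = pooled[pooled["core_islet"]]
    else:
        endo = pooled[pooled["endocrine_candidate"]]
    thresholds: dict[str, float] = {}
    for ch in markers:
        if ch in config.manual_cell_thresholds:
            thresholds[ch] = float(config.manual_cell_thresholds[ch])
            continue
        source = endo if len(endo) >= 20 else pooled
        try:
            thresholds[ch] = celllevel.determine_cell_thresholds(
                source, ch, method=config.cell_threshold_method
            )
        except celllevel.NoPositivePopulation:
            # batch carries no positive mode for this marker: nothing is flagged
            thresholds[ch] = float(np.inf)
        except (ValueError, isletlevel.DegenerateHistogramError):
            # degenerate batch: fall back to the pixel-level islet threshold
            candidates = [
                s["px_thresholds"][ch]
                for s in stash
                if np.isfinite(s["px_thresholds"].get(ch, np.nan))
            ]
            thresholds[ch] = float(np.median(candidates)) if candidates else np.inf
    pooled = celllevel.classify_cells(pooled, thresholds, markers)

    # per-cell Manders on the configured pairs, per image
    cell_frames = []
    for s in stash:
        cells = pooled[pooled["image_id"] == s["image_id"]]
        if not len(cells):
            continue
        for a, b in config.manders_pairs:
            if not s["px_thresholds"]:
                continue
            cells = celllevel.cells_manders(
                cells, s["cell_labels"], s["image"], a, b, s["px_thresholds"]
            )
        peri = celllevel.peri_islet_exocrine_cells(
            cells,
            s["islets"],
            s["image"].pixel_size_um,
            max_distance_um=config.peri_islet_um,
        )
        cells = cells.copy()
        cells["peri_islet"] = cells["cell_id"].isin(peri["cell_id"]) & ~cells[
            "endocrine_candidate"
        ]
        cell_frames.append(cells)
    cell_table = pd.concat(cell_frames, ignore_index=True)
    if config.panel == "A":
        cell_table["proins_ins_ratio"] = celllevel.proinsulin_insulin_ratio(cell_table)
    for ch in markers:
        cell_table[f"threshold_{ch}"] = thresholds[ch]
    if config.panel == "B" and config.exclude_sst_cells:
        cell_table = cell_table[
            ~(cell_table["endocrine_candidate"] & cell_table["flag_sst"])
        ].reset_index(drop=True)
    return islet_table, cell_table


# ---------------------------------------------------------------------------
# donor summaries


def summarize_donor(
    cell_table: pd.DataFrame,
    islet_table: pd.DataFrame,
    config: PipelineConfig,
    peri_areas: pd.Series | None = None,
) -> dict[str, float]:
    """Donor-level metric values (one number per metric)."""
    markers = config.marker_channels
    out: dict[str, float] = {}
    endo = cell_table[
        cell_table["endocrine_candidate"] & (cell_table["islet_id"] >= 0)
    ] if len(cell_table) else cell_table
    n_islet_cells = len(endo)
    if n_islet_cells:
        for ch in markers:
            out[f"{ch}_positive_cell_fraction"] = float(endo[f"flag_{ch}"].mean())
        all_pos = np.ones(n_islet_cells, dtype=bool)
        for ch in markers:
            all_pos &= endo[f"flag_{ch}"].to_numpy()
        out["triple_positive_cell_fraction"] = float(all_pos.mean())
        if config.panel == "A":
            ins_pos = endo[endo["flag_ins"]]
            if len(ins_pos):
                out["beta_cytoplasm_area_um2"] = float(ins_pos["cytoplasm_area_um2"].mean())
                out["beta_nucleus_area_um2"] = float(ins_pos["nucleus_area_um2"].median())
                out["beta_nc_ratio"] = float(ins_pos["nc_ratio"].median())
            ratios = endo["proins_ins_ratio"].dropna()
            if len(ratios):
                out["proins_ins_ratio"] = float(ratios.median())
        else:
            gcg_pos = endo[endo["flag_gcg"]]
            if len(gcg_pos):
                out["alpha_cytoplasm_area_um2"] = float(gcg_pos["cytoplasm_area_um2"].mean())
                out["alpha_nc_ratio"] = float(gcg_pos["nc_ratio"].mean())
        for a, b in config.manders_pairs:
            col = f"manders_m1_{a}_{b}"
            if col in endo.columns:
                vals = endo[col].dropna()
                if len(vals):
                    out[f"cell_{col}"] = float(vals.mean())
        cells_per_islet = endo.groupby(["image_id", "islet_id"]).size()
        out["cells_per_islet"] = float(cells_per_islet.mean())
    if len(islet_table):
        out["islet_area_um2"] = float(islet_table["area_um2"].median())
        for ch in markers:
            out[f"islet_area_fraction_{ch}"] = float(
                islet_table[f"area_fraction_{ch}"].mean()
            )
            out[f"islet_mean_intensity_{ch}"] = float(
                islet_table[f"mean_intensity_{ch}"].mean()
            )
        for a, b in config.manders_pairs:
            col = f"manders_m1_{a}_{b}"
            if col in islet_table.columns:
                out[f"islet_{col}"] = float(islet_table[col].mean())
    if peri_areas is None and len(cell_table) and "peri_islet" in cell_table.columns:
        peri_areas = cell_table.loc[cell_table["peri_islet"], "cell_area_um2"]
    if peri_areas is not None and len(peri_areas):
        out["peri_islet_exocrine_area_um2"] = float(peri_areas.mean())
    return out


_DEFAULT_METRICS_A = [
    "beta_cytoplasm_area_um2",
    "beta_nc_ratio",
    "ins_positive_cell_fraction",
    "pc13_positive_cell_fraction",
    "triple_positive_cell_fraction",
    "proins_ins_ratio",
    "islet_area_fraction_ins",
    "cell_manders_m1_pc13_ins",
]
_DEFAULT_METRICS_B = [
    "alpha_cytoplasm_area_um2",
    "gcg_positive_cell_fraction",
    "pc13_positive_cell_fraction",
    "islet_area_fraction_gcg",
    "islet_area_fraction_sst",
    "cell_manders_m1_pc13_gcg",
]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the run directory.

    The directory holds ``islets.csv``, ``cells.csv``,
    ``donor_summaries.csv``, ``stats.csv``, ``trajectory.csv``, a
    ``resolved_config.yaml`` snapshot and ``run.log``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"seed={config.seed}", f"panel={config.panel}"]
    log_lines.append(f"manual_corrections={config.manual_corrections}")

    # ---- stage: generate --------------------------------------------
    input_dir = Path(config.input_dir) if config.input_dir else out / "data"
    if config.generate is not None:
        gen = dict(config.generate)
        groups = gen.get("groups", ["ND", "T1D_long"])
        overrides = gen.get("preset_overrides", {})
        try:
            config_per_group = {
                g: make_group_preset(g, panel=config.panel, **overrides) for g in groups
            }
            render_cohort(
                config_per_group,
                n_donors_per_group=int(gen.get("n_donors_per_group", 2)),
                islets_per_donor=int(gen.get("islets_per_donor", 2)),
                seed=config.seed,
                out_dir=input_dir,
            )
        except Exception as exc:
            raise PipelineError(f"stage 'generate' failed: {exc}") from exc
        log_lines.append(f"generated cohort in {input_dir}")

    meta_path = input_dir / "metadata.csv"
    if not meta_path.exists():
        raise PipelineError(f"stage 'load' failed: no metadata at {meta_path}")
    metadata = pd.read_csv(meta_path)

    # ---- stage: analyze ---------------------------------------------
    islet_frames, cell_frames, summary_rows = [], [], []
    for _, drow in metadata.sort_values("donor_id").iterrows():
        donor_id = drow["donor_id"]
        donor_dir = input_dir / donor_id
        tiffs = sorted(donor_dir.glob("*.tif*"))
        images = [(p.stem, MultiChannelImage.load(p)) for p in tiffs]
        try:
            islet_df, cell_df = analyze_donor_images(images, config)
        except Exception as exc:
            raise PipelineError(f"stage 'analyze' failed for {donor_id}: {exc}") from exc
        peri = None
        if len(cell_df):
            cell_df.insert(0, "donor_id", donor_id)
            cell_df["group"] = drow["group"]
            cell_frames.append(cell_df)
        if len(islet_df):
            islet_df.insert(0, "donor_id", donor_id)
            islet_df["group"] = drow["group"]
            islet_frames.append(islet_df)
        summary = summarize_donor(cell_df, islet_df, config, peri_areas=peri)
        for metric, value in summary.items():
            summary_rows.append(
                {
                    "donor_id": donor_id,
                    "group": drow["group"],
                    "metric": metric,
                    "value": value,
                }
            )
        log_lines.append(f"analyzed {donor_id}: {len(islet_df)} islets, {len(cell_df)} cells")

    islets_csv = pd.concat(islet_frames, ignore_index=True) if islet_frames else pd.DataFrame()
    cells_csv = pd.concat(cell_frames, ignore_index=True) if cell_frames else pd.DataFrame()
    summaries = pd.DataFrame(summary_rows)
    islets_csv.to_csv(out / "islets.csv", index=False)
    cells_csv.to_csv(out / "cells.csv", index=False)
    summaries.to_csv(out / "donor_summaries.csv", index=False)

    # ---- stage: stats -----------------------------------------------
    metrics = config.metrics or (
        _DEFAULT_METRICS_A if config.panel == "A" else _DEFAULT_METRICS_B
    )
    stat_rows = []
    for metric in metrics:
        if "metric" not in summaries.columns:
            break
        sub = summaries[summaries["metric"] == metric]
        if not len(sub):
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = statsmod.compare_groups(sub, metric=metric)
        except ValueError as exc:
            log_lines.append(f"stats skipped for {metric}: {exc}")
            continue
        stat_rows.append(
            {
                "metric": metric,
                "groups": "|".join(result.groups),
                "test_used": result.test_used,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "normality": "|".join(
                    f"{g}:{int(v)}" for g, v in sorted(result.normality.items())
                ),
            }
        )
    pd.DataFrame(stat_rows).to_csv(out / "stats.csv", index=False)

    # ---- stage: trajectory ------------------------------------------
    if len(cells_csv):
        count_rows = []
        markers = config.marker_channels
        for (donor, group), sub in cells_csv.groupby(["donor_id", "group"]):
            endo = sub[sub["endocrine_candidate"] & (sub["islet_id"] >= 0)]
            pc = celllevel.phenotype_counts(endo, markers)
            pc.insert(0, "donor_id", donor)
            pc.insert(1, "group", group)
            count_rows.append(pc)
        counts = pd.concat(count_rows, ignore_index=True)
        counts.to_csv(out / "phenotype_counts.csv", index=False)
        trajectory = statsmod.phenotype_trajectory(counts)
        trajectory.to_csv(out / "trajectory.csv", index=False)
    else:
        pd.DataFrame().to_csv(out / "trajectory.csv", index=False)

    config.save(out / "resolved_config.yaml")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
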