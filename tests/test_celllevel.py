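"""Single-cell arm: nucleus detection, expansion, measurement,
thresholding, classification, co-localisation, morphometry."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from isletquant import celllevel
from isletquant.celllevel import (
    NoPositivePopulation,
    cell_manders,
    classify_cells,
    detect_nuclei,
    determine_cell_thresholds,
    expand_cells,
    measure_cells,
    peri_islet_exocrine_cells,
    phenotype_class,
    phenotype_counts,
    proinsulin_insulin_ratio,
)
from isletquant.image import MultiChannelImage
from isletquant.isletlevel import DegenerateHistogramError
from isletquant.synthgen import render_islet_image
from conftest import clean_preset, small_preset

PX = 0.5


def _disk_plane(shape, centers, radius_px, value=30000.0):
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    plane = np.zeros(shape)
    for cy, cx in centers:
        plane[(ys - cy) ** 2 + (xs - cx) ** 2 <= radius_px**2] = value
    return plane


class TestDetectNuclei:
    def test_exact_count_noiseless(self, clean_image_truth):
        image, truth = clean_image_truth
        labels, table = detect_nuclei(image.plane("dapi"), image.pixel_size_um)
        assert len(table) == len(truth)

    def test_blank_plane_empty(self):
        with pytest.warns(UserWarning, match="blank"):
            labels, table = detect_nuclei(np.zeros((64, 64)), PX)
        assert labels.max() == 0
        assert len(table) == 0

    def test_overlapping_pair_split_by_watershed(self):
        # two nuclei overlapping by < 20% of their area
        plane = _disk_plane((64, 64), [(32, 26), (32, 37)], radius_px=7)
        labels, table = detect_nuclei(plane, PX, expected_diameter_um=7.0)
        assert len(table) == 2

    def test_endocrine_tagging(self, clean_image_truth):
        image, truth = clean_image_truth
        mask = np.zeros(image.shape, dtype=bool)
        half = truth["centroid_row"] < image.shape[0] / 2
        # islet mask = everything: all candidates endocrine
        mask[:, :] = True
        _, table = detect_nuclei(image.plane("dapi"), PX, islet_masks=[mask])
        assert table["endocrine_candidate"].all()


class TestExpandCells:
    def test_single_nucleus_disc_growth(self):
        labels = np.zeros((96, 96), dtype=np.int32)
        ys, xs = np.mgrid[0:96, 0:96]
        nucleus = (ys - 48) ** 2 + (xs - 48) ** 2 <= 6**2
        labels[nucleus] = 1
        table = pd.DataFrame(
            [{"nucleus_id": 1, "endocrine_candidate": False, "core_islet": False,
              "centroid_row": 48.0, "centroid_col": 48.0,
              "nucleus_area_um2": nucleus.sum() * PX**2}]
        )
        cells = expand_cells(labels, table, None, PX, max_expansion_um=5.0)
        grown = (cells == 1).sum()
        expected = np.pi * (6 + 5.0 / PX) ** 2
        assert grown == pytest.approx(expected, rel=0.05)
        assert ((cells == 1) | ~nucleus).all()

    def test_voronoi_boundary_equidistant(self):
        labels = np.zeros((96, 96), dtype=np.int32)
        ys, xs = np.mgrid[0:96, 0:96]
        # two identical nuclei 4 um (8 px) apart with 5 um expansion
        for i, cx in enumerate((44, 52), start=1):
            labels[(ys - 48) ** 2 + (xs - cx) ** 2 <= 3**2] = i
        table = pd.DataFrame(
            [
                {"nucleus_id": i, "endocrine_candidate": False, "core_islet": False,
                 "centroid_row": 48.0, "centroid_col": cx, "nucleus_area_um2": 1.0}
                for i, cx in ((1, 44.0), (2, 52.0))
            ]
        )
        cells = expand_cells(labels, table, None, PX, max_expansion_um=5.0)
        # the shared boundary is the midline: no cell crosses x = 48
        assert (np.nonzero(cells == 1)[1] <= 48).all()
        assert (np.nonzero(cells == 2)[1] >= 48).all()
        # equidistant midline column goes to one label deterministically
        assert abs((cells == 1).sum() - (cells == 2).sum()) <= 30

    def test_containment_and_disjoint(self, clean_image_truth):
        image, _ = clean_image_truth
        labels, table = detect_nuclei(image.plane("dapi"), PX)
        cells = expand_cells(labels, table, None, PX)
        assert ((labels == 0) | (cells == labels)).all()  # nucleus subset cell

    def test_cytoplasm_correlates_with_truth(self):
        # noiseless cohort spanning the disease size range: per-cell
        # recovery through the full pipeline, r > 0.9
        from isletquant.pipeline import PipelineConfig, analyze_donor_images

        det, tru = [], []
        for group, seed in (("ND", 5), ("T1D_long", 7)):
            cfg = clean_preset(group, n_islets=2, image_shape_px=(384, 384))
            cfg.cell_type_fractions = {"beta": 1.0, "alpha": 0.0, "delta": 0.0}
            image, truth = render_islet_image(cfg, seed=seed)
            _, cells = analyze_donor_images([("im", image)], PipelineConfig())
            endo = cells[cells["endocrine_candidate"] & (cells["islet_id"] >= 0)]
            tree = cKDTree(truth[["centroid_row", "centroid_col"]].to_numpy())
            d, idx = tree.query(endo[["centroid_row", "centroid_col"]].to_numpy())
            keep = d < 6
            det.append(endo.loc[keep, "cytoplasm_area_um2"].to_numpy())
            tru.append(truth["cytoplasm_area_um2"].to_numpy()[idx[keep]])
        r = np.corrcoef(np.concatenate(det), np.concatenate(tru))[0, 1]
        assert r > 0.9


class TestMeasureCells:
    def _toy(self):
        cell = np.zeros((40, 40), dtype=np.int32)
        nuc = np.zeros((40, 40), dtype=np.int32)
        cell[5:25, 5:29] = 1          # 480 px = 120 um^2
        nuc[10:20, 10:22] = 1         # 120 px = 30 um^2
        table = pd.DataFrame(
            [{"nucleus_id": 1, "endocrine_candidate": True, "core_islet": True,
              "centroid_row": 14.5, "centroid_col": 15.5,
              "nucleus_area_um2": 30.0}]
        )
        plane = np.where(cell > 0, 100.0, 0.0)
        img = MultiChannelImage(plane[None], ["ins"], PX)
        return cell, nuc, table, img

    def test_uniform_intensity_mean(self):
        cell, nuc, table, img = self._toy()
        cells = measure_cells(cell, nuc, table, img)
        assert cells.loc[0, "mean_ins"] == pytest.approx(100.0)

    def test_compartment_arithmetic(self):
        cell, nuc, table, img = self._toy()
        cells = measure_cells(cell, nuc, table, img)
        assert cells.loc[0, "cell_area_um2"] == pytest.approx(120.0)
        assert cells.loc[0, "nucleus_area_um2"] == pytest.approx(30.0)
        assert cells.loc[0, "cytoplasm_area_um2"] == pytest.approx(90.0)
        assert cells.loc[0, "nc_ratio"] == pytest.approx(1 / 3)

    def test_zero_pixel_cell_errors(self):
        cell, nuc, table, img = self._toy()
        cell[:] = 0
        with pytest.raises(ValueError, match="zero pixels"):
            measure_cells(cell, nuc, table, img)


class TestThresholds:
    def test_bimodal_simulation_accuracy(self, rng):
        neg = rng.normal(20, 5, 300)
        pos = rng.normal(150, 20, 300)
        cells = pd.DataFrame({"mean_ins": np.concatenate([neg, pos])})
        truth = np.array([False] * 300 + [True] * 300)
        t = determine_cell_thresholds(cells, "ins")
        assert 45 < t < 120
        acc = ((cells["mean_ins"] >= t) == truth).mean()
        assert acc >= 0.98

    def test_manual_threshold_all_negative(self, rng):
        cells = pd.DataFrame({"mean_ins": rng.normal(20, 5, 100)})
        t = determine_cell_thresholds(cells, "ins", method="manual", manual_value=50)
        flagged = classify_cells(cells, {"ins": t}, ["ins"])
        assert flagged["flag_ins"].sum() == 0

    def test_otsu_matches_brute_force(self, rng):
        from test_isletlevel import brute_force_otsu

        vals = np.concatenate([rng.normal(30, 8, 150), rng.normal(160, 25, 100)])
        cells = pd.DataFrame({"mean_ins": vals})
        t = determine_cell_thresholds(cells, "ins", method="otsu")
        assert t == brute_force_otsu(vals)

    def test_too_few_cells_errors(self):
        cells = pd.DataFrame({"mean_ins": np.arange(10.0)})
        with pytest.raises(ValueError, match=">= 20"):
            determine_cell_thresholds(cells, "ins")

    def test_degenerate_distribution_errors(self):
        cells = pd.DataFrame({"mean_ins": np.full(50, 42.0)})
        with pytest.raises(DegenerateHistogramError):
            determine_cell_thresholds(cells, "ins")

    def test_no_positive_mode_raises(self, rng):
        cells = pd.DataFrame({"mean_ins": rng.lognormal(np.log(1000), 0.2, 80)})
        with pytest.raises(NoPositivePopulation):
            determine_cell_thresholds(cells, "ins")


class TestClassify:
    def test_triple_positive(self):
        cells = pd.DataFrame(
            [{"mean_ins": 200.0, "mean_proins": 180.0, "mean_pc13": 150.0}]
        )
        out = classify_cells(cells, {"ins": 50, "proins": 50, "pc13": 50},
                             ["ins", "proins", "pc13"])
        assert out.loc[0, "phenotype"] == "ins+proins+pc13+"

    def test_triple_negative(self):
        cells = pd.DataFrame(
            [{"mean_ins": 10.0, "mean_proins": 20.0, "mean_pc13": 5.0}]
        )
        out = classify_cells(cells, {"ins": 50, "proins": 50, "pc13": 50},
                             ["ins", "proins", "pc13"])
        assert out.loc[0, "phenotype"] == "triple-negative"

    def test_tie_at_threshold_is_positive(self):
        cells = pd.DataFrame([{"mean_ins": 50.0}])
        out = classify_cells(cells, {"ins": 50.0}, ["ins"])
        assert bool(out.loc[0, "flag_ins"])

    def test_missing_threshold_names_channel(self):
        cells = pd.DataFrame([{"mean_ins": 1.0, "mean_pc13": 1.0}])
        with pytest.raises(KeyError, match="pc13"):
            classify_cells(cells, {"ins": 50}, ["ins", "pc13"])

    def test_partition_invariant(self, rng):
        n = 200
        cells = pd.DataFrame(
            {f"mean_{ch}": rng.lognormal(5, 1, n) for ch in ("ins", "proins", "pc13")}
        )
        out = classify_cells(cells, {"ins": 150, "proins": 150, "pc13": 150},
                             ["ins", "proins", "pc13"])
        counts = phenotype_counts(out, ["ins", "proins", "pc13"])
        assert len(counts) == 8
        assert counts["n_cells"].sum() == n

    def test_monotone_in_threshold(self, rng):
        cells = pd.DataFrame({"mean_ins": rng.lognormal(5, 1, 300)})
        prev = None
        for t in np.linspace(10, 1000, 25):
            n_pos = int(classify_cells(cells, {"ins": t}, ["ins"])["flag_ins"].sum())
            if prev is not None:
                assert n_pos <= prev
            prev = n_pos

    def test_phenotype_class_pure_function(self):
        order = ["a", "b"]
        assert phenotype_class({"a": True, "b": False}, order) == "a+b-"
        assert phenotype_class({"a": False, "b": False}, order) == "triple-negative"


class TestCellManders:
    def test_identical_channels(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        plane = np.where(mask, 80.0, 0.0)
        img = MultiChannelImage(np.stack([plane, plane]), ["a", "b"], PX)
        m1, m2 = cell_manders(mask, img, "a", "b", {"a": 40, "b": 40})
        assert m1 == 1.0 and m2 == 1.0

    def test_disjoint_channels(self):
        mask = np.ones((20, 20), dtype=bool)
        a = np.zeros((20, 20))
        b = np.zeros((20, 20))
        a[:10] = 50.0
        b[10:] = 50.0
        img = MultiChannelImage(np.stack([a, b]), ["a", "b"], PX)
        m1, m2 = cell_manders(mask, img, "a", "b", {"a": 25, "b": 25})
        assert m1 == 0.0 and m2 == 0.0

    def test_granule_sharing_analytic(self):
        # coloc fraction 0.8: expected per-cell M1 = c + b(1-c)
        cfg = clean_preset(n_islets=1, image_shape_px=(320, 320), noise_sd=0.0)
        cfg.cell_type_fractions = {"beta": 1.0, "alpha": 0.0, "delta": 0.0}
        for ch in ("ins", "pc13"):
            cfg.marker_models["beta"][ch].p_positive = 1.0
        cfg.coloc_fraction = {"pc13+ins": 0.8}
        expected = 0.8 + cfg.baseline_fraction * 0.2
        vals = []
        for seed in (1, 2):
            image, truth = render_islet_image(cfg, seed=seed)
            labels, table = detect_nuclei(image.plane("dapi"), PX)
            cells_lab = expand_cells(labels, table, None, PX)
            cells = measure_cells(cells_lab, labels, table, image)
            thr = {
                "pc13": 0.5 * truth["intensity_pc13"].median() * 65535,
                "ins": 0.5 * truth["intensity_ins"].median() * 65535,
            }
            out = celllevel.cells_manders(
                cells, cells_lab, image, "pc13", "ins", thr, only_positive=False
            )
            vals.append(out["manders_m1_pc13_ins"].mean())
        assert np.mean(vals) == pytest.approx(expected, abs=0.05)


class TestRatioAndPeriIslet:
    def test_ratio_arithmetic(self):
        cells = pd.DataFrame(
            [
                {"mean_proins": 50.0, "mean_ins": 100.0, "flag_ins": True},
                {"mean_proins": 70.0, "mean_ins": 70.0, "flag_ins": True},
                {"mean_proins": 10.0, "mean_ins": 0.0, "flag_ins": False},
            ]
        )
        r = proinsulin_insulin_ratio(cells)
        assert r.iloc[0] == pytest.approx(0.5)
        assert r.iloc[1] == pytest.approx(1.0)
        assert np.isnan(r.iloc[2])

    def test_generator_proportional_ratio(self):
        cfg = clean_preset(n_islets=2, image_shape_px=(384, 384))
        cfg.cell_type_fractions = {"beta": 1.0, "alpha": 0.0, "delta": 0.0}
        for ch in ("ins", "proins"):
            cfg.marker_models["beta"][ch].p_positive = 1.0
        cfg.marker_models["beta"]["proins"].scale_of = "ins"
        cfg.marker_models["beta"]["proins"].scale_factor = 0.8
        medians = []
        for seed in (1, 2, 3):
            image, _ = render_islet_image(cfg, seed=seed)
            labels, table = detect_nuclei(image.plane("dapi"), PX)
            cells_lab = expand_cells(labels, table, None, PX)
            cells = measure_cells(cells_lab, labels, table, image)
            cells["flag_ins"] = True
            medians.append(proinsulin_insulin_ratio(cells).median())
        assert np.mean(medians) == pytest.approx(0.8, abs=0.05)

    def test_peri_islet_distance_filter(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[80:120, 80:120] = True  # islet; boundary at x=120
        cells = pd.DataFrame(
            [
                # 5 um (10 px) outside the boundary -> included
                {"cell_id": 1, "endocrine_candidate": False,
                 "centroid_row": 100.0, "centroid_col": 130.0,
                 "cell_area_um2": 90.0},
                # 50 um (100 px) outside -> excluded
                {"cell_id": 2, "endocrine_candidate": False,
                 "centroid_row": 100.0, "centroid_col": 199.0,
                 "cell_area_um2": 90.0},
                # endocrine cells never appear in the exocrine subset
                {"cell_id": 3, "endocrine_candidate": True,
                 "centroid_row": 100.0, "centroid_col": 100.0,
                 "cell_area_um2": 90.0},
            ]
        )
        out = peri_islet_exocrine_cells(cells, [mask], PX, max_distance_um=20.0)
        assert list(out["cell_id"]) == [1]

    def test_exocrine_area_recovery(self):
        # mean exocrine cell area near the configured 95.76 um^2 target
        cfg = small_preset("ND", n_islets=1, image_shape_px=(384, 384))
        from isletquant.pipeline import PipelineConfig, analyze_donor_images

        means = []
        for seed in (2, 3):
            image, _ = render_islet_image(cfg, seed=seed)
            _, cell_df = analyze_donor_images([("im", image)], PipelineConfig())
            peri = cell_df[cell_df["peri_islet"]]
            means.append(peri["cell_area_um2"].mean())
        assert np.mean(means) == pytest.approx(95.76, rel=0.10)
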