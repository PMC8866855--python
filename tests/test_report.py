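"""Orchestration, group summaries, evaluation matching, sample size."""

import json

import numpy as np
import pandas as pd
import pytest

import gliamorph as gm
from gliamorph.pipeline import PipelineConfig
from gliamorph.report import evaluate, run_pipeline, sample_size, summarize


class TestSummarize:
    def test_single_record(self):
        df = pd.DataFrame({"class": ["ameboid"], "mean_tmem_total": [42.0]})
        out = summarize(df, ["class"])
        assert out.loc[0, "n"] == 1
        assert out.loc[0, "mean"] == 42.0
        assert out.loc[0, "sd"] == 0.0

    def test_two_records_mean(self):
        df = pd.DataFrame({"class": ["a", "a"], "mean_tmem_total": [10.0, 20.0]})
        out = summarize(df, ["class"])
        assert out.loc[0, "mean"] == 15.0

    def test_hand_computed_sd_and_quartiles(self):
        vals = [2.0, 4.0, 4.0, 4.0, 5.0, 5.0, 7.0, 9.0, 1.0, 3.0]
        df = pd.DataFrame({"class": ["x"] * 10, "mean_tmem_total": vals})
        out = summarize(df, ["class"])
        s = pd.Series(vals)
        assert out.loc[0, "sd"] == pytest.approx(s.std(ddof=1))
        assert out.loc[0, "median"] == s.median()
        assert out.loc[0, "q1"] == s.quantile(0.25)
        assert out.loc[0, "q3"] == s.quantile(0.75)


class TestSampleSize:
    def test_huge_effect_needs_almost_no_animals(self):
        n, _ = sample_size(sigma=1.0, delta=1e9)
        assert n < 1e-6

    def test_sigma_equals_delta_canonical_value(self):
        # f(0.05, 0.2) = (1.95996 + 0.84162)^2 = 7.849; n = 2 f
        n, n_up = sample_size(sigma=1.0, delta=1.0, alpha=0.05, beta=0.2)
        assert n == pytest.approx(2 * (1.959964 + 0.841621) ** 2, rel=1e-4)
        assert n_up == 16

    def test_published_morphometry_design(self):
        # sigma 18.42, delta 42 at (0.05, 0.2): about three animals per group
        n, n_up = sample_size(sigma=18.42, delta=42.0)
        assert n == pytest.approx(3.02, abs=0.02)
        assert n_up == 4

    def test_f_override(self):
        n, _ = sample_size(sigma=18.42, delta=42.0, f=7.58)
        assert n == pytest.approx(2 * 18.42**2 * 7.58 / 42.0**2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sample_size(sigma=0, delta=1)
        with pytest.raises(ValueError):
            sample_size(sigma=1, delta=1, alpha=1.5)


class TestEvaluate:
    def test_truth_measured_directly_gives_perfect_diagonal(self, noiseless_scene):
        _, stack, truth = noiseless_scene
        proj = gm.max_project(stack)
        cfg = PipelineConfig(threshold_gray=300, exclude_border=False)
        from gliamorph.pipeline import segment_cells

        labels = segment_cells(proj["iba1"], cfg, stack.pixel_size_um)
        roi = gm.RoiSpec.whole_image(stack.shape_yx, stack.pixel_size_um)
        cells = gm.quantify_roi(labels, proj["tmem119"], roi)
        rep = evaluate(cells, labels, truth.label_image, truth.to_frame())
        assert rep.n_missed == 0 and rep.n_spurious == 0
        offdiag = rep.confusion.values.sum() - np.trace(rep.confusion.values[:, :3])
        assert offdiag == 0
        assert rep.confusion.values.sum(axis=1).tolist() == [
            sum(1 for c in truth.cells if c.class_label == lab)
            for lab in ("ramified", "hypertrophic", "ameboid")
        ]

    def test_no_overlap_all_missed_and_spurious(self, noiseless_scene):
        _, stack, truth = noiseless_scene
        h, w = truth.label_image.shape
        fake = gm.LabelMask(data=np.zeros((h, w), int), pixel_size_um=0.2)
        fake.data[0:5, 0:5] = 1
        cells = pd.DataFrame({"cell_id": [1], "class": ["ameboid"],
                              "mean_tmem_total": [1.0]})
        rep = evaluate(cells, fake, truth.label_image, truth.to_frame())
        assert rep.n_matched == 0
        assert rep.n_missed == len(truth.cells)
        assert rep.n_spurious == 1

    def test_greedy_matching_is_one_to_one(self, noisy_scene, default_config):
        _, stack, truth = noisy_scene
        cells, _, labels = run_pipeline(stack, default_config)
        rep = evaluate(cells, labels, truth.label_image, truth.to_frame())
        assert rep.n_matched + rep.n_missed == len(truth.cells)
        assert rep.n_matched + rep.n_spurious == labels.n_cells


class TestRunPipeline:
    def test_noiseless_counts_equal_truth(self, noiseless_scene):
        _, stack, truth = noiseless_scene
        cfg = PipelineConfig(threshold_gray=300, exclude_border=False)
        cells, groups, labels = run_pipeline(stack, cfg)
        truth_counts = pd.Series([c.class_label for c in truth.cells]).value_counts()
        seg_counts = cells["class"].value_counts()
        for lab in truth_counts.index:
            assert seg_counts.get(lab, 0) == truth_counts[lab]

    def test_rerun_writes_identical_csvs(self, noiseless_scene, tmp_path):
        _, stack, _ = noiseless_scene
        cfg = PipelineConfig(threshold_gray=300, exclude_border=False)
        run_pipeline(stack, cfg, out_dir=tmp_path / "a")
        run_pipeline(stack, cfg, out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "cells.csv").read_bytes() == \
            (tmp_path / "b" / "cells.csv").read_bytes()
        assert (tmp_path / "a" / "groups.csv").read_bytes() == \
            (tmp_path / "b" / "groups.csv").read_bytes()

    def test_run_log_captures_config(self, noiseless_scene, tmp_path):
        _, stack, _ = noiseless_scene
        cfg = PipelineConfig(threshold_gray=300, exclude_border=False)
        run_pipeline(stack, cfg, out_dir=tmp_path)
        log = json.loads((tmp_path / "run_log.json").read_text())
        assert log["config"]["threshold_gray"] == 300
        assert log["n_cells"] == log["n_segmented"]

    def test_marker_means_come_from_rolling20_marker_projection(self, noiseless_scene):
        """Quantified marker means must equal a hand-computed mean over the
        rolling-20-subtracted marker projection — never the Iba1-chain
        output."""
        from gliamorph.pipeline import preprocess_marker

        _, stack, truth = noiseless_scene
        cfg = PipelineConfig(threshold_gray=300, exclude_border=False)
        cells, _, labels = run_pipeline(stack, cfg)
        marker = preprocess_marker(gm.max_project(stack)["tmem119"], cfg)
        cell = truth.cells[0]
        seg_label = labels.data[int(cell.centroid_yx_px[0]), int(cell.centroid_yx_px[1])]
        assert seg_label > 0
        expected = gm.mean_in_mask(marker, labels.data == seg_label)
        row = cells.set_index("cell_id").loc[seg_label]
        assert row["mean_tmem_total"] == pytest.approx(expected, rel=1e-9)
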