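"""Synthetic movie and track-table generator: ground truth must be true."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from shapetrack.simulate import (SimulationConfig, cumulative_drift,
                                 simulate_cell_channel, simulate_movie,
                                 simulate_structural_channel,
                                 simulate_track_table)


class TestConfigValidation:
    def test_rejects_single_frame(self):
        with pytest.raises(ValueError, match="n_frames"):
            SimulationConfig(n_frames=1)

    @pytest.mark.parametrize("field, value", [
        ("pixel_size_um", 0.0),
        ("round_radius_um", -1.0),
        ("dendritic_arm_count", 2),
        ("noise_sd", -0.1),
    ])
    def test_rejects_invalid_parameters(self, field, value):
        with pytest.raises(ValueError):
            SimulationConfig(**{field: value})

    def test_drift_sequence_length_must_match_frames(self):
        with pytest.raises(ValueError, match="drift_px"):
            SimulationConfig(n_frames=4, drift_px=((0, 0), (1, 0)))


class TestStructuralChannel:
    def test_zero_drift_zero_noise_frames_identical(self, small_config):
        cfg = replace(small_config, noise_sd=0.0, drift_step_sd_px=0.0)
        frames = simulate_structural_channel(cfg)
        for t in range(1, cfg.n_frames):
            np.testing.assert_array_equal(frames[t], frames[0])

    def test_constant_drift_translates_frame(self, small_config):
        drift = tuple((t, 0) for t in range(small_config.n_frames))
        cfg = replace(small_config, noise_sd=0.0, drift_px=drift)
        frames = simulate_structural_channel(cfg)
        # frame t is frame 0 moved down by t rows (interior crop comparison)
        t = 3
        np.testing.assert_allclose(frames[t][t:, :], frames[0][:-t, :])

    def test_same_seed_bit_identical(self, small_config):
        a = simulate_structural_channel(small_config)
        b = simulate_structural_channel(small_config)
        np.testing.assert_array_equal(a, b)

    def test_excessive_drift_errors(self, small_config):
        h = small_config.field_size_px[0]
        drift = tuple((0, 0) if t == 0 else (h + 5, 0)
                      for t in range(small_config.n_frames))
        cfg = replace(small_config, drift_px=drift)
        with pytest.raises(ValueError, match="out of frame"):
            simulate_structural_channel(cfg)

    def test_texture_has_autocorrelation_structure(self, small_config):
        frames = simulate_structural_channel(
            replace(small_config, noise_sd=0.0, drift_step_sd_px=0.0))
        assert frames[0].std() > 0


class TestCellChannel:
    def test_ground_truth_bookkeeping(self, small_config):
        cfg = replace(small_config, n_round_cells=5, n_dendritic_cells=5,
                      min_separation_um=18.0)
        _, truth = simulate_cell_channel(cfg)
        assert len(truth.labels) == 10
        assert sorted(truth.labels["label"]) == ["dendritic"] * 5 + \
            ["round"] * 5
        counts = truth.tracks.groupby("cell_id").size()
        assert (counts == cfg.n_frames).all()
        assert len(truth.applied_drift_px) == cfg.n_frames

    def test_zero_speed_zero_drift_tracks_are_static(self, small_config):
        cfg = replace(small_config, round_speed_um_min=0.0,
                      dendritic_speed_um_min=0.0, drift_step_sd_px=0.0)
        _, truth = simulate_cell_channel(cfg)
        for _, sub in truth.tracks.groupby("cell_id"):
            assert sub["x_um"].nunique() == 1
            assert sub["y_um"].nunique() == 1

    def test_rendered_centroid_matches_truth_plus_drift(self, small_config):
        """Rendered mask centroid = true position + cumulative drift."""
        cfg = replace(small_config, noise_sd=0.0, n_round_cells=1,
                      n_dendritic_cells=0)
        frames, truth = simulate_cell_channel(cfg)
        px = cfg.pixel_size_um
        for t in range(cfg.n_frames):
            rows, cols = np.nonzero(frames[t] > 0.5)
            dy, dx = truth.applied_drift_px[t]
            row_true = truth.tracks.query("frame == @t")
            exp_r = row_true["y_um"].iloc[0] / px + dy
            exp_c = row_true["x_um"].iloc[0] / px + dx
            assert abs(rows.mean() - exp_r) < 0.5
            assert abs(cols.mean() - exp_c) < 0.5

    def test_overcrowding_errors(self):
        cfg = SimulationConfig(field_size_px=(64, 64), n_frames=2,
                               n_round_cells=50, n_dendritic_cells=0,
                               round_radius_um=3.0,
                               dendritic_arm_length_um=4.0,
                               min_separation_um=30.0)
        with pytest.raises(ValueError, match="density|too small"):
            simulate_cell_channel(cfg)

    def test_movie_determinism(self, small_config):
        m1, t1 = simulate_movie(small_config)
        m2, t2 = simulate_movie(small_config)
        np.testing.assert_array_equal(m1.cells, m2.cells)
        np.testing.assert_array_equal(m1.structural, m2.structural)
        pd.testing.assert_frame_equal(t1.tracks, t2.tracks)


class TestTrackTable:
    def test_mrc_concentrates_near_class_mean(self):
        """Law of large numbers: per-cell mean IRC → class mean."""
        cfg = SimulationConfig(field_size_px=(512, 512), n_frames=400,
                               n_round_cells=3, n_dendritic_cells=3, seed=5)
        table, labels = simulate_track_table(cfg, irc_means=(0.25, 0.55),
                                             irc_sd=0.05)
        merged = table.merge(labels, on="cell_id")
        mrc = merged.groupby(["cell_id", "label"])["irc"].mean().reset_index()
        # truncation to [0,1] is negligible at these means, so the sample
        # mean estimates the class mean with se ~ 0.05/sqrt(400) = 0.0025
        for _, row in mrc.iterrows():
            target = 0.25 if row["label"] == "dendritic" else 0.55
            assert abs(row["irc"] - target) < 0.01

    def test_single_class(self, small_config):
        cfg = replace(small_config, n_round_cells=0, n_dendritic_cells=3)
        _, labels = simulate_track_table(cfg)
        assert set(labels["label"]) == {"dendritic"}

    def test_determinism(self, small_config):
        t1, _ = simulate_track_table(small_config)
        t2, _ = simulate_track_table(small_config)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_means_rejected(self, small_config):
        with pytest.raises(ValueError, match="irc_means"):
            simulate_track_table(small_config, irc_means=(0.25, 1.2))

    def test_class_histograms_barely_overlap(self):
        """< 5% of either class's mass crosses the inter-mean midpoint."""
        cfg = SimulationConfig(field_size_px=(512, 512), n_frames=60,
                               n_round_cells=20, n_dendritic_cells=20,
                               min_separation_um=15.0, seed=2)
        table, labels = simulate_track_table(cfg, irc_means=(0.25, 0.55),
                                             irc_sd=0.05)
        merged = table.merge(labels, on="cell_id")
        mid = 0.40
        dend = merged.loc[merged["label"] == "dendritic", "irc"]
        rnd = merged.loc[merged["label"] == "round", "irc"]
        assert (dend > mid).mean() < 0.05
        assert (rnd < mid).mean() < 0.05


def test_explicit_drift_is_zero_referenced():
    cfg = SimulationConfig(n_frames=3, drift_px=((2, 2), (3, 2), (4, 2)))
    cum = cumulative_drift(cfg)
    np.testing.assert_array_equal(cum[0], (0, 0))
    np.testing.assert_array_equal(cum[-1], (2, 0))
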