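"""Particle linking: optimality against a brute-force oracle, bridging,
determinism."""

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from shapetrack.simulate import simulate_cell_channel
from shapetrack.detection import detect_movie
from shapetrack.tracking import (LinkingParams, link_detections,
                                 table_to_tracks, track_summary,
                                 tracks_to_table)


def make_table(rows):
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "irc"])


def brute_force_links(prev_xy, curr_xy, max_disp):
    """Enumerate every partial one-to-one matching; minimize
    Σ d² over links + max_disp² per unmatched point on either side."""
    na, nb = len(prev_xy), len(curr_xy)
    gate = max_disp ** 2
    best_cost, best = np.inf, []
    for k in range(min(na, nb) + 1):
        for a_idx in itertools.combinations(range(na), k):
            for b_perm in itertools.permutations(range(nb), k):
                d2 = [((prev_xy[i] - curr_xy[j]) ** 2).sum()
                      for i, j in zip(a_idx, b_perm)]
                if any(v > gate for v in d2):
                    continue
                cost = sum(d2) + gate * (na - k + nb - k)
                if cost < best_cost:
                    best_cost = cost
                    best = list(zip(a_idx, b_perm))
    return set(best)


def extracted_links(tracks):
    """(frame, x, y) -> (frame+1, x, y) consecutive pairs from tracks."""
    links = set()
    for tr in tracks:
        for i in range(tr.n_frames_observed - 1):
            if tr.frames[i + 1] == tr.frames[i] + 1:
                links.add(((tr.frames[i], round(tr.x_um[i], 9),
                            round(tr.y_um[i], 9)),
                           (tr.frames[i + 1], round(tr.x_um[i + 1], 9),
                            round(tr.y_um[i + 1], 9))))
    return links


class TestLinkingOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_min_squared_displacement(self, seed):
        """On ≤5 cells × ≤6 frames, the Hungarian linker picks exactly the
        assignment found by exhaustive enumeration."""
        rng = np.random.default_rng(seed)
        n_cells = int(rng.integers(2, 6))
        n_frames = int(rng.integers(3, 7))
        max_disp = 12.0
        pos = rng.uniform(0, 60, size=(n_frames, n_cells, 2))
        rows = [(f, pos[f, i, 0], pos[f, i, 1], 0.5)
                for f in range(n_frames) for i in range(n_cells)]
        table = make_table(rows)
        tracks = link_detections(table, LinkingParams(
            max_displacement_um=max_disp, memory_frames=0,
            min_track_length=2))

        expected = set()
        for f in range(n_frames - 1):
            for pi, ci in brute_force_links(pos[f], pos[f + 1], max_disp):
                expected.add(((f, round(pos[f, pi, 0], 9),
                               round(pos[f, pi, 1], 9)),
                              (f + 1, round(pos[f + 1, ci, 0], 9),
                               round(pos[f + 1, ci, 1], 9))))
        assert extracted_links(tracks) == expected


class TestLinkingBehavior:
    def test_two_stationary_cells_two_full_tracks(self):
        rows = [(f, x, 10.0, 0.9) for f in range(5) for x in (5.0, 50.0)]
        tracks = link_detections(make_table(rows))
        assert len(tracks) == 2
        assert all(tr.n_frames_observed == 5 for tr in tracks)

    def test_memory_bridges_single_missing_frame(self):
        rows = [(f, 10.0, 10.0, 0.9) for f in range(6) if f != 3]
        with_memory = link_detections(make_table(rows), LinkingParams(
            memory_frames=1, min_track_length=2))
        assert len(with_memory) == 1
        assert with_memory[0].n_frames_observed == 5  # gap not fabricated
        without = link_detections(make_table(rows), LinkingParams(
            memory_frames=0, min_track_length=2))
        assert sorted(tr.n_frames_observed for tr in without) == [2, 3]

    def test_min_track_length_filters(self):
        rows = [(f, 10.0, 10.0, 0.9) for f in range(2)]
        assert link_detections(make_table(rows), LinkingParams(
            min_track_length=3)) == []

    def test_permutation_invariance(self, rng):
        rows = [(f, x, y, 0.5)
                for f in range(5)
                for x, y in ((10.0 + f, 10.0), (40.0, 40.0 - f),
                             (70.0, 15.0 + 2 * f))]
        table = make_table(rows)
        shuffled = table.sample(frac=1.0, random_state=4).reset_index(
            drop=True)
        t1 = tracks_to_table(link_detections(table))
        t2 = tracks_to_table(link_detections(shuffled))
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_input(self):
        assert link_detections(make_table([])) == []

    def test_ground_truth_recovery_no_identity_switches(self, small_config):
        """Well-separated simulated cells come back as exactly one track
        each, matching the true trajectory."""
        cfg = replace(small_config, noise_sd=0.0, drift_step_sd_px=0.0)
        frames, truth = simulate_cell_channel(cfg)
        det = detect_movie(frames, pixel_size_um=cfg.pixel_size_um)
        tracks = link_detections(det)
        assert len(tracks) == cfg.n_round_cells + cfg.n_dendritic_cells
        for tr in tracks:
            # nearest true cell at the first frame must stay nearest
            d0 = truth.tracks.query("frame == 0")
            cell = d0.iloc[np.hypot(d0["x_um"] - tr.x_um[0],
                                    d0["y_um"] - tr.y_um[0]).argmin()]
            true_tr = truth.tracks[truth.tracks["cell_id"]
                                   == cell["cell_id"]]
            merged = true_tr.set_index("frame").loc[tr.frames]
            err = np.hypot(merged["x_um"].to_numpy() - tr.x_um,
                           merged["y_um"].to_numpy() - tr.y_um)
            assert err.max() < 2.0  # µm; segmentation centroid tolerance


class TestTrackSummary:
    def test_duration_arithmetic(self):
        rows = [(f, 10.0, 10.0, 0.5) for f in range(16)]
        tracks = link_detections(make_table(rows))
        summary = track_summary(tracks, frame_interval_min=2.0)
        assert summary.loc[0, "n_frames_observed"] == 16
        assert summary.loc[0, "duration_min"] == 30.0

    def test_empty(self):
        assert len(track_summary([], 2.0)) == 0

    def test_bridged_gap_counts_only_observed_frames(self):
        rows = [(f, 10.0, 10.0, 0.5) for f in range(6) if f != 2]
        tracks = link_detections(make_table(rows), LinkingParams(
            memory_frames=1, min_track_length=2))
        summary = track_summary(tracks, 2.0)
        assert summary.loc[0, "n_frames_observed"] == 5
        assert summary.loc[0, "first_frame"] == 0
        assert summary.loc[0, "last_frame"] == 5

    def test_table_roundtrip(self):
        rows = [(f, 10.0 + f, 20.0, 0.7) for f in range(4)]
        tracks = link_detections(make_table(rows))
        rebuilt = table_to_tracks(tracks_to_table(tracks))
        assert len(rebuilt) == len(tracks) == 1
        np.testing.assert_array_equal(rebuilt[0].frames, tracks[0].frames)
        np.testing.assert_allclose(rebuilt[0].x_um, tracks[0].x_um)
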