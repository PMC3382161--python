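"""Synthetic two-channel lung-explant movies with known ground truth.

The generator emulates the imaging regime of two-photon lung-slice
recordings: a static collagen-like fiber mesh in the structural (SHG)
channel that drifts rigidly over time, and two motile fluorescent cell
populations in the cell channel — round fast movers (monocyte-like disks)
and dendritiform slow movers (star polygons with radiating arms).  Every
movie comes with exported ground truth: per-cell true trajectories (before
drift), class labels, and the applied per-frame drift, so the registration,
detection, tracking, metric and classification stages can all be scored
against a known answer.

Defaults follow the source imaging regime: a 512 × 512 px field spanning
280 × 280 µm (0.547 µm/px) sampled every 2 minutes for one hour
(31 frames).  Motion is an isotropic random walk with fixed step length
``speed × Δt``; drift is a smooth random walk in shift space with per-frame
steps of the same order as cell displacements.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import draw

from .io import DEFAULT_FRAME_INTERVAL_MIN, DEFAULT_PIXEL_SIZE_UM, Movie


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic movie.

    All lengths are in micrometres unless the name says px; identical
    ``seed`` + config yields bit-identical output.
    """

    field_size_px: tuple[int, int] = (512, 512)  # (rows, cols)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
    n_frames: int = 31
    n_round_cells: int = 10
    n_dendritic_cells: int = 3
    round_speed_um_min: float = 3.0
    dendritic_speed_um_min: float = 1.0
    round_radius_um: float = 5.0
    dendritic_arm_count: int = 5
    dendritic_arm_length_um: float = 12.0
    dendritic_body_radius_um: float = 3.0
    drift_px: tuple[tuple[float, float], ...] | None = None
    drift_step_sd_px: float = 2.0
    noise_sd: float = 0.05
    min_separation_um: float = 30.0
    n_fibers: int = 80
    fiber_sigma_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in ("pixel_size_um", "frame_interval_min", "round_radius_um",
                     "dendritic_arm_length_um", "dendritic_body_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("round_speed_um_min", "dendritic_speed_um_min",
                     "noise_sd", "drift_step_sd_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.dendritic_arm_count < 3:
            raise ValueError("dendritic_arm_count must be >= 3")
        if min(self.field_size_px) < 16:
            raise ValueError("field too small")
        if self.drift_px is not None and len(self.drift_px) != self.n_frames:
            raise ValueError("drift_px must have one (dy, dx) per frame")


@dataclass
class GroundTruth:
    """What the generator actually did.

    ``tracks`` is a tidy table (cell_id, frame, x_um, y_um, label) of true
    centroid positions *before* drift; ``applied_drift_px`` the per-frame
    cumulative (dy, dx) shift shared by both channels; ``rendered_px``
    per-cell per-frame rendered mask pixel counts.
    """

    tracks: pd.DataFrame
    labels: pd.DataFrame  # cell_id, label
    applied_drift_px: np.ndarray  # (n_frames, 2)
    rendered_px: pd.DataFrame | None = None  # cell_id, frame, pixel_count


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per sub-generator (crc32 is stable
    # across processes, unlike the builtin salted str hash)
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(stream.encode())]))


def cumulative_drift(config: SimulationConfig) -> np.ndarray:
    """Per-frame cumulative (dy, dx) drift in integer pixels.

    Either the explicit ``drift_px`` sequence (rounded to integers) or a
    smooth random walk with N(0, drift_step_sd_px) per-frame steps.  Frame
    0 has zero drift by construction.
    """
    if config.drift_px is not None:
        cum = np.rint(np.asarray(config.drift_px, dtype=float)).astype(int)
        cum = cum - cum[0]
    else:
        rng = _rng(config, "drift")
        steps = rng.normal(0.0, config.drift_step_sd_px,
                           size=(config.n_frames, 2))
        steps[0] = 0.0
        cum = np.rint(np.cumsum(steps, axis=0)).astype(int)
    h, w = config.field_size_px
    if (np.abs(cum[:, 0]) >= h).any() or (np.abs(cum[:, 1]) >= w).any():
        raise ValueError("drift pushes the texture fully out of frame")
    return cum


def simulate_structural_channel(config: SimulationConfig) -> np.ndarray:
    """Render the drifting static fiber-mesh (collagen/SHG-like) channel.

    A single texture of random line segments, Gaussian-smoothed so it has
    nonzero autocorrelation structure, is rendered once on an enlarged
    canvas and cropped per frame at that frame's cumulative drift, then
    additive Gaussian noise is applied.
    """
    h, w = config.field_size_px
    cum = cumulative_drift(config)
    margin = int(np.abs(cum).max()) + 1
    ch, cw = h + 2 * margin, w + 2 * margin

    rng = _rng(config, "fibers")
    canvas = np.zeros((ch, cw))
    for _ in range(config.n_fibers):
        r0, c0 = rng.integers(0, ch), rng.integers(0, cw)
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.1, 0.6) * min(ch, cw)
        r1 = int(np.clip(r0 + length * np.sin(ang), 0, ch - 1))
        c1 = int(np.clip(c0 + length * np.cos(ang), 0, cw - 1))
        rr, cc = draw.line(int(r0), int(c0), r1, c1)
        canvas[rr, cc] += 1.0
    canvas = ndimage.gaussian_filter(canvas, config.fiber_sigma_px)
    if canvas.max() > 0:
        canvas /= canvas.max()

    noise_rng = _rng(config, "structural-noise")
    frames = np.empty((config.n_frames, h, w))
    for t, (dy, dx) in enumerate(cum):
        # drift by +d means scene content moves by +d: crop window moves by -d
        frames[t] = canvas[margin - dy:margin - dy + h,
                           margin - dx:margin - dx + w]
    if config.noise_sd > 0:
        frames += noise_rng.normal(0.0, config.noise_sd, frames.shape)
    return frames


def _place_initial(rng, config: SimulationConfig, n: int) -> np.ndarray:
    """Random initial centroids (µm) with a guaranteed minimum separation."""
    h, w = config.field_size_px
    px = config.pixel_size_um
    pad = max(config.round_radius_um, config.dendritic_arm_length_um) + 2 * px
    lo = pad
    hi_x, hi_y = w * px - pad, h * px - pad
    if hi_x <= lo or hi_y <= lo:
        raise ValueError("field too small for the configured cell sizes")
    points: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(2000):
            p = rng.uniform([lo, lo], [hi_x, hi_y])
            if all(np.hypot(*(p - q)) >= config.min_separation_um
                   for q in points):
                points.append(p)
                break
        else:
            raise ValueError(
                "cell density too high to guarantee min_separation_um")
    return np.array(points) if points else np.empty((0, 2))


def _random_walk(rng, start_um: np.ndarray, step_um: float, n_frames: int,
                 bounds_um: tuple[float, float, float, float]) -> np.ndarray:
    """Isotropic fixed-step random walk, reflecting at the field bounds."""
    lo_x, hi_x, lo_y, hi_y = bounds_um
    pos = np.empty((n_frames, 2))
    pos[0] = start_um
    for t in range(1, n_frames):
        heading = rng.uniform(0, 2 * np.pi)
        p = pos[t - 1] + step_um * np.array([np.cos(heading), np.sin(heading)])
        # reflect each coordinate back into the interior
        for k, (lo, hi) in enumerate(((lo_x, hi_x), (lo_y, hi_y))):
            if p[k] < lo:
                p[k] = 2 * lo - p[k]
            elif p[k] > hi:
                p[k] = 2 * hi - p[k]
        pos[t] = p
    return pos


def _star_polygon(center_rc, outer_r_px, inner_r_px, n_arms, phase):
    """Vertex rows/cols of a star (dendritiform) polygon."""
    angles = phase + np.arange(2 * n_arms) * np.pi / n_arms
    radii = np.where(np.arange(2 * n_arms) % 2 == 0, outer_r_px, inner_r_px)
    rows = center_rc[0] + radii * np.sin(angles)
    cols = center_rc[1] + radii * np.cos(angles)
    return rows, cols


def simulate_cell_channel(
        config: SimulationConfig) -> tuple[np.ndarray, GroundTruth]:
    """Render the fluorescent cell channel and its ground truth.

    Round cells are filled disks, dendritic cells star polygons with
    ``dendritic_arm_count`` thin arms.  Centroids follow isotropic random
    walks (step = speed × Δt) reflecting at the field edges; the rendered
    positions are additionally shifted by the same drift as the structural
    channel.  Ground truth records true positions *before* drift, in µm.
    """
    h, w = config.field_size_px
    px = config.pixel_size_um
    cum = cumulative_drift(config)
    rng = _rng(config, "cells")

    n_total = config.n_round_cells + config.n_dendritic_cells
    labels = (["round"] * config.n_round_cells
              + ["dendritic"] * config.n_dendritic_cells)
    starts = _place_initial(rng, config, n_total)

    pad = max(config.round_radius_um, config.dendritic_arm_length_um) + 2 * px
    bounds = (pad, w * px - pad, pad, h * px - pad)
    step = {
        "round": config.round_speed_um_min * config.frame_interval_min,
        "dendritic": config.dendritic_speed_um_min * config.frame_interval_min,
    }
    tracks = np.empty((n_total, config.n_frames, 2))
    phases = rng.uniform(0, 2 * np.pi, size=n_total)
    for i in range(n_total):
        tracks[i] = _random_walk(rng, starts[i], step[labels[i]],
                                 config.n_frames, bounds)

    frames = np.zeros((config.n_frames, h, w))
    rendered = []
    for t in range(config.n_frames):
        dy, dx = cum[t]
        for i in range(n_total):
            x_um, y_um = tracks[i, t]
            r = y_um / px + dy  # row
            c = x_um / px + dx  # col
            mask = np.zeros((h, w), dtype=bool)
            if labels[i] == "round":
                rr, cc = draw.disk((r, c), config.round_radius_um / px,
                                   shape=(h, w))
            else:
                rows, cols = _star_polygon(
                    (r, c), config.dendritic_arm_length_um / px,
                    config.dendritic_body_radius_um / px,
                    config.dendritic_arm_count, phases[i])
                rr, cc = draw.polygon(rows, cols, shape=(h, w))
            mask[rr, cc] = True
            frames[t][mask] = 1.0
            rendered.append((i, t, int(mask.sum())))

    if config.noise_sd > 0:
        noise_rng = _rng(config, "cell-noise")
        frames += noise_rng.normal(0.0, config.noise_sd, frames.shape)

    track_rows = []
    for i in range(n_total):
        for t in range(config.n_frames):
            track_rows.append((i, t, tracks[i, t, 0], tracks[i, t, 1],
                               labels[i]))
    truth = GroundTruth(
        tracks=pd.DataFrame(track_rows,
                            columns=["cell_id", "frame", "x_um", "y_um",
                                     "label"]),
        labels=pd.DataFrame({"cell_id": np.arange(n_total), "label": labels}),
        applied_drift_px=cum,
        rendered_px=pd.DataFrame(rendered,
                                 columns=["cell_id", "frame", "pixel_count"]),
    )
    return frames, truth


def simulate_movie(config: SimulationConfig) -> tuple[Movie, GroundTruth]:
    """Full two-channel movie: cell channel + drifting structural channel."""
    structural = simulate_structural_channel(config)
    cells, truth = simulate_cell_channel(config)
    movie = Movie(cells, structural, config.pixel_size_um,
                  config.frame_interval_min)
    return movie, truth


def simulate_track_table(config: SimulationConfig,
                         irc_means: tuple[float, float] = (0.25, 0.55),
                         irc_sd: float = 0.05) -> tuple[pd.DataFrame,
                                                        pd.DataFrame]:
    """Image-free fixture: tracks with per-frame IRC values.

    Positions follow the same random-walk model as the rendered movies;
    IRC values are drawn per cell per frame from its class distribution
    N(mean, irc_sd²) truncated to [0, 1] — dendritic cells from
    ``irc_means[0]``, round cells from ``irc_means[1]``.

    Returns the tidy table (cell_id, frame, x_um, y_um, irc) and the label
    table (cell_id, label).
    """
    for m in irc_means:
        if not 0 < m < 1:
            raise ValueError("irc_means must lie strictly inside (0, 1)")
    if irc_sd < 0:
        raise ValueError("irc_sd must be nonnegative")

    rng = _rng(config, "track-table")
    n_total = config.n_round_cells + config.n_dendritic_cells
    labels = (["round"] * config.n_round_cells
              + ["dendritic"] * config.n_dendritic_cells)
    mean_of = {"dendritic": irc_means[0], "round": irc_means[1]}
    h, w = config.field_size_px
    px = config.pixel_size_um
    starts = _place_initial(rng, config, n_total)
    bounds = (1.0, w * px - 1.0, 1.0, h * px - 1.0)
    step = {
        "round": config.round_speed_um_min * config.frame_interval_min,
        "dendritic": config.dendritic_speed_um_min * config.frame_interval_min,
    }

    rows = []
    for i in range(n_total):
        pos = _random_walk(rng, starts[i], step[labels[i]], config.n_frames,
                           bounds)
        mu = mean_of[labels[i]]
        if irc_sd == 0:
            irc = np.full(config.n_frames, mu)
        else:
            a, b = (0 - mu) / irc_sd, (1 - mu) / irc_sd
            irc = stats.truncnorm.rvs(a, b, loc=mu, scale=irc_sd,
                                      size=config.n_frames, random_state=rng)
        for t in range(config.n_frames):
            rows.append((i, t, pos[t, 0], pos[t, 1], irc[t]))

    table = pd.DataFrame(rows, columns=["cell_id", "frame", "x_um", "y_um",
                                        "irc"])
    label_table = pd.DataFrame({"cell_id": np.arange(n_total),
                                "label": labels})
    return table, label_table
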