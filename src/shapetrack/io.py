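"""Movie container and file interchange.

A :class:`Movie` holds a time-ordered pair of 2D image channels — the
fluorescent cell channel and the structural (second-harmonic generation,
SHG) collagen channel — together with the spatial and temporal calibration
needed to express results in micrometres and minutes.

Files are exchanged as multi-page TIFF (one file per channel, or one
interleaved two-channel file) and tidy CSV tables; simulation/run
configuration as YAML.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
import yaml

#: Default spatial calibration: 512 px spanning a 280 µm field of view.
DEFAULT_PIXEL_SIZE_UM = 280.0 / 512.0

#: Default temporal calibration: one z-stack every two minutes.
DEFAULT_FRAME_INTERVAL_MIN = 2.0


@dataclass
class Movie:
    """Two-channel calibrated time-lapse movie.

    Parameters
    ----------
    cells : ndarray, shape (T, H, W)
        Fluorescent cell channel (e.g. CX3CR1-GFP).
    structural : ndarray, shape (T, H, W)
        Structural reference channel (e.g. collagen SHG), used for drift
        correction and never for cell detection.
    pixel_size_um : float
        Edge length of one pixel in micrometres.
    frame_interval_min : float
        Time between consecutive frames in minutes.
    """

    cells: np.ndarray
    structural: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        self.structural = np.asarray(self.structural, dtype=float)
        if self.cells.ndim != 3 or self.structural.ndim != 3:
            raise ValueError("channels must be (T, H, W) arrays")
        if self.cells.shape != self.structural.shape:
            raise ValueError(
                f"channel shapes differ: {self.cells.shape} vs "
                f"{self.structural.shape}"
            )
        if self.n_frames < 1:
            raise ValueError("movie needs at least one frame")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ValueError("calibration values must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.cells.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.cells.shape[1:]


def write_movie(movie: Movie, cells_path=None, structural_path=None,
                interleaved_path=None) -> None:
    """Write a movie as multi-page TIFF.

    Either give ``cells_path`` and ``structural_path`` (one file per
    channel) or ``interleaved_path`` (frames alternate cell/structural).
    """
    if interleaved_path is not None:
        stack = np.empty((2 * movie.n_frames,) + movie.frame_shape,
                         dtype=np.float32)
        stack[0::2] = movie.cells
        stack[1::2] = movie.structural
        tifffile.imwrite(interleaved_path, stack)
        return
    if cells_path is None or structural_path is None:
        raise ValueError("give both per-channel paths or interleaved_path")
    tifffile.imwrite(cells_path, movie.cells.astype(np.float32))
    tifffile.imwrite(structural_path, movie.structural.astype(np.float32))


def read_movie(cells_path=None, structural_path=None, interleaved_path=None,
               pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
               frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN) -> Movie:
    """Read a movie written by :func:`write_movie`."""
    if interleaved_path is not None:
        stack = tifffile.imread(interleaved_path)
        if stack.shape[0] % 2:
            raise ValueError("interleaved stack must have an even page count")
        return Movie(stack[0::2], stack[1::2], pixel_size_um,
                     frame_interval_min)
    if cells_path is None or structural_path is None:
        raise ValueError("give both per-channel paths or interleaved_path")
    return Movie(tifffile.imread(cells_path), tifffile.imread(structural_path),
                 pixel_size_um, frame_interval_min)


def write_drift_csv(path, cumulative_shift_px: np.ndarray,
                    peak_correlation: np.ndarray | None = None) -> None:
    """Write per-frame cumulative drift (frame, dy_px, dx_px[, peak_corr])."""
    shifts = np.asarray(cumulative_shift_px, dtype=float)
    out = pd.DataFrame({
        "frame": np.arange(len(shifts)),
        "dy_px": shifts[:, 0],
        "dx_px": shifts[:, 1],
    })
    if peak_correlation is not None:
        out["peak_corr"] = np.asarray(peak_correlation, dtype=float)
    out.to_csv(path, index=False)


def read_config(path) -> dict:
    """Read a YAML key/value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return {} if cfg is None else dict(cfg)


def write_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
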