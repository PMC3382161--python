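"""Per-track motility and shape statistics.

For a track observed on *n* frames with positions p_1 … p_n (µm, in the
drift-corrected 2D projection plane) and per-frame roundness IRC_1 … IRC_n:

* **MRC** (Mean Roundness Coefficient) — the arithmetic mean of the IRC
  over the n observed frames; the feature used to discriminate
  dendritic-shaped from round-shaped cells.
* **MD** (Maximal Distance) — max_i |p_i − p_1|, the farthest the cell
  ever gets from its first position; a confinement measure.
* **MI** (Meandering Index) — D_n / path length, where D_n = |p_n − p_1|;
  1 for a straight path, → 0 for confined or returning paths.  A
  stationary track (zero path length) gets MI = 0 and a flag rather than
  being dropped.
* **velocity** — path length / observed duration (µm/min), the mean
  instantaneous speed; duration spans first to last frame, so bridged
  gaps contribute a single straight-line segment and their elapsed time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tracking import Track


def _path_length(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.hypot(np.diff(x), np.diff(y)).sum())


def mean_roundness(irc: np.ndarray) -> float:
    """Arithmetic mean of per-frame IRC values (the MRC)."""
    irc = np.asarray(irc, dtype=float)
    irc = irc[~np.isnan(irc)]
    if irc.size == 0:
        raise ValueError("track has no IRC observations")
    return float(irc.mean())


def maximal_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Greatest Euclidean distance from the first position (the MD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("track has no positions")
    return float(np.hypot(x - x[0], y - y[0]).max())


def meandering_index(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Final displacement over path length (the MI), in [0, 1].

    Returns ``(mi, stationary)``; a zero-length path is reported as
    MI = 0 with ``stationary=True`` instead of an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("meandering index needs at least 2 positions")
    path = _path_length(x, y)
    if path == 0:
        return 0.0, True
    dn = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    return min(dn / path, 1.0), False


def velocity(x: np.ndarray, y: np.ndarray, frames: np.ndarray,
             frame_interval_min: float) -> float:
    """Mean speed: total path length / observed duration (µm/min)."""
    frames = np.asarray(frames)
    if frames.size < 2:
        raise ValueError("velocity needs at least 2 positions")
    duration = (frames[-1] - frames[0]) * frame_interval_min
    if duration <= 0:
        raise ValueError("track spans zero duration")
    return _path_length(np.asarray(x, float), np.asarray(y, float)) / duration


def compute_track_metrics(tracks: list[Track],
                          frame_interval_min: float) -> pd.DataFrame:
    """All four per-track quantities as a tidy table.

    Columns: track_id, mrc, md_um, mi, final_displacement_um,
    path_length_um, velocity_um_min, n_frames_observed, duration_min,
    stationary.
    """
    rows = []
    for tr in tracks:
        path = _path_length(tr.x_um, tr.y_um)
        mi, stationary = meandering_index(tr.x_um, tr.y_um)
        irc = tr.irc[~np.isnan(tr.irc)]
        rows.append({
            "track_id": tr.track_id,
            "mrc": float(irc.mean()) if irc.size else np.nan,
            "md_um": maximal_distance(tr.x_um, tr.y_um),
            "mi": mi,
            "final_displacement_um": float(np.hypot(
                tr.x_um[-1] - tr.x_um[0], tr.y_um[-1] - tr.y_um[0])),
            "path_length_um": path,
            "velocity_um_min": velocity(tr.x_um, tr.y_um, tr.frames,
                                        frame_interval_min),
            "n_frames_observed": tr.n_frames_observed,
            "duration_min": (tr.n_frames_observed - 1) * frame_interval_min,
            "stationary": stationary,
        })
    return pd.DataFrame(rows, columns=[
        "track_id", "mrc", "md_um", "mi", "final_displacement_um",
        "path_length_um", "velocity_um_min", "n_frames_observed",
        "duration_min", "stationary"])
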