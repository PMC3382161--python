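"""Frame-to-frame linking of detections into cell tracks.

Linking follows the multiple-particle-tracking scheme standard in colloid
and cell tracking: between consecutive frames the one-to-one assignment
minimizing the total squared displacement is chosen among candidate pairs
closer than ``max_displacement_um``, with an unmatched particle costing
``max_displacement_um²`` (the null-link cost).  The optimum is found with
the Hungarian algorithm on an augmented cost matrix; unmatched detections
start new tracks, and a track missing from up to ``memory_frames``
consecutive frames may be bridged when the cell reappears.

Shape is deliberately *not* part of the linking cost: roundness is an
output of tracking, not a feature of it, so classification stays
independent of how tracks were formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

_BIG = 1e12  # forbidden-assignment cost


@dataclass(frozen=True)
class LinkingParams:
    max_displacement_um: float = 20.0
    memory_frames: int = 1
    min_track_length: int = 3

    def __post_init__(self) -> None:
        if self.max_displacement_um <= 0:
            raise ValueError("max_displacement_um must be > 0")
        if self.memory_frames < 0:
            raise ValueError("memory_frames must be >= 0")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")


@dataclass
class Track:
    """Time-ordered detections sharing one cell identity."""

    track_id: int
    frames: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    irc: np.ndarray  # NaN where the source table carries no IRC

    @property
    def n_frames_observed(self) -> int:
        return len(self.frames)


def _assign(prev_xy: np.ndarray, curr_xy: np.ndarray,
            max_disp: float) -> list[tuple[int, int]]:
    """Optimal gated links between two point sets.

    Minimizes Σ d² over links plus max_disp² per unmatched point on either
    side, links allowed only at d ≤ max_disp.  Returns (prev_idx,
    curr_idx) pairs.
    """
    na, nb = len(prev_xy), len(curr_xy)
    if na == 0 or nb == 0:
        return []
    d2 = ((prev_xy[:, None, :] - curr_xy[None, :, :]) ** 2).sum(axis=2)
    gate = max_disp ** 2
    cost = np.full((na + nb, na + nb), _BIG)
    cost[:na, :nb] = np.where(d2 <= gate, d2, _BIG)
    cost[:na, nb:] = np.where(np.eye(na, dtype=bool), gate, _BIG)  # deaths
    cost[na:, :nb] = np.where(np.eye(nb, dtype=bool), gate, _BIG)  # births
    cost[na:, nb:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [(r, c) for r, c in zip(rows, cols)
            if r < na and c < nb and d2[r, c] <= gate]


def link_detections(detections: pd.DataFrame,
                    params: LinkingParams | None = None) -> list[Track]:
    """Link a tidy detection table (frame, x_um, y_um[, irc]) into tracks.

    Tracks shorter than ``min_track_length`` observations are discarded;
    track ids are assigned in order of first appearance, so output is
    deterministic and invariant to within-frame row order.
    """
    if params is None:
        params = LinkingParams()
    if len(detections) == 0:
        return []
    det = detections.sort_values(["frame", "y_um", "x_um"],
                                 kind="stable").reset_index(drop=True)
    has_irc = "irc" in det.columns

    # active track state: list of dicts with last position/frame + history
    active: list[dict] = []
    finished: list[dict] = []
    for f in range(int(det["frame"].min()), int(det["frame"].max()) + 1):
        sub = det[det["frame"] == f]
        # retire tracks whose gap exceeded the allowed memory
        still = []
        for tr in active:
            if f - tr["last_frame"] > params.memory_frames + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still

        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        if len(active) and len(xy):
            prev_xy = np.array([[tr["x"][-1], tr["y"][-1]] for tr in active])
            links = _assign(prev_xy, xy, params.max_displacement_um)
        else:
            links = []
        linked_curr = set()
        for pi, ci in links:
            row = sub.iloc[ci]
            tr = active[pi]
            tr["frames"].append(f)
            tr["x"].append(float(row["x_um"]))
            tr["y"].append(float(row["y_um"]))
            tr["irc"].append(float(row["irc"]) if has_irc else np.nan)
            tr["last_frame"] = f
            linked_curr.add(ci)
        for ci in range(len(sub)):
            if ci in linked_curr:
                continue
            row = sub.iloc[ci]
            active.append({
                "frames": [f], "x": [float(row["x_um"])],
                "y": [float(row["y_um"])],
                "irc": [float(row["irc"]) if has_irc else np.nan],
                "last_frame": f, "start": (f, float(row["y_um"]),
                                           float(row["x_um"])),
            })
    finished.extend(active)

    finished.sort(key=lambda tr: tr["start"])
    tracks = []
    for tr in finished:
        if len(tr["frames"]) < params.min_track_length:
            continue
        tracks.append(Track(
            track_id=len(tracks),
            frames=np.asarray(tr["frames"], dtype=int),
            x_um=np.asarray(tr["x"], dtype=float),
            y_um=np.asarray(tr["y"], dtype=float),
            irc=np.asarray(tr["irc"], dtype=float),
        ))
    return tracks


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    """Tidy per-observation table (track_id, frame, x_um, y_um, irc)."""
    rows = []
    for tr in tracks:
        for i in range(tr.n_frames_observed):
            rows.append((tr.track_id, int(tr.frames[i]), tr.x_um[i],
                         tr.y_um[i], tr.irc[i]))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um",
                                       "irc"])


def table_to_tracks(table: pd.DataFrame,
                    id_column: str = "track_id") -> list[Track]:
    """Rebuild :class:`Track` objects from a tidy table."""
    tracks = []
    for tid, sub in table.groupby(id_column, sort=True):
        sub = sub.sort_values("frame")
        irc = (sub["irc"].to_numpy(dtype=float) if "irc" in sub.columns
               else np.full(len(sub), np.nan))
        tracks.append(Track(int(tid), sub["frame"].to_numpy(dtype=int),
                            sub["x_um"].to_numpy(dtype=float),
                            sub["y_um"].to_numpy(dtype=float), irc))
    return tracks


def frames_for_observation_time(observation_min: float,
                                frame_interval_min: float) -> int:
    """Number of frames corresponding to a total observation time.

    A cell observed on n frames at interval Δt accumulates n·Δt of
    observation (each observed frame represents one acquisition
    interval): 32 min at 2-min sampling ↔ 16 frames.  Distinct from
    ``duration_min`` in :func:`track_summary`, which is the elapsed time
    between the first and last observation, (n − 1)·Δt.
    """
    if observation_min < 0 or frame_interval_min <= 0:
        raise ValueError("need observation_min >= 0 and frame interval > 0")
    return int(round(observation_min / frame_interval_min))


def track_summary(tracks: list[Track],
                  frame_interval_min: float) -> pd.DataFrame:
    """One row per track: span, observation count and observed duration.

    ``duration_min = (n_frames_observed − 1) × frame_interval``; bridged
    gaps count toward the first/last span but not toward observations.
    """
    rows = [(tr.track_id, int(tr.frames[0]), int(tr.frames[-1]),
             tr.n_frames_observed,
             (tr.n_frames_observed - 1) * frame_interval_min)
            for tr in tracks]
    return pd.DataFrame(rows, columns=["track_id", "first_frame",
                                       "last_frame", "n_frames_observed",
                                       "duration_min"])
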