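"""End-to-end analysis: register → detect → track → metrics → classify."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify as _classify
from .detection import SegmentationParams, detect_movie
from .io import Movie
from .metrics import compute_track_metrics
from .registration import DEFAULT_MAX_SHIFT_PX, DriftTrace, correct_drift
from .tracking import LinkingParams, link_detections, track_summary


@dataclass
class PipelineResult:
    aligned: Movie
    drift: DriftTrace
    detections: pd.DataFrame
    tracks_table: pd.DataFrame
    summary: pd.DataFrame
    metrics: pd.DataFrame
    labels: pd.DataFrame
    threshold: float
    mixture_fit: object | None = None


def run_pipeline(movie: Movie,
                 max_shift_px: int = DEFAULT_MAX_SHIFT_PX,
                 segmentation: SegmentationParams | None = None,
                 linking: LinkingParams | None = None,
                 fixed_threshold: float | None =
                 _classify.DEFAULT_FIXED_THRESHOLD,
                 bin_width: float = _classify.DEFAULT_BIN_WIDTH,
                 subpixel: bool = False) -> PipelineResult:
    """Run the whole shape-based tracking analysis on one movie.

    With ``fixed_threshold`` set (default 0.35, the canonical cut) the
    DSC/RSC split uses that value; pass ``fixed_threshold=None`` to fit
    the two-Gaussian mixture to this movie's MRC histogram and use its
    local minimum instead (requires enough tracks for a stable
    histogram).
    """
    from .tracking import tracks_to_table

    aligned, drift = correct_drift(movie, max_shift_px, subpixel=subpixel)
    detections = detect_movie(aligned.cells, segmentation,
                              aligned.pixel_size_um)
    tracks = link_detections(detections, linking)
    metrics = compute_track_metrics(tracks, aligned.frame_interval_min)

    fit = None
    if fixed_threshold is not None:
        threshold = fixed_threshold
    else:
        edges, counts = _classify.build_mrc_histogram(
            metrics["mrc"].dropna(), bin_width)
        fit = _classify.fit_double_gaussian(edges, counts)
        threshold = fit.threshold
    labels = _classify.classify_tracks(metrics, threshold)

    return PipelineResult(
        aligned=aligned, drift=drift, detections=detections,
        tracks_table=tracks_to_table(tracks),
        summary=track_summary(tracks, aligned.frame_interval_min),
        metrics=metrics, labels=labels, threshold=threshold,
        mixture_fit=fit)
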