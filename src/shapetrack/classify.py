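"""Shape-based discrimination of round vs dendritic cell populations.

The per-track Mean Roundness Coefficient is bimodal when two
morphologically distinct populations coexist: dendritiform cells cluster
at low MRC, round cells at high MRC.  This module builds the MRC
frequency distribution, fits a sum of two Gaussians

    f(x) = a1·exp(−(x−µ1)²/2σ1²) + a2·exp(−(x−µ2)²/2σ2²)

to the bin counts by nonlinear least squares, takes the local minimum of
the fitted curve between the two means as the classification threshold,
and labels every track as DSC (dendritic-shaped, MRC below threshold) or
RSC (round-shaped, at or above threshold; the tie goes to RSC by
convention).  A fixed threshold (e.g. the canonical 0.35) may be supplied
instead of the fitted one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from scipy.optimize import curve_fit, minimize_scalar

#: The canonical fixed MRC cut separating dendritic-shaped from
#: round-shaped cells.
DEFAULT_FIXED_THRESHOLD = 0.35

DEFAULT_BIN_WIDTH = 0.05


class FitError(RuntimeError):
    """The two-Gaussian fit is inapplicable or did not converge."""


@dataclass
class MixtureFit:
    """Converged two-Gaussian histogram fit and its derived threshold."""

    amplitudes: tuple[float, float]
    means: tuple[float, float]  # mean1 < mean2
    sigmas: tuple[float, float]
    threshold: float
    r_squared: float
    bin_edges: np.ndarray
    bin_counts: np.ndarray

    def curve(self, x: np.ndarray) -> np.ndarray:
        return _double_gaussian(np.asarray(x, dtype=float),
                                self.amplitudes[0], self.means[0],
                                self.sigmas[0], self.amplitudes[1],
                                self.means[1], self.sigmas[1])


def _double_gaussian(x, a1, mu1, s1, a2, mu2, s2):
    return (a1 * np.exp(-(x - mu1) ** 2 / (2 * s1 ** 2))
            + a2 * np.exp(-(x - mu2) ** 2 / (2 * s2 ** 2)))


def build_mrc_histogram(mrc_values, bin_width: float = DEFAULT_BIN_WIDTH
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-bin frequency distribution of MRC values over [0, 1].

    Bins are right-open [e_i, e_{i+1}) except the last, which is closed
    so that MRC = 1 is counted; counts therefore always sum to N.
    """
    values = np.asarray(mrc_values, dtype=float)
    if values.size == 0:
        raise ValueError("no MRC values")
    if np.isnan(values).any() or (values < 0).any() or (values > 1).any():
        raise ValueError("MRC values must lie in [0, 1]")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts


def fit_double_gaussian(bin_edges: np.ndarray,
                        bin_counts: np.ndarray) -> MixtureFit:
    """Least-squares two-Gaussian fit of a binned MRC distribution.

    Initialization is deterministic: component means start at the two
    most separated prominent peaks of the lightly smoothed histogram,
    sigmas at half their separation, amplitudes at the peak heights.
    Raises :class:`FitError` (with diagnostics, never a silent threshold)
    for unimodal histograms or non-convergence.
    """
    edges = np.asarray(bin_edges, dtype=float)
    counts = np.asarray(bin_counts, dtype=float)
    if len(edges) != len(counts) + 1:
        raise ValueError("need len(bin_edges) == len(bin_counts) + 1")
    if (counts > 0).sum() < 8:
        raise FitError("too few nonzero bins (< 8) for a 6-parameter fit")

    centers = 0.5 * (edges[:-1] + edges[1:])
    smoothed = ndimage.gaussian_filter1d(counts, sigma=1.0, mode="nearest")
    peaks, props = signal.find_peaks(smoothed, prominence=smoothed.max() * .05)
    if len(peaks) < 2:
        raise FitError(
            f"histogram is unimodal after smoothing ({len(peaks)} peak(s) "
            "found); a two-component fit is not identifiable")
    # the two most prominent peaks; among equals prefer wider separation
    order = np.argsort(props["prominences"])[::-1]
    i1, i2 = sorted(peaks[order[:2]])
    mu1, mu2 = centers[i1], centers[i2]
    sep = mu2 - mu1
    p0 = [max(smoothed[i1], 1.0), mu1, max(sep / 2, 1e-2),
          max(smoothed[i2], 1.0), mu2, max(sep / 2, 1e-2)]
    bounds = ([0, 0, 1e-3, 0, 0, 1e-3],
              [np.inf, 1, 1, np.inf, 1, 1])
    try:
        popt, _ = curve_fit(_double_gaussian, centers, counts, p0=p0,
                            bounds=bounds, maxfev=20000)
    except RuntimeError as err:
        raise FitError(f"two-Gaussian fit did not converge: {err}") from err

    a1, m1, s1, a2, m2, s2 = popt
    if m2 < m1:  # order components by mean
        a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
    resid = counts - _double_gaussian(centers, a1, m1, s1, a2, m2, s2)
    ss_tot = float(((counts - counts.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else np.nan

    fit = MixtureFit(amplitudes=(float(a1), float(a2)),
                     means=(float(m1), float(m2)),
                     sigmas=(float(s1), float(s2)),
                     threshold=np.nan, r_squared=float(r2),
                     bin_edges=edges, bin_counts=counts.astype(int))
    fit.threshold = find_threshold(fit)
    return fit


def find_threshold(fit: MixtureFit) -> float:
    """Interior local minimum of the fitted curve between the two means.

    Located on a fine grid over (mean1, mean2) and refined by bounded
    scalar minimization.  Raises :class:`FitError` when the components
    overlap so much that no interior minimum exists.
    """
    m1, m2 = fit.means
    if not m1 < m2:
        raise FitError("component means are not ordered; fit is degenerate")
    grid = np.linspace(m1, m2, 2001)
    vals = fit.curve(grid)
    k = int(np.argmin(vals))
    if k == 0 or k == len(grid) - 1:
        raise FitError("no interior minimum between the component means "
                       "(components overlap too strongly)")
    res = minimize_scalar(lambda x: float(fit.curve(np.array([x]))[0]),
                          bounds=(grid[k - 1], grid[k + 1]),
                          method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def classify_tracks(metrics: pd.DataFrame,
                    threshold: float) -> pd.DataFrame:
    """Label tracks DSC/RSC by their MRC against a threshold.

    DSC if mrc < threshold, RSC otherwise (MRC exactly at the threshold is
    RSC).  Returns (track_id, mrc, label); class fractions are attached as
    ``DataFrame.attrs["fractions"]``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    labels = np.where(metrics["mrc"] < threshold, "DSC", "RSC")
    out = pd.DataFrame({"track_id": metrics["track_id"],
                        "mrc": metrics["mrc"], "label": labels})
    n = len(out)
    out.attrs["fractions"] = {
        "DSC": float((labels == "DSC").sum()) / n if n else np.nan,
        "RSC": float((labels == "RSC").sum()) / n if n else np.nan,
    }
    return out


def empirical_dip(bin_edges: np.ndarray, bin_counts: np.ndarray,
                  lo: float, hi: float) -> float:
    """Diagnostic: center of the lowest raw-histogram bin inside (lo, hi)."""
    centers = 0.5 * (np.asarray(bin_edges)[:-1] + np.asarray(bin_edges)[1:])
    inside = (centers > lo) & (centers < hi)
    if not inside.any():
        raise ValueError("no bins inside the given interval")
    idx = np.flatnonzero(inside)
    return float(centers[idx[np.argmin(np.asarray(bin_counts)[idx])]])
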