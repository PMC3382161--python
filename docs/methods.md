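# Methods

This note documents the models behind `shapetrack`, the defaults and why
they were chosen, the numerical choices, and what the synthetic-data
tests do and do not establish.

## Imaging model and calibration

All analysis operates on 2D frames (maximum-intensity projections of
z-stacks; `registration.max_project`). Default calibration matches the
target imaging regime: 512 × 512 px spanning 280 × 280 µm
(0.546875 µm/px) and one frame every 2 minutes. Coordinates are 0-based
pixels, origin top-left, x = column, y = row; everything downstream of
detection is expressed in µm and minutes.

## Drift correction

Tissue drift is modeled as a per-frame rigid translation shared by both
channels. For each consecutive frame pair the translation maximizing the
normalized (zero-mean, unit-variance) spatial cross-correlation of the
structural channel is found by exhaustive search over ±`max_shift_px`
(the NCC surface is computed with `skimage.feature.match_template` on a
centrally inset window). Per-step shifts accumulate to cumulative shifts
relative to frame 0, and both channels are translated by the negated
cumulative shift, zero-filling exposed borders.

Choices and rationale:

* **Integer shifts by default.** The correlation-argmax scheme is
  integer-valued; an optional parabolic peak interpolation
  (`subpixel=True`) refines it. Sub-pixel interpolation of images blurs
  them slightly, so it stays off by default.
* **Sequential pairwise, not all-to-first.** Robust to slow morphological
  change of the scene; registering frame t against frame t−1 and
  accumulating is equivalent (for a rigid scene) to registering against
  the previous aligned frame without inheriting its zero-filled borders.
  `reference="first"` switches to all-to-first.
* **Normalization.** Plain correlation is sensitive to intensity drift
  (bleaching, laser fluctuation); NCC is not.
* **`max_shift_px = 50` default** (≈ 27 µm): tissue drift is of the same
  order as per-frame cell displacement, and 27 µm comfortably covers
  both.
* Constant (zero-variance) images raise `RegistrationError` rather than
  returning an arbitrary shift; an optional `min_correlation` gate turns
  weak peaks into errors carrying the frame index.
* Only x–y translation is corrected: no rotation, scaling, elastic
  deformation, or z-drift.

## Segmentation and roundness

Per frame: Gaussian smoothing (σ = 1 px) → binarization (Otsu by
default; a fixed threshold is available since no binarization method is
canonical for this data) → optional hole filling → 8-connected
components. Components outside [10, 2000] µm² or touching the image
border (truncated shapes corrupt the roundness estimate) are discarded.

Each surviving component gets

    IRC = 4π · area / perimeter²,

the classical circularity index — the unique standard index that is 1
for a circle, π/4 for a square, and tends to 0 with elongation. The
perimeter uses the Crofton multi-direction estimator, which keeps the
digitization bias small (a naive pixel-edge perimeter can push 4πA/P²
well above 1 for rasterized disks); residual overshoot is clamped so
IRC ∈ [0, 1] always holds. Centroids are unweighted binary-mask
centroids, robust to intensity fluctuation.

## Linking

Between consecutive frames the linker chooses the one-to-one assignment
minimizing Σ d² over links, where candidate links are gated at
d ≤ `max_displacement_um` and an unmatched particle on either side costs
`max_displacement_um²` (the classical null-link cost). The optimum is
computed exactly with the Hungarian algorithm on an augmented cost
matrix; a brute-force enumeration over all partial matchings serves as
the independent oracle in the test suite. Tracks may bridge up to
`memory_frames` missing frames; bridged frames contribute no IRC samples
and a single straight-line segment to path length (unobserved positions
must not fabricate roundness or motion data). Shape is not part of the
linking cost, keeping tracking and classification independent.

Defaults — `max_displacement_um = 20` (≈ 10 µm/min at 2-min sampling,
above reported immune-cell speeds), `memory_frames = 1`,
`min_track_length = 3` — are not prescribed by any source and are fully
configurable.

## Track metrics

MRC, MD, MI and velocity as defined in the README. Two deliberate
choices:

* **Velocity = path length / duration** (mean instantaneous speed), the
  standard motility-assay definition; displacement/duration equals
  MI × velocity and is derivable from the emitted columns
  (`final_displacement_um`, `duration_min`).
* **Stationary tracks get MI = 0 with a `stationary` flag** instead of
  being undefined/dropped.

Two time conventions coexist deliberately: `duration_min` in summaries
is the elapsed first-to-last time, (n − 1)·Δt, while
`frames_for_observation_time` converts a total observation time to a
frame count as n = time/Δt (a cell observed on 16 frames at 2-min
sampling has accumulated 32 min of observation). Both are exposed
because downstream bookkeeping uses both.

## Classification

The MRC histogram uses fixed bins of width 0.05 on [0, 1] (right-open
except the last bin, so counts conserve N). `fit_double_gaussian`
performs bounded nonlinear least squares of a two-Gaussian curve against
bin-center counts with a deterministic initialization: means at the two
most prominent peaks of the lightly smoothed histogram, sigmas at half
their separation, amplitudes at the peak heights — no random restarts.
R² is computed against the bin counts (1 − SSres/SStot), matching a
histogram-curve fit. The classification threshold is the interior local
minimum of the fitted curve between the component means (fine grid +
bounded refinement); when the components overlap so strongly that no
interior minimum exists, or the histogram is unimodal, the fit raises
`FitError` with diagnostics — there is never a silent threshold. The raw
histogram dip (`empirical_dip`) is available as a diagnostic
cross-check. Labels: DSC if MRC < threshold, RSC otherwise; the tie at
exactly the threshold goes to RSC (a strict-inequality definition leaves
equality unassigned; one side must be chosen and documented). A fixed
threshold of 0.35 — the canonical operating point for this assay — can
be supplied to skip the fit, and is the default in `run_pipeline`,
because a single short movie rarely yields enough tracks for a stable
six-parameter histogram fit.

## Group statistics

Two-sided Mann-Whitney U per (metric × contrast), tracks pooled per
group with the track as the statistical unit (no donor-level nesting).
The exact null distribution is enumerated when min(n) ≤ 8 without ties;
otherwise the tie-corrected normal approximation is used. Stars:
`***` p < 0.0001 (deliberately stricter than the common 10⁻³ cut),
`**` p < 0.01, `*` p < 0.05, else `ns`. Primary p-values are
uncorrected for multiplicity, matching common practice for this assay; a
Holm-adjusted column is emitted alongside.

## Synthetic data: what it emulates, what it does not

The generator renders (a) a static collagen-like mesh of random smoothed
line segments, translated per frame by a drift trajectory and overlaid
with Gaussian noise, and (b) two cell populations: filled disks
(round) and star polygons with thin radiating arms (dendritiform),
performing isotropic random walks with fixed step length speed × Δt and
uniform random heading, reflecting at the field edges so tracks are
never censored. Ground truth records true positions before drift, class
labels, applied drift, and rendered mask sizes.

Defaults (chosen once for realism; none is prescribed by a source):
10 round + 3 dendritic cells (≈ the 84/16 split reported for this cell
mixture, at a density that fits a 280-µm field), round speed 3 µm/min
and dendritic 1 µm/min (typical interstitial myeloid-cell speeds, fast
class faster), round radius 5 µm, dendritic arms 5 × 12 µm on a 3-µm
body, drift as a smooth random walk with 2-px per-frame steps rounded to
integer pixels (same order as cell displacement), additive noise
σ = 0.05 of the unit signal amplitude, minimum initial separation 30 µm.

Not emulated: PSF/optics, photobleaching, 3D structure, cell–cell
contact, shape dynamics (a cell's rendered shape class is fixed), or
anisotropic/persistent motion. A green end-to-end test therefore
establishes that the pipeline recovers what the simulator states —
drift, identities, shapes, kinematics — not that it would perform
identically on real tissue, where segmentation and linking errors are
dominated by effects the simulator omits.

The image-free `simulate_track_table` fixture draws per-frame IRC values
from class-conditional truncated normals (defaults N(0.25, 0.05²) for
dendritic, N(0.55, 0.08²) for round, truncated to [0, 1]) and is the
stated world for the mixture-fit tests.

## Numerical notes

* All randomness flows through `numpy.random.Generator` seeded from the
  config seed via `SeedSequence` with a stable per-stream CRC32 key;
  identical config ⇒ bit-identical movies and tables across processes.
* Mixture-fit bounds: amplitudes ≥ 0, means in [0, 1], sigmas in
  [10⁻³, 1]; threshold refinement tolerance 10⁻⁸.
* Assignment ties in linking are broken by the Hungarian implementation
  deterministically; for generic floating-point positions ties have
  measure zero.
* Track ids are assigned by order of first appearance (frame, then
  y, then x), making outputs invariant to input row order.

## Known limitations

* Integer-pixel registration floors localization accuracy at ~0.5 px
  unless `subpixel` is enabled.
* Touching cells merge into one component (no watershed splitting); the
  simulator's minimum-separation constraint sidesteps this, real data
  would not.
* The double-Gaussian fit needs ≥ 8 nonzero bins and two detectable
  modes; small samples should use the fixed 0.35 threshold.
* MI and velocity are 2D-projection quantities; out-of-plane motion is
  invisible and uncorrected.
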