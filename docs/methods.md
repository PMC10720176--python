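# Methods

## Coordinate and shape conventions

All modules share one image convention: x = column, y = row, origin at
the top-left, y increasing downward. An ellipse is stored as
(x_e, y_e, w_e, h_e, a_e): centre, full minor and major axis lengths in
pixels (h_e ≥ w_e enforced at construction, swapping axes and rotating
the angle by 90° when needed), and the major-axis angle in degrees,
counter-clockwise from the x-axis, normalized to [0, 180). Because a
near-circular ellipse has an ill-defined angle, parameter comparisons
treat (w, h, a) and (h, w, a+90°) as the same shape.

## Ellipse fitting

`geometry.fit_ellipse` implements the direct algebraic least-squares
conic fit with the ellipse constraint 4AC − B² = 1 (Fitzgibbon's
method in the numerically stable Halir–Flusser block formulation),
after centring and scaling the input points to unit variance. The
eigenvector satisfying the ellipse constraint is converted to geometric
parameters through the conic's centre and the eigen-decomposition of
its quadratic form. On noise-free points the five parameters are
recovered to ~1e-12 relative error, including from five points on half
an arc — the regime of sparse manual annotations of partially hidden
berries. Collinear, under-determined (< 5 points) and non-elliptical
solutions raise an explicit fit error. (scikit-image's `EllipseModel`
was considered; at the pinned version its estimator fails on a small
fraction of exact inputs, so the fit is implemented here and validated
against an independent conic-residual check.)

Ellipse IoU is computed on 128-vertex polygon approximations
(shapely); the area error of the approximation is far below the 0.01
tolerance at which the tests compare it with a pixel-membership oracle.
The axis-aligned bounding box uses the closed form
half-width = sqrt(A²cos²a + B²sin²a) for semi-axes A, B.

## Detection and segmentation plumbing

The detector and segmenter are *plug-ins*: `detect(tile, offset)` maps
a 416×416 RGB tile to scored boxes in tile coordinates, and
`segment(vignette, transform)` maps a 128×128 vignette to the binary
mask of the complete, de-occluded berry shape. Training such models is
out of scope here; an oracle predictor backed by simulator ground truth
implements the same contract (its score is the visible-contour
fraction, and it only reports berries with ≥ 50% visibility).

Around the predictors:

* **Tiling** — tile origins span 0 … dim−416 per axis with spacing
  ≤ 270 px, so every berry (box diameter < 146 px at typical scales) is
  fully contained in at least one tile. A tile-level box clipped by a
  tile edge is discarded before merging; redundancy between overlapping
  tiles recovers the berry elsewhere. Consequence: a berry whose box
  overhangs the *image* border is not measurable.
* **De-duplication** — greedy NMS by descending score with box-IoU
  threshold 0.70, then a confidence filter (keep score ≥ s). s = 0.89
  is the operating point of the trained detector's score scale; when
  the oracle predictor supplies visibility fractions as scores, runs
  use s = 0.5 so the filter coincides with the measurability rule.
* **Vignettes** — square crop of side max(w_b, h_b)/z with z = 0.75
  centred on the box, zero-padded outside the frame, bilinearly resized
  to 128. The transform stores the integer crop origin and scale, so
  the vignette→image map is exactly invertible.
* **Mask to ellipse** — largest connected component, sub-pixel contour
  at the 0.5 level, direct ellipse fit, parameters mapped back to image
  coordinates. Empty masks and failed fits skip the berry with a
  logged reason; recovery on rasterized masks is within 1 px / 2°.

## Features

Hue lives on the half-circle 0–180° scale (standard hue divided by
two). The berry's raw hue h_raw is the circular mean over the pixels
strictly inside its ellipse, at least dp = max(3, w_e/4) px from the
boundary (computed with an exact Euclidean distance transform on the
rasterized mask) and inside no other ellipse of the frame; a berry left
with no pixel gets no hue. The centred hue is
H = (180 − h_raw − h₅₀) mod 180 with h₅₀ = 100°, the mean raw hue of
berries halfway through colour change; the modulo is taken into
[0, 180) for negative arguments. No low-saturation exclusion is
applied before the circular mean.

Projected area A = (w_e/2)(h_e/2)π. Volume is the sphere of equal
cross-section, V = (4π/3)(A/π)^{3/2}; a printed-form variant with a
cube root exists behind a flag for comparison with other reports but is
dimensionally inconsistent and not used. A constant calibration factor
3.94×10⁻⁶ mL px⁻³ (chessboard-derived, single camera distance)
converts px³ to mL; no per-berry distance correction is attempted.

## Tracking

* **Greedy matching** — one-to-one, closest pairs first, pairs beyond
  δ = 16 px discarded (δ ≈ a quarter of the median berry minor axis,
  which keeps mismatches rare even in dense regions). Ties break by
  lowest index in each set, making the matching deterministic.
* **Registration** — affine coherent point drift: EM over a Gaussian
  mixture centred on the moving points with a uniform outlier
  component (weight 0.1), tolerance 1e-6 on the variance update, at
  most 200 iterations. Both point sets are normalized to zero mean and
  unit RMS radius before EM — without this the near-uniform
  responsibilities of the first iterations collapse the affine map —
  and the transform is mapped back to pixel units afterwards. Sets
  with fewer than 3 non-collinear points are returned unchanged.
* **Set distance** — d(S_i, S_j) = median over c ∈ S_i of the nearest
  distance to S_j (even counts: mean of the two middle values);
  D symmetrizes by averaging both directions. The N×N matrix holds
  m_ij = D(S_i, S̃_j) with S_j registered onto S_i.
* **Matching tree** — grown greedily from the root: while some
  unplaced frame has d_min = min(m_ij, m_ji) < θ = 8 px to a placed
  frame, the closest such frame is attached (child depth = parent
  depth + 1); when none qualifies, a single *long-distance* edge
  attaches the globally closest unplaced frame, ties resolved in
  favour of the deepest placed parent so that successive breaks chain
  rather than fan out. The root is chosen to maximise the number of
  frames placed before the first long-distance edge — equivalently the
  size of the root's θ-connected component — with ties broken by the
  largest point count, then the earliest frame.
* **Propagation** — labels are integers assigned in reading order at
  the root; edges are processed in breadth-first depth order, each
  child registered onto its *parent* (local registration is better
  conditioned than registering onto the root) and matched under δ;
  matched observations inherit labels, unmatched ones stay unlabeled
  (−1). The chronological baseline (chain tree, no registration) is
  available for ablation.

## Kinetics

Per-berry series are smoothed with a centred 8-day moving median on the
time axis (windows truncated at the ends, so irregular sampling is
handled). Berries tracked over < 90% of the experiment are dropped,
then the 10% with the highest raw-vs-smoothed volume MAPE (count
dropped = floor(0.1 n); the rule is a quantile, applied even to clean
cohorts). Baselines: X₀ = median of the raw series over the first 8
days; X_max = max of the *smoothed* values over the last 8 days for V,
median over the last 8 days for H. X_r = (X − X₀)/X₀ and
X_s = (X − X₀)/(X_max − X₀); zero dynamic range flags the berry as
degenerate and excludes it from descriptor summaries. Crossing times
use the first upward crossing, linearly interpolated; V crossings are
evaluated on the smoothed curve, H crossings on the raw hue (hue
averages many pixels and is far less noisy than area). RD = Δt/0.7
between the 0.15 and 0.85 crossings of V_s; RS = ΔV_r/Δt on the same
interval. The mean berry is the calendar-day (floor of time) average of
volumes and hues across berries, run through the identical pipeline.

Two properties of these definitions are worth knowing. First, the
logistic tail leaks into the first-8-day baseline, so even noise-free
recovery of RD and onset carries a fraction-of-a-day bias that grows
when growth resumes within ~8 days of the series start. Second, RD is
sensitive to measurement noise through V_max: the max-of-smoothed rule
picks up positive noise excursions, and the 0.85 crossing then falls
on the flat top of the logistic where a small level shift translates
into a delay of days. At 5% per-frame multiplicative volume noise
(the cohort default here) the median RD error is ~2 days even though
onset stays within 1 day; at the sub-1% noise typical of pixel-level
rasterization jitter both recover to well under a day.

## Simulator

The simulator is 2D with a depth order (no true 3D): berries are
Gaussian-scattered ellipses around the image centre with a minimum
spacing, initial semi-minor axes 22–34 px at the nominal 2048×2448
frame, aspect ratios 1–1.25. Volume follows
V(t)/V₀ = 1 + a·L(t) with L a logistic whose 15–85% rise spans
`rise_days` (default 18 days) and a = 0.6 (+60% volume), onset defined
as the 15% crossing; an optional linear shrivel follows the peak. Raw
hue descends circularly from green (80°) through red to dark
red-violet (170°), with the coloration logistic lagging growth onset
by 4 days. Each frame applies an absolute affine jitter about the
image centre (uniform translation, rotation, scale within configured
bounds) plus persistent events: `rotation` (an abrupt bunch/camera
rotation that later events can undo) and `shuffle` (a non-affine
rearrangement that tracking cannot and should not bridge).
Visibility is the fraction of 64 boundary-arc samples not covered by
shallower berries, matching the visible-contour measurability rule
rather than area overlap. Rendering paints berries back to front as
filled ellipses in HSV with additive pixel noise. Everything derives
from one seed; identical configs give bit-identical output.

Named scenarios fix the study conditions: `static`,
`nominal_jitter` (60 berries, 100 frames at 8 h, shift ≤ 10 px,
rotation ≤ 3°, scale ≤ 1%), `rigid_rotation_event` (20° rotation at
frame 40, undone at 70), `nonaffine_break` (shuffle at frame 30),
`dense_occlusion`, `mini_render` (small frames for image-pipeline
work), and `asynchronous_cohort` (50 berries, 210 frames, onsets
uniform over 18 days = one rise duration, 5% multiplicative volume
noise; the span is chosen so every berry shows both plateaus, which
the baseline definitions require). With that onset spread the
daily-averaged mean berry overestimates the median individual RD by
~7–16% — convolving the logistic with an 18-day uniform onset
distribution widens the 15–85% rise from 25.7 to ~29.8 days in closed
form; substantially larger overestimates require onset spreads that
exceed the rise duration.

What the simulator does *not* emulate: leaves, stems and other
distractors; photometric variation (shading, blur, white balance);
3D perspective and per-berry camera distance; non-elliptical berry
outlines. Tests passing on synthetic data therefore validate the
geometry, matching and kinetics machinery under the stated motion and
occlusion regimes, not the trained detectors' robustness to real
imagery.

## Evaluation

Detections are scored by greedy one-to-one matching on descending
ellipse IoU with IoU > 0.5 required (strictly greater); matched pairs
are TP, the rest FP/FN, and precision/recall/F1 follow as percentages.
Areas of matched pairs are compared by bias, RMSE, MAPE and R².
Tracking is scored by coverage T_c (share of observations that
received a label) and precision T_p (share of labels whose
observations all designate one true berry), computed exhaustively
against simulator identities.

## Problem sizes

The test-suite and acceptance scenarios run the full distance-matrix
construction (N² CPD registrations; ~10⁴ for 100 frames, a couple of
minutes on one CPU). The rendered scenario uses 512×512 frames with 12
berries; geometry checks use 10³ random ellipses and 5×10² matching
instances. These sizes were chosen so that every statistic is stable
at the tolerances tested while the whole pipeline remains quick to run
interactively.
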