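# Methods

## Problem and pipeline

A deciduous tree photographed daily across spring traces a characteristic
greenness trajectory: flat while leaf-off, a rapid rise as buds burst and
leaves expand, and a plateau at full leaf. `dashphen` estimates the date that
rise begins from dashcam-style inputs: one RGB frame per day and per-frame
bounding-box detections of the tree. The pipeline is

    detections → edge filter → confidence filter → deduplication
               → crop → (ROI mask) → GCC → 3-day rolling mean → green-up date

Every stage is exposed as a library function; the `pipeline` module chains
them and records stage-by-stage accounting so that the number of boxes
removed by each filter is auditable. The pipeline halts on the first stage
error rather than skipping records: with data this sparse (~90 points per
season), silent drops would bias the series.

## Detection filtering

Boxes are integer pixel rectangles, 0-based, origin top-left, half-open
`[min, max)` — under this convention `y_min == 0` means the box touches the
top edge of the frame, the signature of a detection that has ballooned past
the canopy. The cascade removes (1) top-edge boxes, (2) boxes with
confidence strictly below 0.30 (a box at exactly 0.30 is kept), and
(3) duplicates: within each date and class, boxes are visited in descending
confidence and any box overlapping an already-kept box with IoU > 0.5 is
dropped, so exactly the highest-confidence box of each overlap group
survives. Ties in confidence are broken by input order. The edge rule is
y-only by default (an `include_x_edges` flag exists for cameras that clip
laterally).

Detector quality is evaluated with single-class mean average precision:
detections sorted by descending confidence, greedy one-to-one matching to
unmatched same-date truth boxes at IoU ≥ threshold, and the area under the
precision–recall curve with all-point interpolation (the running maximum of
precision integrated over recall steps). All-point interpolation was chosen
over the older 11-point variant because it is the modern convention and has
an exact closed form that an independent enumeration oracle can check.

## Greenness

GCC is computed per pixel and averaged (`per_pixel=True`), the phenocam
convention; the ratio-of-channel-means alternative is available. Pixels
whose channel sum is zero carry no chromatic information and are excluded;
a crop that is entirely black yields an explicit `nan` rather than a value.

Two modes exist because the ratio can be applied either to the native
R, G, B channels or, after an HSV conversion, positionally to (H, S, V).
The `rgb` mode is the standard literature index and is exactly invariant to
global multiplicative illumination before 8-bit quantization; the `hsv` mode
reproduces workflows that convert to HSV to mitigate illuminance variation
before forming the ratio, and stretches the index non-linearly. The `gcc()`
function defaults to `hsv` for continuity with that workflow; the pipeline's
`RunConfig` defaults to `rgb`, which we recommend for new analyses and which
makes threshold crossings directly comparable to the simulator's
green-fraction truth (rgb-GCC is a monotone function of the green fraction).

ROIs are defined in cropped-box coordinates and persisted per tree, so the
same canopy portion is sampled all season even as the detection box wanders.

## Smoothing and transition dates

The rolling mean is calendar-based: the window for output date *d* is
`[d − (w−1)//2, d + w//2]` (for the default `w = 3`: `[d−1, d+1]`), and lost
days simply contribute nothing — with a daily capture protocol and missing
days, an observation-count window would mix unequal time spans. Output dates
supported by fewer than `min_obs = 2` observations are emitted as missing.

Green-up (threshold method, default): baseline = mean of the first 5 valid
smoothed values (capture deliberately starts pre-green-up); ceiling = 95th
percentile of valid smoothed values (robust to single bright frames);
amplitude = ceiling − baseline; green-up = first date above
`baseline + 0.10 × amplitude` whose next two valid observations are also
above it. The three-observation persistence guard exists because a single
sunny morning can push one smoothed value over the threshold; smoothing
alone does not prevent that. Seasons whose amplitude is below 0.02 raise a
"no seasonal signal" error instead of returning a meaningless date. The
plateau is the same sustained crossing at 90% of amplitude and is reported
as absent when greenness is still rising at the series' end. The 10%
amplitude-threshold convention follows the fixed-phenocam literature on
start-of-season dates; the fraction is configurable.

The logistic alternative fits `baseline + amplitude/(1 + exp(−k(t − t₀)))`
by least squares (bounded Levenberg–Marquardt via trust-region, initial
values from the data, `k ∈ [1e-4, 5]`), and reports the analytic crossing
`t₀ − ln((1−f)/f)/k`. Non-convergence falls back to the threshold method
with a warning. On noiseless logistic series the fit recovers (t₀, k) to
well under 1%.

Dates are ISO calendar dates throughout; day-of-year is written alongside in
output tables.

## The synthetic season simulator

The simulator provides the ground truth the method is validated against. It
emulates: a ~90-day daily capture with Bernoulli missing days; a logistic
green fraction g(day) rising from `baseline_green = 0.05` to
`max_green = 0.9` with midpoint day 40 and rate 0.3/day; per-day global
illumination multipliers uniform in 1 ± 0.1; canopy-centre jitter (σ = 3 px)
from varying vehicle position; occasional grey occluders (10% of frames);
and a detector that always returns the true box at confidence 0.99 plus,
with probabilities 0.2 / 0.15 / 0.15, a shifted duplicate (confidence
0.5–0.95), a spurious low-confidence box (< 0.30), and a box touching the
top edge — rates in line with the duplicate-box and outlier frequencies
reported for real roadside detectors. An optional `box_noise_px` blurs the
detector's own localisation around the truth (0 by default; 8 px is used in
the detection-evaluation experiment as a realistic imprecision of roughly
6% of the box size).

The canopy is an ellipse whose colour is the continuous blend
`(1−g)·branch + g·leaf` of fixed branch (85, 70, 55) and leaf (70, 160, 60)
colours, modulated by a season-constant multiplicative texture field.
Because texture and illumination are both multiplicative, the unquantized
per-pixel rgb-GCC of the canopy equals the GCC of the blended colour
exactly, giving a closed-form greenness truth curve
(`canopy_gcc_curve`) that is strictly monotone in g; the rendered 8-bit
frames add only rounding noise (≲ 0.5%). The true green-up and plateau
dates are the 10% and 90% amplitude crossings of the green-fraction curve.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: discrete leaf/branch structure and within-canopy
colour heterogeneity beyond the texture field; sky colour changing with
weather (the background is constant up to the global multiplier); shadows
cast on the canopy; perspective and scale changes as the vehicle's distance
varies; chromatic (non-multiplicative) illumination changes such as golden-
hour light, to which GCC is *not* invariant; and multiple overlapping trees.
Recovery results on synthetic seasons are therefore a validity check of the
algorithmic chain, not a field-accuracy claim.

Determinism: one seeded `numpy` generator drives a season, with the draw
order documented in the module docstring; identical configurations reproduce
frames, boxes and truth byte for byte.

## Numerical and design choices

- GCC is a monotone but slightly concave rational function of the green
  fraction (the branch and leaf colours have different channel sums), so the
  10%-amplitude crossing on the GCC scale sits ~1 day earlier than on the
  green-fraction scale; the estimator's small early bias on synthetic
  seasons is this geometry, not an implementation artefact.
- Rounding: green-up dates from the logistic method round `t₀ − ln(9)/k` to
  the nearest whole day; the threshold method returns an observed date.
- Degenerate inputs: empty pixel sets, empty series, empty truth sets and
  out-of-bounds boxes raise typed errors naming the offence; constant series
  raise "no seasonal signal".
- When several frames share a date in directory mode, the detection with the
  highest post-filter confidence is used — an automated proxy for manual
  optimum-view frame selection.

## Problem sizes

The test suite validates green-up recovery on 50 seeded seasons of 90 days
at 320 × 240 px (the acceptance script uses the same), the noise-response
property at 3 illumination levels × 40 seeds, and mAP against an exhaustive
enumeration oracle on fixtures of ≤ 10 boxes; these sizes give stable Monte
Carlo estimates while keeping a full run around two minutes on one CPU.
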