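# Methods

This note documents the models, numerical choices and limitations behind
`glucast`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A CGM trace is a uniform 5-minute grid (`GlucoseSeries`): anchor timestamp
`t0`, values in mg/dL, and an explicit boolean mask for missing slots.
Missingness is never encoded as a sentinel; values at masked slots are NaN
and the mask is authoritative. Timestamps are timezone-naive local clock
time, because the calendar features (day part, hour of day) describe the
patient's day, not UTC. Raw device events are snapped to wall-clock
5-minute boundaries within a 60 s tolerance (ties toward the earlier slot;
collisions keep the nearer event; farther events are dropped and tallied).
The snapping rule is an assumption — real devices jitter and no single
convention is standard — but it is deterministic and documented.

## Hybrid imputation (training variant)

Gaps — maximal runs of missing slots — are processed left to right and
routed by length:

| length (slots) | branch |
|---|---|
| 1–11 (< 1 h) | cubic spline |
| 12–50 | ARIMA forecast + purge |
| ≥ 51 | cut the series |

Boundary choices at exactly 12 and 50: "fewer than 12" is read as ≤ 11, the
ARIMA band is the closed interval [12, 50], and after the purge step a
remaining missing count < 12 is re-interpolated while ≥ 12 splits the
series (the count 12 itself is assigned to the split branch).

**Spline.** Not-a-knot cubic splines fitted on up to 24 contiguous present
slots per side of the gap (the scan stops at the nearest missing slot, so
anchors never reach across a cut or an unprocessed gap). Not-a-knot was
chosen because it reproduces cubic polynomials exactly, which gives the
test suite a machine-precision oracle. At least 4 anchors are required;
gaps touching the series boundary have no anchor on one side and are always
cut — interpolation is undefined there. Spline output is floored at
1 mg/dL so pathological extrapolation cannot produce non-positive glucose.

**ARIMA.** Fitted per gap on the contiguous present run immediately
preceding it: minimum 50 slots (else fall back to spline with a warning),
maximum 288 slots (one day — ample context at 5-minute cadence, chosen to
bound fit cost). Order is selected by AIC over the 18-point grid
p ∈ {0..2}, d ∈ {0, 1}, q ∈ {0..2}, fitted by `statsmodels` ARIMA with
concentrated scale; if every candidate fails, order (1,1,0) is tried; if
that fails too, the gap is cut. The gap is filled with the ℓ-step forecast.

**Purge.** An imputed slot is re-blanked iff its value leaves the
physiological reporting range [40, 400] mg/dL or the band mean ± 3 SD of
the 24 *originally observed* values flanking the gap (12 per side, fewer
near a boundary, ε = 10⁻⁹ slack against float jitter on constant flanks).
Only the just-imputed slots are examined; observed values are never
flagged, however extreme — global outliers are deliberately ignored. The
criterion is a documented stand-in: it is local, deterministic, and
scale-appropriate, but no canonical definition exists for this step.

After purging: zero remaining holes → done; fewer than 12 → a second spline
round fills them (anchored partly on surviving ARIMA fills); 12 or more →
the whole gap is dropped and the series is partitioned there.

The output is a list of fully valued, time-disjoint segments with per-slot
provenance (`observed` / `spline` / `arima` / `cut`). Observed values pass
through bitwise unchanged on every path, and segment lengths plus dropped
slots conserve the original grid — both are asserted in tests. Segments
shorter than 29 slots are kept but flagged unusable: they cannot yield a
single supervised window.

## Inference variant

At test time the goals invert: forecasts must stay aligned with the
original grid, so *every* interior gap is spline-filled regardless of
length and the series is never cut. Leading/trailing missing runs, which
cannot be interpolated, are trimmed. The originally-observed mask is
carried alongside so that evaluation uses only real measurements as truth —
filled slots provide model input but are never scored against.

## Features and transform

Nine channels per slot, in fixed order: glucose, diff1, diff6, trend, avg,
std, day_part, day_of_week, hour_of_day. "Past hour" means the 12 samples
ending at and including the current slot; rows without a full in-segment
12-sample history are invalid (the first 11 rows of each segment). The
trend is the OLS slope over that window in mg/dL per 5-minute step; std is
the sample SD (ddof = 1). Day-part boundaries are the clock partition
[0,4), [4,8), [8,11), [11,14), [14,17), [17,21), [21,24) — seven intervals
tracking night / morning / midday / afternoon / evening structure; the
exact cuts are a design choice and configurable. All rolling statistics
look strictly backward (no future leakage, tested by perturbing future
samples).

The transform maps channels to a common scale while staying invertible on
the target: glucose and avg (strictly positive) get a natural log, std
(non-negative) gets log1p, the signed channels diff1/diff6/trend stay
linear; all six are then z-scored with mean/SD fitted on training rows
only and frozen. Calendar channels are divided by their range into (0, 1].
Targets are modeled in transformed space and inverted to mg/dL before any
metric; the round trip is exact to < 10⁻⁹ across 40–400 mg/dL.

## Forecaster

Supervised pairs: a window ends at row t iff rows t−11..t are all valid and
row t+6 exists in the same segment, so a segment of length L yields
max(0, L − 28) windows. The target is the transformed glucose 6 steps
(30 minutes) ahead; windows never span segment boundaries.

Architecture (defaults): 3 stacked vanilla recurrent layers,
h_t = tanh(x_t W_x^T + h_{t−1} W_h^T + b), hidden width 64, input 9, read
over 12 steps; the final hidden state feeds linear(64→64) + tanh and then
linear(64→1) as the regression head ("two linear layers" is read as one
hidden linear block plus the scalar head). Weights initialize uniform in
±1/√64 from a seeded generator. Training: MSE in transformed space, Adam
(lr 10⁻³, β = 0.9/0.999, batch 64), the last 20% of windows in time order
held out for validation (chronological, never random — random splits leak
across overlapping windows), early stopping on validation RMSE with
patience 10 within at most 200 epochs, best-epoch weights restored.
Shuffling permutes window order only. The network and backpropagation
through time are implemented on numpy arrays; at ~30k parameters this
trains a two-week trace in under a minute on one CPU and is exactly
reproducible for a fixed seed. One model is trained per patient/trace.

The skill reference is the persistence baseline, forecast(t+6) = g(t): any
model without genuine predictive content fails to beat it at a 30-minute
horizon.

## Evaluation

RMSE, MAE and R² (about the true mean) in mg/dL; R² is NaN with a warning
when the truth is constant. Classification metrics derive from mapping both
truth and forecast through the glycemic thresholds (< 70 / 70–180 / > 180
mg/dL): a 3×3 confusion matrix, the generalized (multiclass) Matthews
correlation (c·s − Σ p_k t_k) / √((s² − Σ p_k²)(s² − Σ t_k²)) with 0 on a
degenerate denominator, and per-class precision/recall/F1 with 0 on zero
denominators. Clarke Error Grid zones use the canonical 1987 piecewise
inequalities with rule order fixed A → E → C → D → else B; the suite pins
the assignment against an independently coded reference on a dense
[20, 600]² grid. When an originally-observed mask is supplied, every metric
is computed only over masked points.

## Synthetic generator

`simulate_trace` emulates the statistical texture of a CGM stream, not its
physiology: baseline 120 mg/dL; a 24 h cosine of amplitude 15 mg/dL peaking
mid-afternoon; three daily meals (08:00, 13:00, 19:00, ±20 min jitter) with
log-normal amplitudes clipped to 40–90 mg/dL and a gamma-shaped
rise/decay kernel (peak at 30 min, tail scale 120 min / 4); stationary
AR(1) noise (φ = 0.8, SD 5 mg/dL); everything clipped to 40–400 mg/dL.
These defaults produce hour-scale learnable structure — meal and circadian
excursions a forecaster can anticipate — so beating persistence is possible
but not trivial. `inject_missingness` places Poisson(rate × days) gaps
(default 2/day) uniformly away from the first/last 12 slots,
non-overlapping and separated by at least one observed slot, with lengths
drawn 60/30/10% from the short (1–11), medium (12–50) and long (51–150)
regimes — deliberately mirroring the routing thresholds so every
imputation branch is exercised. Trace and gap seeds are independent.

What passing tests on this generator do **not** show: real CGM exhibits
sensor drift and recalibration jumps, compression artifacts, skewed and
patient-specific meal/insulin dynamics, and missingness correlated with
glucose level (e.g. compression lows at night). Error magnitudes on real
data will differ; the synthetic studies validate the pipeline's mechanics
and relative skill, not clinical performance.

## Problem sizes

The end-to-end surrogate study (tests and `scripts/acceptance.py`) uses one
simulated patient, 14 days (4032 slots), trained on the first 11 days and
evaluated on the last 3 — large enough for several hundred held-out,
originally observed targets and a stable skill comparison, while a full
seeded run stays in the tens of seconds. Unit and property tests use
1–6-day traces.

## Known limitations

- ARIMA order search cost dominates preprocessing (~1 s per medium gap);
  the one-day history cap bounds it.
- The purge criterion and the day-part boundaries are reasonable but
  unvalidated conventions; both are centralized constants.
- A forecaster trained on a quasi-normoglycemic synthetic patient rarely
  predicts the minority classes, so 3-class MCC on synthetic studies can sit
  near 0 even when regression skill is clear — a property of the simulated
  class balance, not of the metric implementation.
- The OhioT1DM XML reader parses the glucose stream only; insulin, meal and
  exercise streams are out of scope by design.
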