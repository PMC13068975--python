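# glucast

Short-horizon blood-glucose forecasting from continuous glucose monitoring
(CGM) data, for researchers and engineers building diabetes decision-support
tools. Given a single-channel CGM trace sampled every 5 minutes, `glucast`
predicts the glucose level 30 minutes ahead (6 samples) and evaluates the
forecasts both numerically and clinically.

The pipeline has four stages:

1. **Hybrid gap imputation.** CGM traces lose samples (sensor warm-up,
   drop-outs). Gaps are routed by length ℓ: ℓ ≤ 11 slots → not-a-knot cubic
   spline interpolation; 12 ≤ ℓ ≤ 50 → ARIMA(p, d, q) forecast across the gap
   (order chosen by AIC over p ∈ {0..2}, d ∈ {0, 1}, q ∈ {0..2}), followed by
   a purge of implausible fills (outside 40–400 mg/dL or beyond ±3 SD of the
   24 flanking observations) and a second spline round if fewer than 12 slots
   remain missing; ℓ ≥ 51 → the series is cut into separate segments.
2. **Feature engineering.** Nine channels per time step: glucose, diff1
   (g_t − g_{t−1}), diff6 (g_t − g_{t−6}), one-hour OLS trend slope, one-hour
   mean and sample SD (12-sample trailing windows), day part (1–7), day of
   week (1–7), hour of day (1–24). Strictly positive channels are
   log-transformed, everything is standardized with training statistics only,
   and each reading is labeled hypoglycemic (< 70 mg/dL), normal
   (70–180 mg/dL) or hyperglycemic (> 180 mg/dL).
3. **Recurrent forecaster.** Windows of 12 steps × 9 channels feed a stack of
   3 vanilla tanh RNN layers (hidden 64) and two linear layers (64 → 64 → 1),
   trained with Adam (lr 10⁻³, batch 64, MSE loss) and chronological early
   stopping — implemented directly in numpy with backpropagation through
   time, so runs are bitwise reproducible on CPU.
4. **Clinical evaluation.** RMSE / MAE / R² in mg/dL, the 3-class Matthews
   correlation coefficient over glycemic states, per-class
   precision/recall/F1, and Clarke Error Grid zone percentages (A accurate …
   E dangerous). At inference time gaps are spline-filled *without*
   thresholds and never cut, and all metrics are restricted to slots that
   were actually observed in the original file.

Because benchmark CGM datasets such as OhioT1DM are distributed only under
data-use agreements, the package ships a seeded synthetic CGM generator
(circadian sinusoid + gamma-shaped meal excursions with log-normal amplitudes
+ AR(1) sensor noise, clipped to 40–400 mg/dL) with controllable missingness
in the same three gap regimes, so every stage is testable end to end. An
optional reader for the OhioT1DM XML event format is included for users who
hold the data.

## Worked example

```bash
glucast run-all --seed 3 --days 4 --test-days 1 --max-epochs 5 --out-dir run/
```

simulates 5 days of CGM for one synthetic patient, trains a personalized
forecaster on the first 4 days (hybrid imputation, feature transform fitted
on training rows only), and scores the held-out last day with the inference
pipeline. It prints progress lines per stage and finally:

```
INFO glucast: evaluate: n=230 rmse=19.12 mg/dL (persistence 20.35)
{"rmse": 19.120174376251985, "persistence_rmse": 20.34683490870905, "n": 230}
```

Here `n` is the number of originally observed 30-minute-ahead targets in the
held-out day, `rmse` the trained model's error on them, and
`persistence_rmse` the error of the naive "glucose stays where it is"
baseline — the model must beat it to demonstrate any forecasting skill (even
this 5-epoch toy run does). `run/report.json` holds the full evaluation:
R², MCC, per-class metrics and Clarke zone percentages.

The same pipeline is available as a library:

```python
from glucast import run_study
study = run_study(seed=1)          # 14 simulated days, 3-day held-out tail
print(study["rmse_mgdl"], study["persistence_rmse_mgdl"], study["ceg_zone_A_pct"])
# 14.897270130736324 17.4088704000363 94.61325966850829
```

Individual stages (`load_series`, `impute_hybrid`, `derive_features`,
`make_windows`, `train_model`, `evaluate_forecasts`, …) are importable from
`glucast` directly; see the module docstrings.

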