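# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind the package, in the order the pipeline runs.

## Synthetic tracker data

The generator emulates what a consumer wrist tracker exports, not
physiology. Three facts about such data drive its design:

1. **Calories and footsteps co-occur.** Both are logged per *activity
   episode* — an interval for which the tracker reports only totals. The
   generator draws, per episode, a duration (truncated normal, mean 15 min,
   SD 5, hard cap at mean + 4 SD) and a cadence (truncated normal, 80 ± 15
   steps/min), sets `steps = duration × cadence`, and computes calories as
   resting burn (1.2 kcal/min) plus 0.04 kcal per step, times a relative
   noise factor of SD 0.25. The noise factor matters: without it calories
   are an exact affine function of steps and their Pearson correlation is
   1.0, whereas tracker energy equations also use heart rate, age and body
   metrics; with it, the per-minute correlation lands near 0.96 (real
   trackers report values around 0.89).
2. **Heart rate is decoupled from activity.** The heart-rate process is
   baseline 72 BPM + a 24-h sinusoid (amplitude 6 BPM, peak 17:00) + a
   stationary AR(1) (coefficient 0.97, innovation SD 1.5 BPM), sampled at
   exponentially distributed intervals (mean 120 s) to mimic the tracker's
   irregular logging. An `hr_activity_coupling` term (BPM per step/min)
   exists but defaults to 0, which reproduces the near-zero heart-rate
   correlations typical of mild-intensity everyday data.
3. **Step autocorrelation lives at the episode scale.** With episode starts
   drawn uniformly at random each day, the per-minute step series
   autocorrelates strongly at lags up to roughly the episode duration and is
   statistically flat beyond ~3× the mean duration.

Schedule regularity is a single scalar: with probability `regularity` an
episode starts at the user's fixed daily template time, otherwise
uniformly at random. The default is 0. This is deliberate: a repeating
daily schedule *is* long-range structure — it plants genuine ACF mass at
the template's separation lags — so a nonzero default would contradict the
flat-beyond-episode-scale signature above. Regularity is raised explicitly
when the regular-vs-irregular predictability contrast is the object of
study; at `regularity = 1` the same clock times recur every day and the
between-day variance of the daily step profile collapses.

Episode counts are `round(episode_rate)` per day (8 by default — commuting
legs, errands and a workout for an active student is a plausible order).
Resting energy is exported as zero-step background episodes of at most 60
minutes so the episode CSV format is uniform and the downstream
mean-distribution step is exercised everywhere. All randomness flows from
one seed through named `SeedSequence` child streams (episodes, heart-rate
process, heart-rate sampling), so identical profiles give bitwise-identical
output on any platform.

**What the generator does not emulate:** accelerometer waveforms, sleep
staging, heart-rate response to exercise (unless coupling is enabled),
device dropout/non-wear gaps, and inter-user physiological covariates.
Passing tests on synthetic data therefore demonstrate correctness of the
pipeline and qualitative reproduction of the field's statistical
signatures — not clinical validity on real wearers.

## Preprocessing

* **Heart rate** is linearly interpolated onto the minute grid; outside the
  observed range the nearest event's value is extended constantly, which
  avoids extrapolation artifacts at the log boundaries.
* **Episode totals** are spread uniformly: each covered minute receives the
  episode mean (`total/duration`); a minute overlapped for a fraction f
  receives f times the mean, so fully contained episodes conserve their
  totals exactly. Episodes are half-open `[start, end)` — abutting episodes
  never double-count a boundary minute. Overlapping episodes are an error;
  episodes sticking out of the grid are clipped with a warning.
* **log(1+x), not log(x):** step and calorie minutes are frequently exactly
  zero, and log1p is the standard skew-taming transform that keeps them
  finite (0 maps to 0).
* **Min–max bounds are fixed physiological extremes** (HR 30–220 BPM,
  calories 0–20 kcal/min, steps 0–220 steps/min), not data minima/maxima:
  normalization must not depend on the observed sample, or train and test
  spans would be scaled differently. Out-of-range values (tracker
  artifacts) clip to the boundary with a warning rather than aborting a
  months-long run. The forward chain (log1p → min–max) is exactly
  invertible and the package round-trips it to 1e-9 relative.
* A gap-free minute grid is assumed; wear-time gaps are not modeled.

## Models and training

All forecasters map an input window of `input_len` minutes to an output
window of `output_len` minutes in normalized space.

* Single recurrent layer of GRU cells (`hidden_units`, default 52 — the
  width that a fine-grained sweep found best for the many-to-one
  univariate layout). Many-to-one: final hidden state → dropout →
  ReLU dense (width = hidden) → linear map to the whole output window in
  one shot — a direct multi-output head, not autoregressive decoding, which
  is what makes the output length free of the input length. Many-to-many:
  a shared linear head on every step's hidden state, so output length
  equals input length by construction.
* DNN baseline: flattened window → dense 52 (ReLU) → dropout → dense 26
  (ReLU) → linear. OLS baseline: one affine map from the flattened input
  to the flattened output, solved in closed form by least squares
  (`(n·c+1)·m·c` parameters); it ignores the epoch settings.
* Training: Adam at its published defaults (lr 1e-3, β 0.9/0.999), MSE
  loss, batch size 128, inverted dropout 0.2 in every trainable layer
  (training only), validation split 10% of training windows chosen by the
  model seed, early stopping after 5 epochs without validation improvement
  (best parameters restored), max 200 epochs. Patience and epoch caps are
  configurable; the defaults are conventional values, since "train until no
  improvement" does not pin them down.
* Everything is numpy: initialization (Glorot uniform), shuffling, dropout
  masks and the validation split all draw from `default_rng(seed)`, so two
  trainings with the same seed and data are bit-identical. Gradients
  (including full backprop-through-time for the GRU) are verified against
  central-difference numerical gradients in the test suite.

## Experiment harness

* **Walk-forward prediction** tiles the prediction span with consecutive
  non-overlapping output windows, each conditioned on the `input_len` true
  observed minutes immediately before it. Using true past data (rather
  than recursively feeding predictions back) matches per-window SMAPE
  evaluation and avoids compounding error; a recursive mode exists behind a
  flag. Every forecast carries a per-window `(input_start, input_end,
  window_start)` audit, and `assert_no_leakage` verifies that no input
  minute lies at or after its window's start.
* **Length experiments** vary one parameter at a time over fixed grids —
  input 5/15/30/60/120 min, output likewise, both tied, training
  1W/2W/1M/3M/5M, prediction 1D/3D/1W/1M/3M — with the others pinned at the
  defaults (training 1 month, input 15, output 15, prediction 1 week), and
  compare the many-to-one GRU (52 units) against the DNN and OLS baselines,
  one univariate model per channel per user. Calendar conversions are
  fixed: 1 day = 1440 min, 1 week = 7 days, 1 month = 30 days. A setting a
  user's series cannot cover is marked unavailable and the run continues.
* Training windows use stride 1 (maximal sample count); SMAPE/MSE are
  reported in the models' normalized space, per cell of a tidy
  (model, user, channel, setting) table from which all aggregations are
  recomputable.
* The per-(day, clock-time-bucket) MSE profile table supports the
  regularity contrast: a regular user shows day-to-day consistent low-error
  valleys, an irregular one a flat high profile.

One practical note on SMAPE for step data: outside episodes the true step
count is exactly zero while a continuous model's output is merely small, and
each such minute contributes the maximal 200% term. Zero-inflated channels
therefore sit near the SMAPE upper bound even for visually good forecasts —
comparisons between models remain meaningful, absolute step SMAPE less so.
Terms with `y = ŷ = 0` contribute 0 (configurable to be skipped entirely);
the formula is undefined there and zero minutes are the common case.

## Low-activeness windows

Definition 1 marks a 15-minute window less active for one channel when
strictly more than 70% of its minutes (10.5, i.e. at least 11) are strictly
below that calendar day's channel mean; both inequalities are strict, so
exact ties break toward "not less active". Windows straddling midnight
compare each minute against its own day's mean. Definition 2 intersects the
three channels. For forecasts, the predicted labels threshold against the
predicted series' own daily averages by default — the rule stays usable
before the day's true data exist — with a flag to use the true averages
instead. The 2-of-3 vote fuses per-channel predicted labels; note that the
vote (≥2 channels) is scored against the definition-2 truth (all 3
channels), so even a perfect forecaster has recall 1 but not necessarily
precision 1: windows with exactly two low channels are voted positive but
are not definition-2 positives. Precision/recall/F1 use less-active as the
positive class; zero-denominator cases score 0 with a warning.

Window evaluation of forecasts is done on the physical (inverse-
transformed) scale: the log transform is nonlinear, so "below the daily
mean" differs between scales, and daily averages of BPM/kcal/steps are the
interpretable quantity.

## Problem sizes

The test suite and the reproduction script run at desk scale, chosen so the
full pipeline (simulation → preprocessing → training → walk-forward →
window scoring) executes in minutes on one CPU: statistical signatures on a
30-day simulated user (43 200 minutes); forecasting comparisons with 3-day
training and 1-day prediction at input = output = 15 and 52 hidden units;
the end-to-end length-experiment check on input lengths {5, 15}. The
harness accepts the full study grids (multi-month training spans) unchanged
when more time is available.

## Known limitations

* Model quality claims transfer to real tracker data only qualitatively;
  the generator's independence and stationarity assumptions are idealized.
* The step channel's SMAPE saturates near 200% on zero-inflated spans (see
  above).
* No hyper-parameter search beyond the hidden-unit sweep; no LSTM variant
  (GRU only); no cross-user pooling — one model per user per channel.
* Wear-time gaps, device changes and timezone shifts are out of scope; the
  per-minute grid must be complete.
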