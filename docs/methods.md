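# Methods

## Model

Follow-up is partitioned into `n` left-closed, right-open intervals
`[t_{j−1}, t_j)` with `t_0 = 0`. For each individual the network outputs
`surv_pred(j) = 1 − h_j`, the conditional probability of surviving
interval `j` given survival to its start; cumulative survival is the
running product `S_j = ∏_{i≤j} surv_pred(i)`. The likelihood of an
individual failing in interval `j` is `h_j ∏_{i<j} (1 − h_i)`; of a
censored individual, `∏ (1 − h_i)` over the intervals credited as
survived. Because the likelihood factorizes over individuals, the loss
of a mini-batch depends only on that mini-batch, which is what permits
stochastic/mini-batch gradient descent and out-of-core training — the
property that Cox-partial-likelihood approaches lack.

### Target encoding and half-interval credit

`surv_s` marks survived intervals, `surv_f` the failure interval. For
failures, interval membership follows the half-open convention: an event
exactly at a boundary `t_j` belongs to interval `j+1`. For censored
individuals, an interval counts as survived when the censoring time
reaches its midpoint (ties count as surviving, `≥`); for the first
interval the reference point is `t_1/2`. Without this half-interval
credit the discretization would bias survival downward, since censored
individuals observed through most of an interval would contribute
nothing to it.

Degenerate inputs are kept, not dropped: a censored time before the
first midpoint yields all-zero vectors and contributes exactly zero to
the likelihood (the empty product), with a logged warning. An event at
or past `t_n` is clamped into the final interval with a logged warning —
the recommended practice is to extend the last interval past the last
follow-up time of interest, and `make_event_quantile_grid` does this
automatically; clamping is the graceful fallback. Censored times past
`t_n` simply credit every interval. The model provides no survival
predictions past `t_n` (`ExtrapolationError`), by construction.

### Heads

*Flexible*: the last feature layer is densely connected to `n` sigmoid
outputs — log odds of surviving each interval are linear in the
features. Baseline hazard and covariate effects both vary freely with
follow-up time, so non-proportional hazards are representable.

*Proportional hazards*: a single linear predictor `Xβ` (no bias) and `n`
free baseline logits; `surv_pred(j) = sigmoid(base_logits_j)^exp(Xβ)`.
The log survival ratio of two individuals is then `exp(Δ Xβ)` in every
interval — the discrete-time counterpart of the Cox model via the
complementary log–log link. Useful for small samples (n+d parameters
instead of n·(d+1)) and for interpretability.

### Loss and gradients

The loss is the negative log likelihood written bilinearly in
(`surv_s`, `surv_f`, `surv_pred`). Predictions are clipped to
`[ε, 1−ε]`, ε = 1e−7, before logarithms to keep the loss finite; the
analytic gradient is zero where the clip is active (the clip is flat),
so it matches finite differences of the loss as implemented everywhere.
Batch reduction is the sum by default; mean reduction is available and
only rescales the effective learning rate. The quadratic ("heuristic")
loss — `½h²` per survived interval, `½(1−h)²` for the failure interval —
is provided for comparison; it shares the likelihood's minimizer exactly
when the model is saturated (cell-wise `h = d/r`, e.g. any null model),
and only then. The demonstration that the two losses have different
minimizers therefore uses the proportional-hazards head, which is
genuinely constrained (`n+1` parameters against `2n` cells for one
binary covariate); with a flexible head and one binary covariate every
(group, interval) cell has its own parameters and the difference
vanishes by saturation.

All gradients are closed-form backpropagation (dense layers + ReLU;
sigmoid or power-law head) implemented in numpy and verified against
central finite differences at tolerance 1e−5 in the suite. Weight
initialization is Glorot-uniform from the run seed; biases and baseline
logits start at 0 (initial conditional survival 0.5 per interval).

### Training defaults

RMSprop (ρ = 0.9, ε = 1e−7), learning rate 0.01, batch size 256, 1,000
epochs, sum reduction, mandatory seed. These defaults converge reliably
on the simulation designs below; for fits that must reach the exact
optimum (e.g. matching the life-table hazard to 1e−3), the suite uses
staged refinement — successive full-batch fits at learning rates 0.05,
0.005, 0.0005 — since a fixed-rate RMSprop orbits the optimum at a radius
proportional to its learning rate. L2 regularization applies to kernel
weights only (not biases or baseline logits); its strength can be chosen
by k-fold cross-validation (default k = 10) maximizing held-out log
likelihood.

## Time grids

* `make_uniform_grid(width, max_time)` — equal widths; the last boundary
  is the smallest multiple of `width` covering `max_time`.
* `make_halflife_grid(half_life, fractions)` — boundaries at
  `−ln(1−x)·half_life/ln 2`; with equally spaced fractions the widths
  grow geometrically, roughly equalizing event counts per interval under
  exponential-like survival.
* `make_event_quantile_grid(times, events, n)` — boundaries at the
  empirical `k/n` quantiles of event times, extended to the maximum
  follow-up; tied quantiles are deduplicated (reducing `n`) with a
  warning. 15–40 intervals widening with follow-up is the practical
  sweet spot; discrimination is insensitive to the choice (see the
  grid-robustness test).

## Metrics

Kaplan–Meier estimation is delegated to `lifelines`, the concordance
index and censored Brier score to `scikit-survival`, with conventions
pinned by hand-computed fixtures in the suite:

* **C-index**: scores are "higher = better predicted survival" (we rank
  by predicted 365-day survival by default, configurable); comparable
  pairs need the earlier time to be an event; tied scores credit 0.5;
  tied-time pairs where both are events are skipped. Undefined (no
  comparable pairs) raises rather than returning a number.
* **Brier (censored)**: Graf's IPCW form — failures by `t` weighted by
  `1/G(T_i⁻)`, survivors past `t` by `1/G(t)`, censored-before-`t`
  weight 0, `G` the Kaplan–Meier of the censoring distribution. With no
  censoring it reduces exactly to mean squared error.
* **Calibration**: by prediction deciles (rank-based cuts so ties split
  evenly; group-mean prediction vs group Kaplan–Meier at the horizon) or
  by known group (averaged predicted curve — the mean of the
  piecewise-linear per-individual curves, computed as the curve through
  the mean knot values — overlaid on the group Kaplan–Meier).

Between interval ends, survival curves are interpolated linearly in `S`
(a step mode is available); predicted median survival is the 0.5
crossing of that piecewise-linear curve.

## Simulated cohorts

The generators are first-class, seeded, and emit the latent truth for
parameter-recovery tests.

* **Two-group exponential** (default n = 5,000): half the cohort at
  covariate 0 with median survival 200 d, half at 1 with median 400 d;
  independent exponential censoring with half-life 400 d (≈ 2/3 and 1/2
  of each group's events observed, matching the analytic
  `rate_T/(rate_T+rate_C)`).
* **Binary-covariate Weibull** (default n = 5,000): shape 1.2, group
  medians in ratio 2:1, scales solved numerically so the pooled median
  is 182 d, no censoring. Shape and scales are free parameters of this
  design — the published experiment it emulates does not pin them — so
  the absolute C-index of this cohort is a property of these defaults,
  not a universal constant; what the experiment establishes is the
  *invariance* of the C-index across grid layouts.
* **Digit cohort** (default n = 5,139): labels 0–4 uniform, exponential
  survival with scale `365·exp(−0.9·digit)/ln 2` days (median 365 d for
  digit 0 down to ≈10 d for digit 4), uncensored. Covariates are the
  one-hot digit encoding, optionally as several noise-corrupted copies
  standing in for image features; the "perfect model" ranks by the true
  label, with analytic pairwise concordance ≈0.761 for uniform digits.

What these cohorts do **not** emulate: covariate measurement error and
missingness patterns of clinical data, informative censoring, competing
risks, high-dimensional or image inputs. Passing tests show the
estimator and metrics are correct under the stated generating processes,
not that any particular clinical dataset is well modelled.

## Problem sizes in the suite and acceptance script

Unit and property tests run on cohorts of 100–8,000 (one 100,000-draw
Monte-Carlo check of the censoring fraction). The end-to-end tests fit
n = 5,000 cohorts: the calibration-recovery fit uses the full 1,000
epochs; the four grid-robustness fits use 300 epochs each, which is past
convergence for a one-covariate linear model. The acceptance script
averages the perfect-ranking concordance over 5 simulated cohorts and
the two-group crossing times over 3 independent simulate+fit replicates,
seeds derived from `--seed` via `numpy.random.SeedSequence`.

## Known limitations

* No competing risks, time-varying covariates, or calendar-date
  handling.
* No survival predictions beyond the last boundary; extend the grid
  instead.
* The trainer is plain numpy on one CPU: adequate for tabular models of
  this scale, but not a platform for convolutional feature extractors;
  the heads accept any externally computed feature map.
* Checkpoints store parameters as JSON; portable and diffable, but not
  suited to multi-megabyte networks.
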