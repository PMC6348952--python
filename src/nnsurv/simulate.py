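"""Synthetic survival cohorts for the three validation experiments.

Three generators, each reproducible from an integer seed:

* :func:`simulate_two_group` — one binary covariate, exponential survival
  with group medians 200 and 400 days, independent exponential censoring
  with half-life 400 days (defaults; n = 5,000).
* :func:`simulate_weibull_binary` — one binary covariate, Weibull survival
  with the scale depending on the group.  Defaults: shape 1.2, group
  medians in ratio 2:1, scales solved so the pooled median is 182 days,
  no censoring.
* :func:`simulate_digit_cohort` — "digit" labels 0-4 standing in for image
  classes; exponential survival with median ``365 * exp(-0.9 * digit)``
  days (365 d for digit 0 down to ~10 d for digit 4), uncensored.
  Optional noisy one-hot covariate copies stand in for image features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .encoding import SurvivalRecord

__all__ = [
    "SimulatedCohort",
    "simulate_two_group",
    "simulate_weibull_binary",
    "simulate_digit_cohort",
    "digit_median",
    "digit_scale",
    "weibull_default_scales",
    "two_group_event_fraction",
]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class SimulatedCohort:
    """A simulated cohort plus the latent truth that generated it."""

    times: np.ndarray        # observed follow-up (days)
    events: np.ndarray       # 1 = failure observed
    covariates: np.ndarray   # (n, p) model inputs
    latent: pd.DataFrame     # per-individual truth: group/digit, scale, true time
    seed: int

    @property
    def n(self) -> int:
        return self.times.size

    def to_records(self) -> list[SurvivalRecord]:
        return [
            SurvivalRecord(time=float(t), event=int(e), covariates=x)
            for t, e, x in zip(self.times, self.events, self.covariates)
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_days": self.times, "event": self.events})
        for j in range(self.covariates.shape[1]):
            df[f"x{j}"] = self.covariates[:, j]
        return df


def simulate_two_group(n=5000, median0=200.0, median1=400.0, censor_median=400.0,
                       seed=0) -> SimulatedCohort:
    """Two-group exponential cohort with exponential censoring.

    The first half of the cohort has covariate 0 (poor prognosis, median
    survival ``median0``); the second half covariate 1 (median
    ``median1``).  Censoring times are exponential with median
    ``censor_median``, independent of survival; the observed time is the
    minimum and the event indicator marks survival <= censoring.
    """
    if n < 0 or min(median0, median1, censor_median) <= 0:
        raise ValueError("n must be >= 0 and all medians positive")
    rng = np.random.default_rng(seed)
    group = (np.arange(n) >= n // 2).astype(float)
    medians = np.where(group == 0, median0, median1)
    scale = medians / LN2                      # exponential scale = median / ln 2
    t_true = rng.exponential(scale)
    t_cens = rng.exponential(censor_median / LN2, size=n)
    times = np.minimum(t_true, t_cens)
    events = (t_true <= t_cens).astype(int)
    latent = pd.DataFrame({"group": group.astype(int), "scale": scale,
                           "true_time": t_true, "censor_time": t_cens})
    return SimulatedCohort(times=times, events=events,
                           covariates=group[:, None], latent=latent, seed=seed)


def two_group_event_fraction(median_surv, censor_median):
    """Analytic P(event observed) for one group: rate_T / (rate_T + rate_C)."""
    rate_t = LN2 / median_surv
    rate_c = LN2 / censor_median
    return rate_t / (rate_t + rate_c)


def weibull_default_scales(shape=1.2, pooled_median=182.0, median_ratio=2.0):
    """Solve the group scales for the interval-width experiment.

    Group medians are constrained to ``m1 = median_ratio * m0`` (covariate
    1 = good prognosis) and the balanced-mixture median to
    ``pooled_median``: ``0.5 * S0(m) + 0.5 * S1(m) = 0.5`` with
    ``S_g(t) = exp(-(t / scale_g)^shape)``.  Returns ``(scale0, scale1)``.
    """
    def pooled_surv_at(m0):
        s0 = m0 / LN2 ** (1.0 / shape)
        s1 = median_ratio * s0
        t = pooled_median
        return 0.5 * (np.exp(-((t / s0) ** shape)) + np.exp(-((t / s1) ** shape))) - 0.5

    m0 = brentq(pooled_surv_at, pooled_median / 10, pooled_median * 10)
    s0 = m0 / LN2 ** (1.0 / shape)
    return s0, median_ratio * s0


def simulate_weibull_binary(n=5000, shape=1.2, scale0=None, scale1=None,
                            seed=0) -> SimulatedCohort:
    """Binary-covariate Weibull cohort (no censoring).

    With the default ``scale0``/``scale1`` left unset they are solved so
    that group medians are in ratio 2:1 and the pooled median is 182 days.
    ``shape = 1`` reduces to exponential survival.
    """
    if n < 0 or shape <= 0:
        raise ValueError("n must be >= 0 and shape positive")
    if (scale0 is None) != (scale1 is None):
        raise ValueError("provide both scales or neither")
    if scale0 is None:
        scale0, scale1 = weibull_default_scales(shape=shape)
    if min(scale0, scale1) <= 0:
        raise ValueError("scales must be positive")
    rng = np.random.default_rng(seed)
    group = (np.arange(n) >= n // 2).astype(float)
    scale = np.where(group == 0, scale0, scale1)
    times = scale * rng.weibull(shape, size=n)
    events = np.ones(n, dtype=int)
    latent = pd.DataFrame({"group": group.astype(int), "scale": scale,
                           "true_time": times})
    return SimulatedCohort(times=times, events=events,
                           covariates=group[:, None], latent=latent, seed=seed)


def digit_scale(digit, coef=0.9, base_halflife=365.0):
    """Exponential scale parameter beta = base_halflife * exp(-coef*digit) / ln 2."""
    return base_halflife * np.exp(-coef * np.asarray(digit, dtype=float)) / LN2


def digit_median(digit, coef=0.9, base_halflife=365.0):
    """Closed-form median survival: beta * ln 2 = base_halflife * exp(-coef*digit)."""
    return digit_scale(digit, coef, base_halflife) * LN2


def simulate_digit_cohort(n=5139, digits=range(5), coef=0.9, base_halflife=365.0,
                          seed=0, noisy_features=0, noise_sd=0.5) -> SimulatedCohort:
    """Digit-labelled exponential cohort, uncensored.

    Digit labels are drawn uniformly from ``digits``; survival times are
    exponential with scale :func:`digit_scale`, so median survival decays
    geometrically with the digit.  Covariates are the one-hot encoding of
    the digit; with ``noisy_features = k > 0``, ``k`` independently
    noise-corrupted copies of the one-hot block (Gaussian noise,
    ``noise_sd``) stand in for image-like features.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    digits = np.asarray(list(digits))
    rng = np.random.default_rng(seed)
    label = rng.choice(digits, size=n)
    scale = digit_scale(label, coef=coef, base_halflife=base_halflife)
    times = rng.exponential(scale) if n else np.empty(0)
    onehot = (label[:, None] == digits[None, :]).astype(float)
    if noisy_features > 0:
        blocks = [onehot + rng.normal(0.0, noise_sd, size=onehot.shape)
                  for _ in range(noisy_features)]
        covariates = np.hstack(blocks)
    else:
        covariates = onehot
    latent = pd.DataFrame({"digit": label, "scale": scale, "true_time": times})
    return SimulatedCohort(times=times, events=np.ones(n, dtype=int),
                           covariates=covariates, latent=latent, seed=seed)
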