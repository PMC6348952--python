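"""Discrimination and calibration metrics for censored survival data.

Kaplan–Meier estimation is delegated to ``lifelines``; Harrell's
concordance index and the Graf (inverse-probability-of-censoring-weighted)
Brier score to ``scikit-survival``.  The wrappers fix the conventions used
throughout this package:

* ``c_index`` takes scores where **higher = better predicted survival**
  (e.g. predicted 1-year survival probability); tied scores score 0.5 and
  pairs with tied times where both are events are skipped.
* ``brier_censored`` weights individuals failing by ``t`` with
  ``1/G(T_i^-)`` and individuals still under observation with ``1/G(t)``,
  where ``G`` is the Kaplan–Meier estimate of the censoring distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sksurv.metrics import brier_score as _sksurv_brier
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .errors import MetricUndefinedError
from .model import StepSurvivalCurve, survival_at

__all__ = [
    "KMCurve",
    "kaplan_meier",
    "c_index",
    "brier_censored",
    "CalibrationTable",
    "calibration_deciles",
    "calibration_by_group",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate with its underlying life table."""

    event_times: np.ndarray   # distinct times with >= 1 observed event
    survival: np.ndarray      # S(t) at those times (step values)
    at_risk: np.ndarray       # r_j just before each event time
    events: np.ndarray        # d_j at each event time

    def at(self, t):
        """Step-function value(s) S(t); 1 before the first event, last
        value carried forward past the last observed event time."""
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t_arr, side="right")
        vals = np.concatenate(([1.0], self.survival))[idx]
        return float(vals) if t_arr.ndim == 0 else vals


def _as_arrays(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty input")
    return times, events.astype(int)


def kaplan_meier(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimate ``S(t) = prod (1 - d_j/r_j)``."""
    times, events = _as_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    rows = table[table["observed"] > 0]
    event_times = rows.index.to_numpy(dtype=float)
    survival = kmf.survival_function_at_times(event_times).to_numpy()
    return KMCurve(
        event_times=event_times,
        survival=survival,
        at_risk=rows["at_risk"].to_numpy(dtype=float),
        events=rows["observed"].to_numpy(dtype=float),
    )


def c_index(scores, times, events) -> float:
    """Harrell's concordance index.

    ``scores``: higher = longer predicted survival.  A pair is comparable
    when the earlier time is an observed event; the member predicted to
    survive longer should be the one surviving longer.  Tied scores
    credit 0.5; pairs with tied times where both are events are skipped.
    """
    times, events = _as_arrays(times, events)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            value, *_ = concordance_index_censored(events.astype(bool), times, -scores)
    except Exception as exc:  # sksurv NoComparablePairs
        raise MetricUndefinedError(f"concordance undefined: {exc}") from exc
    if not np.isfinite(value):
        raise MetricUndefinedError("concordance undefined: no comparable pairs")
    return float(value)


def brier_censored(times, events, predicted_survival, t) -> float:
    """Censored-data Brier score at horizon ``t`` (Graf et al. weighting).

    ``predicted_survival`` is each individual's predicted probability of
    surviving past ``t``.  Individuals censored before ``t`` get weight 0;
    failures by ``t`` contribute ``S_hat(t)^2 / G(T_i^-)``; individuals
    observed past ``t`` contribute ``(1 - S_hat(t))^2 / G(t)``; the score
    is the mean over the cohort.
    """
    times, events = _as_arrays(times, events)
    pred = np.asarray(predicted_survival, dtype=float)
    if np.any((pred < 0) | (pred > 1)):
        raise ValueError("predicted survival probabilities must be in [0, 1]")
    y = Surv.from_arrays(event=events.astype(bool), time=times)
    try:
        _, score = _sksurv_brier(y, y, pred, float(t))
    except ValueError as exc:
        raise MetricUndefinedError(f"Brier score undefined at t={t}: {exc}") from exc
    return float(score[0])


@dataclass(frozen=True)
class CalibrationTable:
    """Per-group mean predicted survival vs Kaplan–Meier observed survival."""

    table: pd.DataFrame  # columns: group, n, mean_predicted, observed_km
    t: float

    def __post_init__(self):
        assert {"group", "n", "mean_predicted", "observed_km"} <= set(self.table.columns)


def calibration_deciles(times, events, predicted_survival, t, n_groups=10) -> CalibrationTable:
    """Group individuals by quantile of predicted survival at ``t`` and
    compare the group-mean prediction with the group Kaplan–Meier estimate.

    Grouping cuts on the rank of the prediction (ties split as evenly as
    possible).  A perfectly calibrated model puts every row on the
    identity line up to sampling noise.
    """
    times, events = _as_arrays(times, events)
    pred = np.asarray(predicted_survival, dtype=float)
    if times.size < n_groups:
        raise ValueError(f"need at least {n_groups} records for {n_groups} groups")
    ranks = pd.Series(pred).rank(method="first")
    labels = pd.qcut(ranks, n_groups, labels=False, duplicates="drop")
    rows = []
    for g in np.unique(labels):
        sel = labels.to_numpy() == g
        km = kaplan_meier(times[sel], events[sel])
        rows.append({
            "group": int(g),
            "n": int(sel.sum()),
            "mean_predicted": float(pred[sel].mean()),
            "observed_km": km.at(t),
        })
    return CalibrationTable(table=pd.DataFrame(rows), t=float(t))


def calibration_by_group(labels, curves, times, events, time_mesh=None, groups=None):
    """Average predicted survival curve vs Kaplan–Meier, per group.

    Parameters
    ----------
    labels : per-individual group label
    curves : list of StepSurvivalCurve (one per individual, shared grid)
    times, events : observed follow-up data
    time_mesh : evaluation times; defaults to 0 ... t_n on a fine mesh
    groups : optional explicit group order; unknown labels raise

    Returns ``{label: (mesh, mean_predicted, KMCurve)}`` — the standard
    by-group calibration display (average model prediction overlaid on the
    actual Kaplan–Meier curve).
    """
    labels = np.asarray(labels)
    times, events = _as_arrays(times, events)
    if len(curves) != times.size:
        raise ValueError("one predicted curve per individual is required")
    grid = curves[0].grid
    S_matrix = np.vstack([c.S for c in curves])
    if time_mesh is None:
        time_mesh = np.linspace(0.0, grid.boundaries[-1], 200)
    time_mesh = np.asarray(time_mesh, dtype=float)
    if groups is None:
        groups = list(pd.unique(labels))
    out = {}
    for g in groups:
        sel = labels == g
        if not np.any(sel):
            raise ValueError(f"unknown or empty group label {g!r}")
        # the mean of piecewise-linear curves is the piecewise-linear curve
        # through the mean knot values
        mean_curve = StepSurvivalCurve(grid=grid, S=S_matrix[sel].mean(axis=0))
        mean_pred = survival_at(time_mesh, mean_curve)
        out[g] = (time_mesh, mean_pred, kaplan_meier(times[sel], events[sel]))
    return out
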