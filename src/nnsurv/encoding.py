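"""Censored-data target encoding.

Each individual's (time, event) pair is transformed into two binary vectors
of length ``n`` (the number of time intervals):

* ``surv_s`` — the intervals the individual is credited with surviving;
* ``surv_f`` — the single interval in which failure occurred, if observed.

For a failure at time ``t``, ``surv_s(j) = 1`` iff ``t >= t_j`` and
``surv_f`` is 1 in the interval containing ``t``.  For a censored
individual, ``surv_s(j) = 1`` iff the censoring time reaches the interval's
midpoint — individuals censored in the second half of an interval get
"credit" for surviving it, which removes the downward bias a naive
discretization would introduce — and ``surv_f`` is identically zero.

The negative log likelihood of the discrete-time model is a bilinear
function of these vectors and the predicted conditional survival
probabilities, which is what makes mini-batch training convenient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import TimeGrid

logger = logging.getLogger(__name__)

__all__ = ["SurvivalRecord", "SurvivalEncoding", "encode_record", "encode_dataset"]


@dataclass(frozen=True)
class SurvivalRecord:
    """One individual: follow-up time (days), event indicator, covariates."""

    time: float
    event: int
    covariates: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")
        object.__setattr__(self, "covariates", np.asarray(self.covariates, dtype=float))


@dataclass(frozen=True)
class SurvivalEncoding:
    """The paired target vectors for one individual."""

    surv_s: np.ndarray
    surv_f: np.ndarray

    @property
    def n(self) -> int:
        return self.surv_s.size


def encode_dataset(times, events, grid: TimeGrid):
    """Vectorized encoding of a whole cohort.

    Returns ``(surv_s, surv_f)`` float arrays of shape ``(n_individuals,
    grid.n)``.  Event times at or past the last boundary are clamped into
    the final interval with a logged warning (the recommended fix is to
    extend the last interval past the last follow-up time of interest).
    Censored individuals before the first interval's midpoint get all-zero
    vectors: they contribute nothing to the likelihood but are kept.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if np.any(times < 0):
        raise ValueError("negative follow-up time")
    if times.ndim != 1 or events.shape != times.shape:
        raise ValueError("times and events must be equal-length 1-D arrays")

    n = grid.n
    boundaries = grid.boundaries
    mids = grid.midpoints
    is_event = events == 1

    surv_s = np.zeros((times.size, n))
    surv_f = np.zeros((times.size, n))

    # Failures: survived every interval whose upper boundary they reached;
    # failed in the interval containing t (boundary times roll forward).
    t_ev = times[is_event]
    surv_s[is_event] = (t_ev[:, None] >= boundaries[None, :]).astype(float)
    idx = grid.interval_index(t_ev)
    clamped = idx >= n
    if np.any(clamped):
        logger.warning(
            "%d event time(s) at or beyond the last boundary t_n=%g were "
            "clamped into the final interval; consider extending the grid",
            int(clamped.sum()), boundaries[-1],
        )
        idx = np.minimum(idx, n - 1)
    rows = np.flatnonzero(is_event)
    surv_f[rows, idx] = 1.0
    surv_s[rows[clamped], n - 1] = 0.0  # clamped failures did not survive interval n

    # Censored: credit for each interval whose midpoint was reached.
    t_cs = times[~is_event]
    surv_s[~is_event] = (t_cs[:, None] >= mids[None, :]).astype(float)

    n_silent = int(np.sum(~is_event & (times < mids[0])))
    if n_silent:
        logger.warning(
            "%d censored record(s) before the first interval midpoint %g "
            "carry no likelihood information (all-zero encoding)",
            n_silent, mids[0],
        )
    return surv_s, surv_f


def encode_record(record: SurvivalRecord, grid: TimeGrid) -> SurvivalEncoding:
    """Encode a single individual; see :func:`encode_dataset`."""
    s, f = encode_dataset(np.array([record.time]), np.array([record.event]), grid)
    return SurvivalEncoding(surv_s=s[0], surv_f=f[0])
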