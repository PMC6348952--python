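"""Follow-up time grids.

Follow-up time is partitioned into ``n`` left-closed, right-open intervals
``[t_{j-1}, t_j)`` with an implicit origin ``t_0 = 0`` and strictly
increasing upper boundaries ``t_1 < ... < t_n`` (days).  All model targets,
predictions and survival curves are indexed by these intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TimeGrid",
    "make_uniform_grid",
    "make_halflife_grid",
    "make_event_quantile_grid",
]


@dataclass(frozen=True)
class TimeGrid:
    """Ordered interval boundaries partitioning follow-up time.

    Parameters
    ----------
    boundaries
        Upper limits ``t_1 < t_2 < ... < t_n`` of the ``n`` intervals, in
        days.  The origin ``t_0 = 0`` is implicit.  Interval ``j`` (1-based)
        covers ``[t_{j-1}, t_j)``.
    """

    boundaries: np.ndarray = field()

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 1:
            raise ValueError("grid needs at least one boundary")
        if not np.all(b > 0):
            raise ValueError("all boundaries must be positive")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)

    @property
    def n(self) -> int:
        """Number of intervals."""
        return self.boundaries.size

    @property
    def edges(self) -> np.ndarray:
        """All ``n + 1`` interval edges, including the origin 0."""
        return np.concatenate(([0.0], self.boundaries))

    @property
    def midpoints(self) -> np.ndarray:
        """Midpoint of each interval, ``(t_{j-1} + t_j) / 2``."""
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def interval_index(self, t) -> np.ndarray:
        """0-based interval index containing time(s) ``t``.

        A time exactly at a boundary ``t_j`` belongs to interval ``j + 1``
        (half-open convention).  Times ``>= t_n`` return ``n`` (out of
        range); callers decide whether to clamp or raise.
        """
        return np.searchsorted(self.boundaries, np.asarray(t, dtype=float), side="right")

    def __len__(self) -> int:
        return self.n


def make_uniform_grid(width: float, max_time: float) -> TimeGrid:
    """Uniform intervals of the given width, covering at least ``max_time``.

    The last boundary is the smallest multiple of ``width`` that is
    ``>= max_time``, so the final interval may extend past ``max_time``.
    """
    if width <= 0 or max_time <= 0:
        raise ValueError("width and max_time must be positive")
    if max_time < width:
        raise ValueError("max_time must be at least one interval width")
    n = int(np.ceil(max_time / width - 1e-12))
    return TimeGrid(width * np.arange(1, n + 1))


def make_halflife_grid(half_life: float, coverage_fractions) -> TimeGrid:
    """Geometrically widening intervals from an exponential decay clock.

    Boundaries are placed where an exponential with the given half-life has
    decayed by each coverage fraction ``x``: ``t = -ln(1 - x) * half_life /
    ln 2``.  With equally spaced fractions this yields interval widths that
    grow with follow-up time, so that under roughly exponential survival a
    comparable number of events lands in each interval.

    ``coverage_fractions`` must start at 0 (the origin) and increase
    strictly; all fractions must be < 1 (a fraction of 1 would place a
    boundary at infinity).
    """
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    x = np.asarray(coverage_fractions, dtype=float)
    if x.size < 2 or x[0] != 0:
        raise ValueError("coverage_fractions must start at 0 and contain at least one more value")
    if np.any(x >= 1):
        raise ValueError("coverage fractions must be < 1 (1 maps to an infinite boundary)")
    if not np.all(np.diff(x) > 0):
        raise ValueError("coverage fractions must be strictly increasing")
    borders = -np.log1p(-x[1:]) * half_life / np.log(2.0)
    return TimeGrid(borders)


def make_event_quantile_grid(times, events, n_intervals: int) -> TimeGrid:
    """Boundaries at empirical quantiles of the observed event times.

    Places the ``n_intervals`` boundaries at the ``k / n_intervals``
    quantiles (k = 1..n_intervals) of the failure times, so roughly equal
    numbers of events fall in each interval.  The last boundary is extended
    to the maximum follow-up time (events or censorings) if the event
    quantiles fall short, so every record lies inside the grid.

    Duplicate quantile values (heavy ties) are deduplicated, reducing the
    number of intervals, with a logged warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    event_times = times[events == 1]
    if np.unique(event_times).size < n_intervals:
        raise ValueError(
            f"need at least {n_intervals} distinct event times, "
            f"got {np.unique(event_times).size}"
        )
    qs = np.arange(1, n_intervals + 1) / n_intervals
    boundaries = np.quantile(event_times, qs)
    max_followup = times.max()
    if boundaries[-1] < max_followup:
        boundaries[-1] = max_followup
    uniq = np.unique(boundaries)
    if uniq.size < boundaries.size:
        logger.warning(
            "quantile boundaries had ties; grid reduced from %d to %d intervals",
            boundaries.size, uniq.size,
        )
        boundaries = uniq
    return TimeGrid(boundaries)
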