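"""Tabular input/output.

Survival tables are delimited text (comma by default), UTF-8, "." decimal,
header required, with a ``time_days`` column (follow-up in days), a binary
``event`` column, and any number of numeric covariate columns.  Missing
covariate cells are imputed by the column median with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataFormatError

logger = logging.getLogger(__name__)

__all__ = ["SurvivalDataset", "read_survival_table", "write_survival_table",
           "write_survival_curves", "read_survival_curves"]

TIME_COL = "time_days"
EVENT_COL = "event"


@dataclass(frozen=True)
class SurvivalDataset:
    times: np.ndarray
    events: np.ndarray
    covariates: np.ndarray        # (n, p), float, imputed
    covariate_names: list[str]

    @property
    def n(self) -> int:
        return self.times.size


def read_survival_table(path, delimiter=",") -> SurvivalDataset:
    """Parse a survival table; impute missing covariates by column median."""
    df = pd.read_csv(path, sep=delimiter)
    for col in (TIME_COL, EVENT_COL):
        if col not in df.columns:
            raise DataFormatError(f"missing mandatory column {col!r} in {path}")
    events = df[EVENT_COL]
    if not events.isin([0, 1]).all():
        bad = sorted(set(events) - {0, 1})
        raise DataFormatError(f"column {EVENT_COL!r} must be binary; found values {bad}")
    times = df[TIME_COL].to_numpy(dtype=float)
    if np.any(times < 0) or np.any(~np.isfinite(times)):
        raise DataFormatError(f"column {TIME_COL!r} must be finite and >= 0")
    cov_names = [c for c in df.columns if c not in (TIME_COL, EVENT_COL)]
    cov = df[cov_names].apply(pd.to_numeric, errors="raise") if cov_names else df[[]]
    n_missing = int(cov.isna().sum().sum()) if cov_names else 0
    if n_missing:
        cov = cov.fillna(cov.median())
        logger.info("imputed %d missing covariate value(s) by column median", n_missing)
    return SurvivalDataset(
        times=times,
        events=events.to_numpy(dtype=int),
        covariates=cov.to_numpy(dtype=float).reshape(len(df), len(cov_names)),
        covariate_names=cov_names,
    )


def write_survival_table(path, times, events, covariates=None, covariate_names=None,
                         delimiter=","):
    df = pd.DataFrame({TIME_COL: np.asarray(times, dtype=float),
                       EVENT_COL: np.asarray(events, dtype=int)})
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        names = covariate_names or [f"x{j}" for j in range(covariates.shape[1])]
        for j, name in enumerate(names):
            df[name] = covariates[:, j]
    df.to_csv(path, sep=delimiter, index=False)


def write_survival_curves(path, S, boundaries, delimiter=","):
    """One row per individual, one column per interval end; the header
    carries the boundary times."""
    S = np.asarray(S, dtype=float).reshape(-1, len(boundaries))
    df = pd.DataFrame(S, columns=[f"{b:g}" for b in boundaries])
    df.to_csv(path, sep=delimiter, index=False)


def read_survival_curves(path, delimiter=","):
    """Inverse of :func:`write_survival_curves`: returns (S, boundaries)."""
    df = pd.read_csv(path, sep=delimiter)
    boundaries = np.array([float(c) for c in df.columns])
    return df.to_numpy(dtype=float), boundaries
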