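"""Accumulating day-1..t summary features.

For every daily variable (mood + 10 wearables) and every as-of day t, three
statistics summarize the observations from day 1 through day t: the mean and
sample SD of the available values and the percent of days missing. Means
require at least two observed values and SDs at least three; below those
minima the statistic is unavailable (NaN) and is later filled with the
training-fold median inside the cross-validation loop — never globally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import DAILY_VARIABLES, WEARABLE_VARIABLES, CohortDataset

__all__ = [
    "PREDICTOR_SETS",
    "feature_columns",
    "summarize_variable",
    "build_feature_matrix",
    "ImputationModel",
    "fit_imputation",
    "apply_imputation",
]

logger = logging.getLogger(__name__)

PREDICTOR_SETS = ("mood_only", "mood_plus_wearable")

MIN_OBS_MEAN = 2  # fewer observed values than this -> mean unavailable
MIN_OBS_SD = 3  # fewer observed values than this -> SD unavailable

_STATS = ("mean", "sd", "pct_missing")

# Midpoints of each variable's plausible range; last-resort imputation
# constants for mean features with no available training values.
_RANGE_MIDPOINT: dict[str, float] = {"mood": 5.5}
_RANGE_MIDPOINT.update({w.name: (w.lo + w.hi) / 2.0 for w in WEARABLE_VARIABLES})


def variables_for(predictor_set: str) -> tuple[str, ...]:
    if predictor_set == "mood_only":
        return ("mood",)
    if predictor_set == "mood_plus_wearable":
        return DAILY_VARIABLES
    raise ValueError(f"unknown predictor set {predictor_set!r}")


def feature_columns(predictor_set: str) -> list[str]:
    """Feature names in canonical order: 3 per variable (3 or 33 total)."""
    return [f"{stat}_{v}" for v in variables_for(predictor_set) for stat in _STATS]


def summarize_variable(values: Sequence[float]) -> tuple[float, float, float]:
    """(mean, sample SD, percent missing) of one variable over days 1..t.

    ``values`` has one slot per day; NaN marks a missing day. Statistics use
    the available observations only. The mean requires >= 2 observations and
    the SD >= 3; otherwise NaN is returned for that statistic. Percent
    missing is always defined: 100 * (#missing) / t.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("summarize_variable requires a non-empty 1-d sequence")
    t = arr.size
    obs = arr[~np.isnan(arr)]
    n_obs = obs.size
    mean = float(np.mean(obs)) if n_obs >= MIN_OBS_MEAN else float("nan")
    sd = float(np.std(obs, ddof=1)) if n_obs >= MIN_OBS_SD else float("nan")
    pct_missing = 100.0 * (t - n_obs) / t
    return mean, sd, pct_missing


def build_feature_matrix(
    cohort: CohortDataset, t: int, predictor_set: str = "mood_plus_wearable"
) -> pd.DataFrame:
    """Per-participant summary features using days 1..t only (no lookahead).

    Returns a DataFrame indexed by participant_id with 3 columns per variable
    (33 for the full set, 3 for mood-only); unavailable statistics are NaN.
    """
    if not 1 <= t <= cohort.horizon_days:
        raise ValueError(f"t={t} outside 1..{cohort.horizon_days}")
    variables = variables_for(predictor_set)
    window = cohort.daily[cohort.daily["day"] <= t]
    grouped = window.groupby("participant_id", sort=False)[list(variables)]
    counts = grouped.count()
    means = grouped.mean()
    sds = grouped.std(ddof=1)

    out = pd.DataFrame(index=counts.index)
    for v in variables:
        n_obs = counts[v]
        out[f"mean_{v}"] = means[v].where(n_obs >= MIN_OBS_MEAN)
        out[f"sd_{v}"] = sds[v].where(n_obs >= MIN_OBS_SD)
        out[f"pct_missing_{v}"] = 100.0 * (t - n_obs) / t
    # Align to the outcome table's participant order.
    out = out.loc[cohort.participant_ids]
    out.index.name = "participant_id"
    return out[feature_columns(predictor_set)]


@dataclass(frozen=True)
class ImputationModel:
    """Training-fold medians, one per feature column."""

    medians: pd.Series

    @property
    def columns(self) -> list[str]:
        return list(self.medians.index)


def fit_imputation(train_rows: pd.DataFrame) -> ImputationModel:
    """Median of each feature over the available training values.

    A feature with no available training value at all falls back to a fixed
    constant — 0 for SD features, the variable-range midpoint for means —
    with a logged warning.
    """
    if len(train_rows) == 0:
        raise ValueError("cannot fit imputation on an empty training set")
    medians = train_rows.median(axis=0, skipna=True)
    for col in medians.index[medians.isna()]:
        stat, _, var = col.partition("_")
        fallback = 0.0 if stat == "sd" else _RANGE_MIDPOINT.get(var, 0.0)
        logger.warning(
            "feature %s has no available training values; imputing constant %s",
            col, fallback,
        )
        medians[col] = fallback
    return ImputationModel(medians=medians)


def apply_imputation(model: ImputationModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Fill unavailable entries with training medians; never alters a value."""
    return rows.fillna(model.medians)
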