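"""Synthetic daily mood-diary + wearable cohorts.

Generates seeded cohorts with the statistical structure the temporal analysis
assumes: a latent severity trait per person drives daily mood level and
volatility, decaying adherence (missingness rises over the quarter and with
severity), ten Fitbit-style daily streams, and binary end-of-quarter outcomes
(depression, suicidal ideation) at calibrated prevalences.

The latent severity is retained in the outcome table as a truth channel for
recovery tests only; no feature path may read it.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "SyntheticConfig",
    "DailyObservation",
    "ParticipantRecord",
    "CohortDataset",
    "WEARABLE_VARIABLES",
    "DAILY_VARIABLES",
    "ConfigurationError",
    "CalibrationError",
    "CohortParseError",
    "calibrate_prevalence",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]


class ConfigurationError(ValueError):
    """Invalid synthetic-cohort configuration."""


class CalibrationError(RuntimeError):
    """Prevalence calibration failed to converge."""


class CohortParseError(ValueError):
    """Malformed cohort file; message names the offending row."""


@dataclass(frozen=True)
class _WearableSpec:
    """Population model for one daily wearable stream.

    mean/between_sd describe the person-level mean; within_sd the day-to-day
    AR(1) deviation; severity_loading shifts the person mean per SD of latent
    severity when the informative-wearables flag is on; lo/hi are clip bounds.
    """

    name: str
    mean: float
    between_sd: float
    within_sd: float
    severity_loading: float
    lo: float
    hi: float


# Plausible daily ranges for an adult cohort wearing a fitness tracker.
# Sleep times are minutes from midnight (sleep_start ~ 23:00 the prior night).
WEARABLE_VARIABLES: tuple[_WearableSpec, ...] = (
    _WearableSpec("total_sleep", 420.0, 35.0, 45.0, -15.0, 120.0, 720.0),
    _WearableSpec("sleep_start", 1380.0, 45.0, 40.0, 12.0, 1140.0, 1620.0),
    _WearableSpec("sleep_end", 390.0, 45.0, 40.0, 8.0, 120.0, 780.0),
    _WearableSpec("sleep_efficiency", 93.0, 2.5, 3.0, -0.8, 40.0, 100.0),
    _WearableSpec("total_steps", 8000.0, 2200.0, 2500.0, -600.0, 0.0, 40000.0),
    _WearableSpec("sedentary_minutes", 600.0, 80.0, 90.0, 20.0, 0.0, 1440.0),
    _WearableSpec("lightly_active_minutes", 200.0, 50.0, 60.0, -10.0, 0.0, 1440.0),
    _WearableSpec("fairly_active_minutes", 30.0, 12.0, 15.0, -3.0, 0.0, 1440.0),
    _WearableSpec("very_active_minutes", 25.0, 12.0, 15.0, -4.0, 0.0, 1440.0),
    _WearableSpec("resting_hr", 62.0, 5.0, 2.0, 1.5, 35.0, 120.0),
)

WEARABLE_NAMES: tuple[str, ...] = tuple(w.name for w in WEARABLE_VARIABLES)
#: All daily variables in canonical order: mood first, then the ten wearables.
DAILY_VARIABLES: tuple[str, ...] = ("mood",) + WEARABLE_NAMES

_AR1_RHO = 0.5  # day-to-day autocorrelation of wearable deviations


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    The defaults emulate the study conditions the pipeline targets: a
    ~2459-person intern cohort observed daily for one 92-day quarter, daily
    mood on a 1-10 integer scale, end-of-quarter depression prevalence near
    18.5% and suicidal-ideation prevalence near 6.8%, and adherence that
    decays over time and is worse at higher latent severity.

    Parameters
    ----------
    mood_effect : float
        Drop in expected daily mood, in mood points, per SD of latent
        severity.
    mood_volatility_effect : float
        Log-linear link from severity to the person's daily mood SD.
    missingness_base : float
        Day-1 missingness probability of the mood item for a person of
        average severity.
    adherence_decay : float
        Per-day increase in missingness log-odds (>= 0).
    missingness_severity_link : float
        Increase in missingness log-odds per SD of latent severity.
    wearable_signal : bool
        If False, wearable streams are pure noise (no severity loading).
    mood_signal_until : int or None
        If set, mood reflects severity only on days <= this value; later
        days are generated at mood_effect 0 (used for plateau experiments).
    """

    n_participants: int = 2459
    horizon_days: int = 92
    mood_baseline: float = 7.0
    mood_person_sd: float = 0.8
    mood_daily_sd: float = 1.2
    mood_effect: float = 1.0
    mood_volatility_effect: float = 0.2
    missingness_base: float = 0.25
    wearable_missingness_base: float = 0.35
    adherence_decay: float = 0.02
    missingness_severity_link: float = 0.3
    depression_prevalence_target: float = 0.185
    si_prevalence_target: float = 0.068
    depression_severity_effect: float = 1.2
    si_severity_effect: float = 1.4
    wearable_signal: bool = True
    mood_signal_until: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be a positive integer")
        if self.horizon_days < 1:
            raise ConfigurationError("horizon_days must be >= 1")
        for name in (
            "mood_baseline", "mood_person_sd", "mood_daily_sd", "mood_effect",
            "mood_volatility_effect", "missingness_base",
            "wearable_missingness_base", "adherence_decay",
            "missingness_severity_link", "depression_prevalence_target",
            "si_prevalence_target", "depression_severity_effect",
            "si_severity_effect",
        ):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigurationError(f"{name} must be finite, got {v!r}")
        for name in ("missingness_base", "wearable_missingness_base"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        if self.adherence_decay < 0:
            raise ConfigurationError("adherence_decay must be >= 0")
        for name in ("depression_prevalence_target", "si_prevalence_target"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(
                    f"{name} must be strictly inside (0, 1), got {v!r}"
                )
        if self.mood_signal_until is not None and self.mood_signal_until < 0:
            raise ConfigurationError("mood_signal_until must be >= 0 or None")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class DailyObservation:
    """One participant-day: mood (1-10 integer or None) and ten wearables."""

    day: int
    mood: Optional[int]
    wearable: dict[str, Optional[float]]


@dataclass(frozen=True)
class ParticipantRecord:
    """One person's full observation stream plus end-of-quarter labels."""

    participant_id: str
    observations: tuple[DailyObservation, ...]
    depression: int
    si: int
    latent_severity: float  # truth channel, never a predictor


class CohortDataset:
    """A cohort stored as two tidy tables.

    ``daily``: one row per participant-day with columns participant_id, day,
    mood and the ten wearable variables (NaN = missing). ``outcomes``: one
    row per participant with depression, si and latent_severity.
    """

    def __init__(self, daily: pd.DataFrame, outcomes: pd.DataFrame, horizon_days: int):
        self.daily = daily.reset_index(drop=True)
        self.outcomes = outcomes.reset_index(drop=True)
        self.horizon_days = int(horizon_days)
        self._validate()

    def _validate(self) -> None:
        required = ["participant_id", "day"] + list(DAILY_VARIABLES)
        for col in required:
            if col not in self.daily.columns:
                raise CohortParseError(f"daily table missing column {col!r}")
        for col in ("participant_id", "depression", "si"):
            if col not in self.outcomes.columns:
                raise CohortParseError(f"outcome table missing column {col!r}")
        ids = self.outcomes["participant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CohortParseError(f"duplicate participant id {dup!r} in outcomes")
        days = self.daily["day"]
        if ((days < 1) | (days > self.horizon_days)).any():
            bad = self.daily.loc[(days < 1) | (days > self.horizon_days)].iloc[0]
            raise CohortParseError(
                f"day {bad['day']!r} out of range 1..{self.horizon_days} "
                f"for participant {bad['participant_id']!r}"
            )
        counts = self.daily.groupby("participant_id", sort=False)["day"].agg(
            ["size", "nunique"]
        )
        wrong = counts[(counts["size"] != self.horizon_days)
                       | (counts["nunique"] != self.horizon_days)]
        if len(wrong):
            raise CohortParseError(
                f"participant {wrong.index[0]!r} does not have exactly one row "
                f"per day 1..{self.horizon_days}"
            )
        if set(ids) != set(self.daily["participant_id"].unique()):
            raise CohortParseError("participant ids differ between daily and outcomes")

    @property
    def n_participants(self) -> int:
        return len(self.outcomes)

    @property
    def participant_ids(self) -> pd.Series:
        return self.outcomes["participant_id"]

    def labels(self, outcome: str) -> np.ndarray:
        """Binary labels for 'depression' or 'si', ordered as participant_ids."""
        if outcome not in ("depression", "si"):
            raise ValueError(f"unknown outcome {outcome!r}")
        return self.outcomes[outcome].to_numpy(dtype=int)

    @property
    def records(self) -> Iterator[ParticipantRecord]:
        """Iterate the cohort as per-person record objects (test/debug view)."""
        out = self.outcomes.set_index("participant_id")
        for pid, grp in self.daily.groupby("participant_id", sort=False):
            grp = grp.sort_values("day")
            obs = tuple(
                DailyObservation(
                    day=int(r.day),
                    mood=None if pd.isna(r.mood) else int(r.mood),
                    wearable={
                        n: (None if pd.isna(getattr(r, n)) else float(getattr(r, n)))
                        for n in WEARABLE_NAMES
                    },
                )
                for r in grp.itertuples(index=False)
            )
            row = out.loc[pid]
            yield ParticipantRecord(
                participant_id=str(pid),
                observations=obs,
                depression=int(row["depression"]),
                si=int(row["si"]),
                latent_severity=float(row.get("latent_severity", float("nan"))),
            )

    def subset(self, participant_ids: Sequence[str]) -> "CohortDataset":
        keep = set(participant_ids)
        return CohortDataset(
            self.daily[self.daily["participant_id"].isin(keep)],
            self.outcomes[self.outcomes["participant_id"].isin(keep)],
            self.horizon_days,
        )


def calibrate_prevalence(
    target: float, severity_effect: float, tol: float = 1e-6
) -> float:
    """Intercept a such that E[expit(a + severity_effect * U)] = target, U ~ N(0,1).

    The expectation is evaluated by Gauss-Hermite quadrature; the intercept is
    found by bracketed root finding. Accurate to well under 1e-4 in prevalence.
    """
    if not 0.0 < target < 1.0:
        raise ConfigurationError(f"target prevalence must be in (0, 1), got {target!r}")
    if not math.isfinite(severity_effect):
        raise ConfigurationError("severity_effect must be finite")
    if severity_effect == 0.0:
        return float(logit(target))

    nodes, weights = np.polynomial.hermite.hermgauss(80)
    scale = math.sqrt(2.0) * severity_effect

    def prevalence(a: float) -> float:
        return float(weights @ expit(a + scale * nodes) / math.sqrt(math.pi))

    lo, hi = -60.0, 60.0
    if not prevalence(lo) < target < prevalence(hi):
        raise CalibrationError(
            f"target {target} not bracketed for severity_effect {severity_effect}"
        )
    try:
        a = brentq(lambda x: prevalence(x) - target, lo, hi, xtol=tol, maxiter=200)
    except RuntimeError as exc:  # pragma: no cover - brentq rarely fails in bracket
        raise CalibrationError(str(exc)) from exc
    return float(a)


def _participant_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"P{i:0{width}d}" for i in range(1, n + 1)])


def generate_cohort(config: SyntheticConfig) -> CohortDataset:
    """Draw a cohort; a pure function of the config (seed included).

    Generative model, per person i with latent severity u_i ~ N(0, 1):

    * mood(day) = round+clamp to [1,10] of
      baseline + person_sd*z_i - mood_effect*u_i + sd_i*eps(day),
      sd_i = mood_daily_sd * exp(mood_volatility_effect * u_i);
    * each variable-day is masked missing independently with probability
      expit(logit(base) + adherence_decay*(day-1) + severity_link*u_i);
    * wearables are person-mean + AR(1) daily deviations, with person means
      shifted by severity only when wearable_signal is on;
    * outcomes ~ Bernoulli(expit(a + b*u_i)) with a calibrated so the
      marginal prevalence hits the configured target.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, T = cfg.n_participants, cfg.horizon_days
    days = np.arange(1, T + 1)

    u = rng.standard_normal(n)
    person_intercept = cfg.mood_baseline + cfg.mood_person_sd * rng.standard_normal(n)

    # Daily mood: optionally drop the severity->mood link after a cutoff day.
    mood_sd = cfg.mood_daily_sd * np.exp(cfg.mood_volatility_effect * u)
    eps = rng.standard_normal((n, T))
    effect_on = np.ones(T)
    if cfg.mood_signal_until is not None:
        effect_on = (days <= cfg.mood_signal_until).astype(float)
    mood_latent = (
        person_intercept[:, None]
        - cfg.mood_effect * u[:, None] * effect_on[None, :]
        + mood_sd[:, None] * eps
    )
    mood = np.clip(np.rint(mood_latent), 1, 10)

    # Missingness propensity: shared person/day terms, separate base rates.
    day_term = cfg.adherence_decay * (days - 1)[None, :]
    sev_term = cfg.missingness_severity_link * u[:, None]

    def miss_prob(base: float) -> np.ndarray:
        if base == 0.0:
            return np.zeros((n, T))
        if base == 1.0:
            return np.ones((n, T))
        return expit(logit(base) + day_term + sev_term)

    mood_missing = rng.random((n, T)) < miss_prob(cfg.missingness_base)
    mood = np.where(mood_missing, np.nan, mood)

    p_wear = miss_prob(cfg.wearable_missingness_base)
    wearables: dict[str, np.ndarray] = {}
    for spec in WEARABLE_VARIABLES:
        mu = spec.mean + spec.between_sd * rng.standard_normal(n)
        if cfg.wearable_signal:
            mu = mu + spec.severity_loading * u
        # AR(1) deviations at stationary SD within_sd.
        innov = rng.standard_normal((n, T)) * spec.within_sd
        dev = np.empty((n, T))
        dev[:, 0] = innov[:, 0]
        root = math.sqrt(1.0 - _AR1_RHO**2)
        for t in range(1, T):
            dev[:, t] = _AR1_RHO * dev[:, t - 1] + root * innov[:, t]
        vals = np.clip(mu[:, None] + dev, spec.lo, spec.hi)
        missing = rng.random((n, T)) < p_wear
        wearables[spec.name] = np.where(missing, np.nan, vals)

    a_dep = calibrate_prevalence(
        cfg.depression_prevalence_target, cfg.depression_severity_effect
    )
    a_si = calibrate_prevalence(cfg.si_prevalence_target, cfg.si_severity_effect)
    depression = rng.binomial(1, expit(a_dep + cfg.depression_severity_effect * u))
    si = rng.binomial(1, expit(a_si + cfg.si_severity_effect * u))

    pids = _participant_ids(n)
    daily = pd.DataFrame(
        {
            "participant_id": np.repeat(pids, T),
            "day": np.tile(days, n),
            "mood": mood.ravel(),
        }
    )
    for name in WEARABLE_NAMES:
        daily[name] = wearables[name].ravel()
    outcomes = pd.DataFrame(
        {
            "participant_id": pids,
            "depression": depression,
            "si": si,
            "latent_severity": u,
        }
    )
    return CohortDataset(daily, outcomes, horizon_days=T)


_DAILY_FILE = "daily.csv"
_OUTCOMES_FILE = "outcomes.csv"


def write_cohort(cohort: CohortDataset, path: str | Path) -> None:
    """Write long-format daily.csv + outcomes.csv under directory ``path``.

    Missing values are written as empty fields.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    daily = cohort.daily.copy()
    # Mood is integer-valued when present; avoid '5.0' in the text format.
    daily["mood"] = daily["mood"].astype("Int64")
    daily.to_csv(path / _DAILY_FILE, index=False, float_format="%.6g")
    cohort.outcomes.to_csv(path / _OUTCOMES_FILE, index=False)


def read_cohort(path: str | Path) -> CohortDataset:
    """Read a cohort written by :func:`write_cohort`, validating its shape."""
    path = Path(path)
    daily_path, out_path = path / _DAILY_FILE, path / _OUTCOMES_FILE
    for p in (daily_path, out_path):
        if not p.exists():
            raise CohortParseError(f"expected cohort file {p} not found")
    daily = pd.read_csv(daily_path)
    outcomes = pd.read_csv(out_path)
    if "day" not in daily.columns or daily["day"].isna().any():
        bad = daily.index[daily["day"].isna()][0] if "day" in daily else "?"
        raise CohortParseError(f"malformed daily row {bad}: missing day value")
    mood = daily["mood"]
    frac = mood.dropna() % 1
    if (frac != 0).any():
        row = mood.dropna()[frac != 0].index[0]
        raise CohortParseError(f"malformed daily row {row}: non-integer mood")
    dup = daily.duplicated(subset=["participant_id", "day"])
    if dup.any():
        row = daily[dup].iloc[0]
        raise CohortParseError(
            f"duplicate participant-day key ({row['participant_id']!r}, {row['day']})"
        )
    horizon = int(daily["day"].max())
    return CohortDataset(daily, outcomes, horizon_days=horizon)
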