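"""Shared fixtures: small synthetic cohorts and hand-built cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from moodhorizon.cohort import (
    DAILY_VARIABLES,
    WEARABLE_NAMES,
    CohortDataset,
    SyntheticConfig,
    generate_cohort,
)


def cohort_from_mood(
    mood: np.ndarray,
    depression: np.ndarray,
    si: np.ndarray | None = None,
    wearables: str = "noise",
    seed: int = 0,
) -> CohortDataset:
    """Build a cohort from an explicit (n, T) mood matrix (NaN = missing).

    Wearable streams are filled with pure noise ('noise') or left entirely
    missing ('missing'); they carry no outcome information either way.
    """
    mood = np.asarray(mood, dtype=float)
    n, T = mood.shape
    rng = np.random.default_rng(seed)
    pids = [f"P{i:04d}" for i in range(1, n + 1)]
    daily = pd.DataFrame(
        {
            "participant_id": np.repeat(pids, T),
            "day": np.tile(np.arange(1, T + 1), n),
            "mood": mood.ravel(),
        }
    )
    for name in WEARABLE_NAMES:
        if wearables == "noise":
            daily[name] = rng.normal(100.0, 10.0, size=n * T)
        else:
            daily[name] = np.nan
    if si is None:
        si = np.zeros(n, dtype=int)
    outcomes = pd.DataFrame(
        {
            "participant_id": pids,
            "depression": np.asarray(depression, dtype=int),
            "si": np.asarray(si, dtype=int),
            "latent_severity": np.zeros(n),
        }
    )
    return CohortDataset(daily, outcomes, horizon_days=T)


@pytest.fixture(scope="session")
def small_cohort() -> CohortDataset:
    """120 participants x 14 days with signal; enough cases for 5 folds."""
    cfg = SyntheticConfig(
        n_participants=120,
        horizon_days=14,
        mood_effect=1.5,
        depression_prevalence_target=0.25,
        si_prevalence_target=0.20,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_cohort() -> CohortDataset:
    """8 participants x 6 days, for shape/feature tests only."""
    cfg = SyntheticConfig(
        n_participants=8,
        horizon_days=6,
        depression_prevalence_target=0.4,
        si_prevalence_target=0.4,
        seed=7,
    )
    return generate_cohort(cfg)
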