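"""Canonical evaluation scenarios for the synthetic generator.

Three named configurations exercise the pipeline's key behaviours and are
used by both the validation suite and the reproduction script:

* ``null``: every severity link switched off — daily data carry no outcome
  information, so out-of-sample AUC must hover at chance.
* ``strong_signal``: a large severity-to-mood effect with pure-noise
  wearables — mood summaries alone should predict well, and adding noise
  wearable features should not help.
* ``plateau``: the severity-to-mood link is expressed only through day 10
  of a 30-day window — the AUC curve should flatten shortly after, and the
  one-SE rule should detect convergence well before the final day.
"""

from __future__ import annotations

from .cohort import SyntheticConfig

__all__ = ["null_config", "strong_signal_config", "plateau_config",
           "PLATEAU_SIGNAL_DAYS"]

PLATEAU_SIGNAL_DAYS = 10


def null_config(seed: int, n_participants: int = 500) -> SyntheticConfig:
    """No-signal cohort: outcomes independent of every daily stream."""
    return SyntheticConfig(
        n_participants=n_participants,
        horizon_days=92,
        mood_effect=0.0,
        mood_volatility_effect=0.0,
        missingness_severity_link=0.0,
        depression_severity_effect=0.0,
        si_severity_effect=0.0,
        wearable_signal=False,
        seed=seed,
    )


def strong_signal_config(seed: int, n_participants: int = 800) -> SyntheticConfig:
    """Large mood signal, noise wearables: mood summaries should suffice."""
    return SyntheticConfig(
        n_participants=n_participants,
        horizon_days=92,
        mood_effect=2.0,
        mood_volatility_effect=0.3,
        depression_severity_effect=1.5,
        si_severity_effect=1.5,
        wearable_signal=False,
        seed=seed,
    )


def plateau_config(seed: int, n_participants: int = 500) -> SyntheticConfig:
    """Mood informative only through day 10 of a 30-day window."""
    return SyntheticConfig(
        n_participants=n_participants,
        horizon_days=30,
        mood_effect=2.0,
        mood_volatility_effect=0.3,
        depression_severity_effect=1.5,
        si_severity_effect=1.5,
        mood_signal_until=PLATEAU_SIGNAL_DAYS,
        wearable_signal=False,
        seed=seed,
    )
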