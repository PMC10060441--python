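"""Per-day AUC curves and convergence detection.

Sweeps days 1..horizon for each model configuration, producing a
PerformanceCurve of per-day nested-CV AUC estimates, then locates two
landmark days on each curve:

* the first day whose mean AUC lies within one standard error of the
  final day's mean AUC (the one-standard-error convergence rule), and
* the last day whose mean AUC falls below the acceptability threshold
  (0.70 by convention).

By default the one-SE band is the final day's SE around the final day's
mean; a candidate-day-SE variant and a sustained-crossing variant (the rule
must hold from that day onward) are available for sensitivity analyses,
since a single noisy day can satisfy the literal rule spuriously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .classifiers import MODEL_CONFIGS, ModelConfig
from .cohort import CohortDataset
from .crossval import (
    DEFAULT_INNER_K,
    DEFAULT_K,
    DEFAULT_REPEATS,
    DayPerformance,
    derive_seed,
    evaluate_day,
    make_fold_plan,
)

__all__ = [
    "PerformanceCurve",
    "ConvergenceSummary",
    "ACCEPTABLE_AUC",
    "run_temporal_sweep",
    "first_day_within_one_se",
    "last_day_below_threshold",
    "summarize_convergence",
]

ACCEPTABLE_AUC = 0.70


@dataclass
class PerformanceCurve:
    """Per-day performance points for one model configuration, day-ordered."""

    config: ModelConfig
    points: list[DayPerformance]

    def __post_init__(self) -> None:
        days = [p.day for p in self.points]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("curve days must be strictly increasing")
        if any(p.config != self.config for p in self.points):
            raise ValueError("all points must share the curve's config")

    @property
    def days(self) -> np.ndarray:
        return np.array([p.day for p in self.points])

    @property
    def mean_aucs(self) -> np.ndarray:
        return np.array([p.mean_auc for p in self.points])

    @property
    def se_aucs(self) -> np.ndarray:
        return np.array([p.se_auc for p in self.points])

    @property
    def final(self) -> DayPerformance:
        return self.points[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.days,
                "outcome": self.config.outcome,
                "algorithm": self.config.algorithm,
                "predictor_set": self.config.predictor_set,
                "mean_auc": self.mean_aucs,
                "se_auc": self.se_aucs,
                "n_estimates": [len(p.auc_estimates) for p in self.points],
            }
        )

    def tidy_estimates(self) -> pd.DataFrame:
        """One row per (day, outer estimate) for the per-fold results file."""
        rows = []
        for p in self.points:
            ids = p.fold_ids or [(i // p.n_folds, i % p.n_folds)
                                 for i in range(len(p.auc_estimates))]
            for (r, f), est in zip(ids, p.auc_estimates):
                rows.append(
                    {
                        "day": p.day,
                        "outcome": self.config.outcome,
                        "algorithm": self.config.algorithm,
                        "predictor_set": self.config.predictor_set,
                        "repeat": r,
                        "fold": f,
                        "auc": est,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ConvergenceSummary:
    """Landmark days for one curve (one row of the summary table)."""

    config: ModelConfig
    final_day: int
    final_day_mean_auc: float
    final_day_se_auc: float
    first_day_within_one_se: Optional[int]
    last_day_below_acceptable: Optional[int]
    acceptable_threshold: float = ACCEPTABLE_AUC


def run_temporal_sweep(
    cohort: CohortDataset,
    configs: Sequence[ModelConfig] = MODEL_CONFIGS,
    days: Optional[Sequence[int]] = None,
    master_seed: int = 0,
    k: int = DEFAULT_K,
    repeats: int = DEFAULT_REPEATS,
    inner_k: int = DEFAULT_INNER_K,
    shared_folds: bool = False,
    progress: Optional[Callable[[ModelConfig, int, DayPerformance], None]] = None,
    cache: Optional[dict] = None,
) -> list[PerformanceCurve]:
    """Evaluate every (config, day) cell and assemble per-config curves.

    Fold plans are regenerated per day from (master_seed, day) so each day
    is an independent analysis; ``shared_folds=True`` reuses one plan across
    days for lower curve-to-curve noise. ``cache`` maps
    (config.label, day) -> DayPerformance and is consulted and updated,
    making sweeps resumable.
    """
    if days is None:
        days = range(1, cohort.horizon_days + 1)
    days = sorted(set(int(d) for d in days))
    if not days:
        raise ValueError("empty day grid")
    if any(d < 1 or d > cohort.horizon_days for d in days):
        raise ValueError(f"days must lie in 1..{cohort.horizon_days}")

    shared_plans: dict[str, object] = {}
    curves = []
    for config in configs:
        points = []
        for day in days:
            key = (config.label, day)
            if cache is not None and key in cache:
                perf = cache[key]
            else:
                plan = None
                if shared_folds:
                    y = cohort.labels(config.outcome)
                    if config.outcome not in shared_plans:
                        shared_plans[config.outcome] = make_fold_plan(
                            y, k=k, repeats=repeats, inner_k=inner_k,
                            seed=derive_seed(master_seed, 0),
                        )
                    plan = shared_plans[config.outcome]
                perf = evaluate_day(
                    cohort, day, config, master_seed=master_seed,
                    k=k, repeats=repeats, inner_k=inner_k, plan=plan,
                )
                if cache is not None:
                    cache[key] = perf
            points.append(perf)
            if progress is not None:
                progress(config, day, perf)
        curves.append(PerformanceCurve(config=config, points=points))
    return curves


def first_day_within_one_se(
    curve: PerformanceCurve,
    band: str = "final",
    sustained: bool = False,
) -> Optional[int]:
    """First day whose mean AUC is within 1 SE of the final day's mean.

    ``band='final'`` (default) uses the final day's SE; ``band='candidate'``
    uses each candidate day's own SE. With ``sustained=True`` the rule must
    hold for the candidate day and every later evaluated day. Returns the
    final day itself if no earlier day qualifies, and None only for an
    empty curve.
    """
    if not curve.points:
        return None
    final = curve.final
    means = curve.mean_aucs
    if band == "final":
        ses = np.full_like(means, final.se_auc)
    elif band == "candidate":
        ses = curve.se_aucs
    else:
        raise ValueError("band must be 'final' or 'candidate'")
    ok = means >= final.mean_auc - ses
    if sustained:
        # Require the rule to hold from the candidate day through the end.
        ok = np.logical_and.accumulate(ok[::-1])[::-1]
    idx = np.flatnonzero(ok)
    return int(curve.days[idx[0]]) if len(idx) else int(final.day)


def last_day_below_threshold(
    curve: PerformanceCurve, threshold: float = ACCEPTABLE_AUC
) -> Optional[int]:
    """Largest day with mean AUC below ``threshold``; None if none exists."""
    below = np.flatnonzero(curve.mean_aucs < threshold)
    return int(curve.days[below[-1]]) if len(below) else None


def summarize_convergence(
    curve: PerformanceCurve,
    threshold: float = ACCEPTABLE_AUC,
    band: str = "final",
    sustained: bool = False,
) -> ConvergenceSummary:
    final = curve.final
    return ConvergenceSummary(
        config=curve.config,
        final_day=final.day,
        final_day_mean_auc=final.mean_auc,
        final_day_se_auc=final.se_auc,
        first_day_within_one_se=first_day_within_one_se(
            curve, band=band, sustained=sustained
        ),
        last_day_below_acceptable=last_day_below_threshold(curve, threshold),
        acceptable_threshold=threshold,
    )
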