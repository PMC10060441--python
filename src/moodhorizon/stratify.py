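"""Adherence-defined subgroup analyses.

Participants are grouped each day by their proportion of missing daily mood
responses over days 1..t, and the best-performing full-sample configuration
(elastic net with mood-only predictors, missingness feature included) is
re-evaluated within each subgroup. Because the rates are recalculated every
day, one participant can move between groups over the quarter.

Depression uses three groups on the missingness proportion — low [0, 1/3),
medium [1/3, 2/3], high (2/3, 1] — while suicidal ideation, whose lower
prevalence limits subgroup power, uses two: high (>= 1/2 missing) and low
(< 1/2). Boundaries are exact fractions and half-open by construction so
every rate lands in exactly one group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classifiers import ModelConfig
from .cohort import CohortDataset
from .crossval import (
    DEFAULT_INNER_K,
    DEFAULT_K,
    DEFAULT_REPEATS,
    DayPerformance,
    FoldPlanError,
    derive_seed,
    evaluate_day,
)
from .temporal import ACCEPTABLE_AUC, ConvergenceSummary, PerformanceCurve, summarize_convergence

__all__ = [
    "MissingnessGroupSpec",
    "assign_groups",
    "run_stratified_sweep",
    "StratifiedCurves",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MissingnessGroupSpec:
    """Group boundaries on the proportion of missing mood days.

    ``boundaries`` are the interior cut-points; group g holds rates m with
    boundaries[g-1] <= m (strict/inclusive per the labels below). The
    defaults implement: depression low [0, 1/3), medium [1/3, 2/3],
    high (2/3, 1]; SI low [0, 1/2), high [1/2, 1].
    """

    outcome: str
    labels: tuple[str, ...]
    boundaries: tuple[float, ...]

    @classmethod
    def for_outcome(cls, outcome: str) -> "MissingnessGroupSpec":
        if outcome == "depression":
            return cls(
                outcome="depression",
                labels=("low", "medium", "high"),
                boundaries=(1.0 / 3.0, 2.0 / 3.0),
            )
        if outcome == "si":
            return cls(outcome="si", labels=("low", "high"), boundaries=(0.5,))
        raise ValueError(f"unknown outcome {outcome!r}")

    def group_of(self, missing_rate: float) -> str:
        """Group label for one missingness proportion in [0, 1].

        Interior boundaries are inclusive on their left group's upper side
        for the 3-group scheme (medium = [1/3, 2/3]) and inclusive into the
        higher group for the 2-group scheme (exactly 1/2 -> high).
        """
        if not 0.0 <= missing_rate <= 1.0:
            raise ValueError(f"missing rate {missing_rate!r} outside [0, 1]")
        if len(self.labels) == 2:
            return self.labels[1] if missing_rate >= self.boundaries[0] else self.labels[0]
        lo, hi = self.boundaries
        if missing_rate < lo:
            return self.labels[0]
        if missing_rate <= hi:
            return self.labels[1]
        return self.labels[2]


def assign_groups(
    cohort: CohortDataset, t: int, spec: MissingnessGroupSpec
) -> pd.Series:
    """participant_id -> missingness group from mood missingness over days 1..t."""
    if not 1 <= t <= cohort.horizon_days:
        raise ValueError(f"t={t} outside 1..{cohort.horizon_days}")
    window = cohort.daily[cohort.daily["day"] <= t]
    observed = window.groupby("participant_id", sort=False)["mood"].count()
    observed = observed.reindex(cohort.participant_ids, fill_value=0)
    rate = 1.0 - observed / t
    groups = rate.map(spec.group_of)
    groups.name = "missingness_group"
    groups.index = pd.Index(cohort.participant_ids, name="participant_id")
    return groups


@dataclass
class StratifiedCurves:
    """Per-group performance curves for one outcome's missingness spec."""

    spec: MissingnessGroupSpec
    config: ModelConfig
    curves: dict[str, PerformanceCurve]
    skipped: list[tuple[str, int, str]] = field(default_factory=list)

    def convergence(self, threshold: float = ACCEPTABLE_AUC) -> list[tuple[str, ConvergenceSummary]]:
        return [
            (group, summarize_convergence(curve, threshold=threshold))
            for group, curve in self.curves.items()
        ]


def run_stratified_sweep(
    cohort: CohortDataset,
    spec: MissingnessGroupSpec,
    days: Sequence[int],
    master_seed: int = 0,
    config: Optional[ModelConfig] = None,
    k: int = DEFAULT_K,
    repeats: int = DEFAULT_REPEATS,
    inner_k: int = DEFAULT_INNER_K,
) -> StratifiedCurves:
    """Rerun the ENR mood-only model within each daily missingness group.

    Group membership is recomputed at every day t before evaluation, so the
    subsample itself changes along the curve. A day-group cell whose
    subsample cannot support the fold scheme (too few cases) is skipped with
    a logged warning and recorded in ``skipped``.
    """
    if config is None:
        config = ModelConfig(
            outcome=spec.outcome, algorithm="ENR", predictor_set="mood_only"
        )
    days = sorted(set(int(d) for d in days))
    points: dict[str, list[DayPerformance]] = {g: [] for g in spec.labels}
    skipped: list[tuple[str, int, str]] = []
    for day in days:
        groups = assign_groups(cohort, day, spec)
        for g in spec.labels:
            ids = groups.index[groups == g]
            if len(ids) == 0:
                skipped.append((g, day, "empty group"))
                continue
            sub = cohort.subset(ids)
            try:
                perf = evaluate_day(
                    sub, day, config,
                    master_seed=derive_seed(master_seed, g),
                    k=k, repeats=repeats, inner_k=inner_k,
                )
            except FoldPlanError as exc:
                logger.warning(
                    "skipping group %s at day %s: %s", g, day, exc
                )
                skipped.append((g, day, str(exc)))
                continue
            points[g].append(perf)
    curves = {
        g: PerformanceCurve(config=config, points=pts)
        for g, pts in points.items()
        if pts
    }
    return StratifiedCurves(spec=spec, config=config, curves=curves, skipped=skipped)
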