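"""Model / Results API tying the pipeline together.

``TemporalPrediction`` is built from a cohort (or from raw daily/outcome
tables) and a set of model configurations; ``fit`` runs the per-day nested
cross-validation sweep and returns ``TemporalPredictionResults`` carrying
the per-day AUC curves, their standard errors, the convergence landmarks
and a printable summary table. ``StratifiedTemporalPrediction`` is the
adherence-subgroup variant.

Example
-------
>>> from moodhorizon import SyntheticConfig, generate_cohort, TemporalPrediction
>>> cohort = generate_cohort(SyntheticConfig(n_participants=300, seed=7))
>>> model = TemporalPrediction(cohort, days=[7, 30, 92])
>>> res = model.fit(seed=7)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classifiers import MODEL_CONFIGS, ModelConfig
from .cohort import CohortDataset, SyntheticConfig, generate_cohort
from .crossval import DEFAULT_INNER_K, DEFAULT_K, DEFAULT_REPEATS
from .stratify import MissingnessGroupSpec, StratifiedCurves, run_stratified_sweep
from .temporal import (
    ACCEPTABLE_AUC,
    PerformanceCurve,
    run_temporal_sweep,
    summarize_convergence,
)

__all__ = [
    "TemporalPrediction",
    "TemporalPredictionResults",
    "StratifiedTemporalPrediction",
    "StratifiedTemporalPredictionResults",
]


class TemporalPrediction:
    """How-soon-can-we-predict analysis over a daily-observation cohort.

    Parameters
    ----------
    cohort : CohortDataset
        Daily mood/wearable streams plus end-of-quarter binary outcomes.
    configs : sequence of ModelConfig
        Which outcome x algorithm x predictor-set cells to run (default:
        the full 8-member space).
    days : sequence of int, optional
        The day grid to evaluate (default: every day 1..horizon).
    k, repeats, inner_k : int
        Outer folds, outer repeats and inner tuning folds of the nested CV.
    shared_folds : bool
        Reuse one outer fold plan across days instead of redrawing per day.
    one_se_band : {'final', 'candidate'}; sustained : bool
        Variants of the one-standard-error convergence rule.
    """

    def __init__(
        self,
        cohort: CohortDataset,
        configs: Sequence[ModelConfig] = MODEL_CONFIGS,
        days: Optional[Sequence[int]] = None,
        k: int = DEFAULT_K,
        repeats: int = DEFAULT_REPEATS,
        inner_k: int = DEFAULT_INNER_K,
        shared_folds: bool = False,
        one_se_band: str = "final",
        sustained: bool = False,
        acceptable_threshold: float = ACCEPTABLE_AUC,
    ):
        self.cohort = cohort
        self.configs = list(configs)
        self.days = (
            list(range(1, cohort.horizon_days + 1)) if days is None
            else sorted(set(int(d) for d in days))
        )
        self.k = k
        self.repeats = repeats
        self.inner_k = inner_k
        self.shared_folds = shared_folds
        self.one_se_band = one_se_band
        self.sustained = sustained
        self.acceptable_threshold = acceptable_threshold

    @classmethod
    def from_dataframes(
        cls,
        daily: pd.DataFrame,
        outcomes: pd.DataFrame,
        horizon_days: Optional[int] = None,
        **kwargs,
    ) -> "TemporalPrediction":
        horizon = int(daily["day"].max()) if horizon_days is None else horizon_days
        return cls(CohortDataset(daily, outcomes, horizon), **kwargs)

    @classmethod
    def from_synthetic(
        cls, config: Optional[SyntheticConfig] = None, **kwargs
    ) -> "TemporalPrediction":
        return cls(generate_cohort(config or SyntheticConfig()), **kwargs)

    def fit(
        self, seed: int = 0, progress=None, cache: Optional[dict] = None
    ) -> "TemporalPredictionResults":
        curves = run_temporal_sweep(
            self.cohort,
            configs=self.configs,
            days=self.days,
            master_seed=seed,
            k=self.k,
            repeats=self.repeats,
            inner_k=self.inner_k,
            shared_folds=self.shared_folds,
            progress=progress,
            cache=cache,
        )
        return TemporalPredictionResults(self, curves, seed)


class TemporalPredictionResults:
    """Per-day AUC curves and convergence landmarks from a fitted sweep."""

    def __init__(
        self,
        model: TemporalPrediction,
        curves: list[PerformanceCurve],
        seed: int,
    ):
        self.model = model
        self.curves = curves
        self.seed = seed

    def curve(self, config: ModelConfig) -> PerformanceCurve:
        for c in self.curves:
            if c.config == config:
                return c
        raise KeyError(f"no curve for {config}")

    def per_day_table(self) -> pd.DataFrame:
        """Tidy per-day summary: one row per (config, day)."""
        return pd.concat([c.to_frame() for c in self.curves], ignore_index=True)

    def tidy_estimates(self) -> pd.DataFrame:
        """One row per (config, day, outer repeat, outer fold) AUC estimate."""
        return pd.concat([c.tidy_estimates() for c in self.curves],
                         ignore_index=True)

    def convergence_table(self) -> pd.DataFrame:
        """Final-day AUC and landmark days per configuration."""
        rows = []
        for c in self.curves:
            s = summarize_convergence(
                c,
                threshold=self.model.acceptable_threshold,
                band=self.model.one_se_band,
                sustained=self.model.sustained,
            )
            rows.append(
                {
                    "outcome": c.config.outcome,
                    "algorithm": c.config.algorithm,
                    "predictor_set": c.config.predictor_set,
                    "final_day": s.final_day,
                    "final_day_mean_auc": s.final_day_mean_auc,
                    "final_day_se_auc": s.final_day_se_auc,
                    "first_day_within_one_se": s.first_day_within_one_se,
                    "last_day_below_acceptable": s.last_day_below_acceptable,
                    "acceptable_threshold": s.acceptable_threshold,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Printable convergence summary, one row per model configuration."""
        tab = self.convergence_table()
        lines = [
            "Temporal prediction of end-of-quarter outcomes",
            "=" * 78,
            f"participants: {self.model.cohort.n_participants}"
            f"   days evaluated: {len(self.model.days)}"
            f" (final day {max(self.model.days)})",
            f"outer CV: {self.model.repeats} x {self.model.k}-fold"
            f"   inner CV: {self.model.inner_k}-fold   seed: {self.seed}",
            f"acceptable AUC threshold: {self.model.acceptable_threshold:.2f}"
            f"   one-SE band: {self.model.one_se_band}"
            + ("   (sustained)" if self.model.sustained else ""),
            "-" * 78,
            f"{'outcome':<11}{'algo':<5}{'predictors':<20}"
            f"{'AUC(final)':>11}{'SE':>7}{'1-SE day':>9}{'<thr day':>9}",
            "-" * 78,
        ]
        for _, r in tab.iterrows():
            one_se = "-" if pd.isna(r.first_day_within_one_se) else int(r.first_day_within_one_se)
            below = "N/A" if pd.isna(r.last_day_below_acceptable) else int(r.last_day_below_acceptable)
            lines.append(
                f"{r.outcome:<11}{r.algorithm:<5}{r.predictor_set:<20}"
                f"{r.final_day_mean_auc:>11.3f}{r.final_day_se_auc:>7.3f}"
                f"{one_se:>9}{below:>9}"
            )
        lines.append("=" * 78)
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        from .plotting import plot_curves

        return plot_curves(self.curves, ax=ax, **kwargs)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<TemporalPredictionResults: {len(self.curves)} configs, "
            f"{len(self.model.days)} days, seed={self.seed}>"
        )


class StratifiedTemporalPrediction:
    """Missingness-subgroup rerun of the best full-sample configuration."""

    def __init__(
        self,
        cohort: CohortDataset,
        outcome: str = "depression",
        spec: Optional[MissingnessGroupSpec] = None,
        days: Optional[Sequence[int]] = None,
        k: int = DEFAULT_K,
        repeats: int = DEFAULT_REPEATS,
        inner_k: int = DEFAULT_INNER_K,
        acceptable_threshold: float = ACCEPTABLE_AUC,
    ):
        self.cohort = cohort
        self.spec = spec or MissingnessGroupSpec.for_outcome(outcome)
        self.days = (
            list(range(1, cohort.horizon_days + 1)) if days is None
            else sorted(set(int(d) for d in days))
        )
        self.k = k
        self.repeats = repeats
        self.inner_k = inner_k
        self.acceptable_threshold = acceptable_threshold

    def fit(self, seed: int = 0) -> "StratifiedTemporalPredictionResults":
        strat = run_stratified_sweep(
            self.cohort,
            self.spec,
            days=self.days,
            master_seed=seed,
            k=self.k,
            repeats=self.repeats,
            inner_k=self.inner_k,
        )
        return StratifiedTemporalPredictionResults(self, strat, seed)


class StratifiedTemporalPredictionResults:
    def __init__(
        self,
        model: StratifiedTemporalPrediction,
        stratified: StratifiedCurves,
        seed: int,
    ):
        self.model = model
        self.stratified = stratified
        self.seed = seed

    @property
    def curves(self) -> dict[str, PerformanceCurve]:
        return self.stratified.curves

    def per_day_table(self) -> pd.DataFrame:
        frames = []
        for group, curve in self.stratified.curves.items():
            f = curve.to_frame()
            f.insert(1, "missingness_group", group)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def convergence_table(self) -> pd.DataFrame:
        rows = []
        for group, s in self.stratified.convergence(
            threshold=self.model.acceptable_threshold
        ):
            rows.append(
                {
                    "outcome": s.config.outcome,
                    "missingness_group": group,
                    # Completion-rate alias to keep the two conventions straight.
                    "completion_group": {"low": "high", "medium": "medium",
                                         "high": "low"}[group],
                    "final_day": s.final_day,
                    "final_day_mean_auc": s.final_day_mean_auc,
                    "final_day_se_auc": s.final_day_se_auc,
                    "first_day_within_one_se": s.first_day_within_one_se,
                    "last_day_below_acceptable": s.last_day_below_acceptable,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        tab = self.convergence_table()
        lines = [
            f"Missingness-stratified sweep ({self.stratified.config.label})",
            "-" * 78,
            f"{'group (missingness)':<22}{'AUC(final)':>11}{'SE':>7}"
            f"{'1-SE day':>9}{'<thr day':>9}",
            "-" * 78,
        ]
        for _, r in tab.iterrows():
            below = "N/A" if pd.isna(r.last_day_below_acceptable) else int(r.last_day_below_acceptable)
            lines.append(
                f"{r.missingness_group:<22}{r.final_day_mean_auc:>11.3f}"
                f"{r.final_day_se_auc:>7.3f}{int(r.first_day_within_one_se):>9}"
                f"{below:>9}"
            )
        if self.stratified.skipped:
            lines.append(f"skipped day-group cells: {len(self.stratified.skipped)}")
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        from .plotting import plot_curves

        labeled = [
            (f"{g} missingness", c) for g, c in self.stratified.curves.items()
        ]
        from .plotting import plot_labeled_curves

        return plot_labeled_curves(labeled, ax=ax, **kwargs)
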