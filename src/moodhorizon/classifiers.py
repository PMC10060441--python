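"""Classifiers and hyperparameter grids.

Two algorithms are compared: elastic-net-penalized logistic regression (ENR)
and a 100-tree random forest (RF). Each is tuned over a 3 x 3 grid of
conventional 3-level defaults: ENR penalty log-spaced over [1e-10, 1] with
L1 proportion (mixture) in {0, 0.5, 1}; RF variables-per-split (mtry)
spread over [1, n_predictors] with minimum node size in {2, 21, 40}.

The ENR objective is the glmnet convention: mean negative log-likelihood plus
penalty * [mixture * ||b||_1 + (1 - mixture)/2 * ||b||_2^2], fitted on
features standardized with training statistics; probabilities are returned on
the original feature scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ModelConfig",
    "MODEL_CONFIGS",
    "EnrHyperparams",
    "RfHyperparams",
    "FittedClassifier",
    "SingleClassError",
    "grid_candidates",
    "fit_enr",
    "fit_rf",
    "fit_classifier",
]

OUTCOMES = ("depression", "si")
ALGORITHMS = ("ENR", "RF")


class SingleClassError(ValueError):
    """Training labels contain a single class; the fold must be skipped."""


@dataclass(frozen=True, order=True)
class ModelConfig:
    """One outcome x algorithm x predictor-set combination."""

    outcome: str
    algorithm: str
    predictor_set: str

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.predictor_set not in ("mood_only", "mood_plus_wearable"):
            raise ValueError("predictor_set must be mood_only or mood_plus_wearable")

    @property
    def label(self) -> str:
        return f"{self.outcome}:{self.algorithm}:{self.predictor_set}"


#: The full 8-member configuration space (2 outcomes x 2 algorithms x 2 sets).
MODEL_CONFIGS: tuple[ModelConfig, ...] = tuple(
    ModelConfig(outcome=o, algorithm=a, predictor_set=p)
    for o in OUTCOMES
    for a in ALGORITHMS
    for p in ("mood_only", "mood_plus_wearable")
)


@dataclass(frozen=True)
class EnrHyperparams:
    penalty: float  # overall regularization magnitude (> 0)
    mixture: float  # L1 proportion in [0, 1]

    def __post_init__(self) -> None:
        if not self.penalty > 0:
            raise ValueError("penalty must be > 0")
        if not 0.0 <= self.mixture <= 1.0:
            raise ValueError("mixture must be in [0, 1]")

    def regularization_rank(self) -> tuple:
        # Ties in tuning break toward larger penalty, then larger mixture.
        return (-self.penalty, -self.mixture)


@dataclass(frozen=True)
class RfHyperparams:
    mtry: int  # variables tried per split
    min_node: int  # minimum observations for a node to split further
    n_trees: int = 100

    def __post_init__(self) -> None:
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_node < 2:
            raise ValueError("min_node must be >= 2")

    def regularization_rank(self) -> tuple:
        # Ties break toward larger min_node, then smaller mtry.
        return (-self.min_node, self.mtry)


Hyperparams = Union[EnrHyperparams, RfHyperparams]


def grid_candidates(algorithm: str, n_predictors: int) -> list[Hyperparams]:
    """The 3 x 3 = 9 hyperparameter settings searched for one algorithm."""
    if n_predictors < 1:
        raise ValueError("n_predictors must be >= 1")
    if algorithm == "ENR":
        penalties = np.logspace(-10, 0, 3)  # 1e-10, 1e-5, 1
        mixtures = (0.0, 0.5, 1.0)
        return [
            EnrHyperparams(penalty=float(p), mixture=m)
            for p in penalties
            for m in mixtures
        ]
    if algorithm == "RF":
        mtry_values = np.unique(
            np.rint(np.linspace(1, n_predictors, 3)).astype(int)
        )
        # Keep 3 levels even when the range collapses (n_predictors <= 3).
        while len(mtry_values) < 3 and len(mtry_values) < n_predictors:
            mtry_values = np.arange(1, n_predictors + 1)[:3]
        min_nodes = (2, 21, 40)
        return [
            RfHyperparams(mtry=int(m), min_node=n)
            for m in mtry_values
            for n in min_nodes
        ]
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class FittedClassifier:
    """A fitted model plus the feature scaling needed to score new rows."""

    algorithm: str
    estimator: object
    scale_mean: np.ndarray | None = None
    scale_sd: np.ndarray | None = None

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probabilities for a fully imputed feature matrix."""
        X = np.asarray(X, dtype=float)
        if self.scale_mean is not None:
            X = (X - self.scale_mean) / self.scale_sd
        proba = self.estimator.predict_proba(X)
        idx = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
        return proba[:, idx]


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassError("training labels contain a single class")
    return y


def fit_enr(
    X: np.ndarray,
    y: np.ndarray,
    hp: EnrHyperparams,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> FittedClassifier:
    """Elastic-net logistic regression on standardized features.

    The glmnet-style (mean-loss) penalty maps onto scikit-learn's summed-loss
    objective via C = 1 / (n * penalty). The intercept is unpenalized, so in
    the total-shrinkage limit the predicted probability collapses to the
    training class-1 proportion.

    At the near-zero-penalty grid corner the saga solver may stop at the
    iteration cap short of full convergence; the residual gradient there is
    immaterial for probability ranking, so the cap is treated as a normal
    stop rather than surfaced as a warning (raise ``max_iter`` for exact
    coefficient work).
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    if np.isnan(X).any():
        raise ValueError("ENR requires a fully imputed feature matrix")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    Xs = (X - mu) / sd

    C = 1.0 / (len(y) * hp.penalty)
    if hp.mixture == 0.0:
        est = LogisticRegression(
            C=C, solver="lbfgs", max_iter=max_iter, tol=tol
        )
    else:
        est = LogisticRegression(
            l1_ratio=hp.mixture,
            C=C,
            solver="saga",
            max_iter=max_iter,
            tol=tol,
            random_state=seed,
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        est.fit(Xs, y)
    # The intercept is unpenalized, so its exact optimum given the fitted
    # coefficients is a 1-d logistic MLE. saga's step size collapses at very
    # strong penalties and can leave the intercept short of that optimum;
    # a few Newton steps restore it (rank-preserving, so AUC is unaffected).
    eta_x = Xs @ est.coef_.ravel()
    b0 = float(est.intercept_[0])
    ybar_target = y.astype(float)
    for _ in range(50):
        p = expit(b0 + eta_x)
        grad = float(np.mean(p - ybar_target))
        hess = float(np.mean(p * (1.0 - p)))
        if hess <= 0 or abs(grad) < 1e-12:
            break
        b0 -= grad / hess
    est.intercept_ = np.array([b0])
    return FittedClassifier("ENR", est, scale_mean=mu, scale_sd=sd)


def fit_rf(
    X: np.ndarray, y: np.ndarray, hp: RfHyperparams, seed: int = 0
) -> FittedClassifier:
    """100-tree Gini random forest; probability = mean per-tree leaf proportion."""
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    if np.isnan(X).any():
        raise ValueError("RF requires a fully imputed feature matrix")
    mtry = min(hp.mtry, X.shape[1])
    est = RandomForestClassifier(
        n_estimators=hp.n_trees,
        criterion="gini",
        max_features=mtry,
        min_samples_split=hp.min_node,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    est.fit(X, y)
    return FittedClassifier("RF", est)


def fit_classifier(
    X: np.ndarray, y: np.ndarray, hp: Hyperparams, seed: int = 0
) -> FittedClassifier:
    if isinstance(hp, EnrHyperparams):
        return fit_enr(X, y, hp, seed=seed)
    if isinstance(hp, RfHyperparams):
        return fit_rf(X, y, hp, seed=seed)
    raise TypeError(f"unknown hyperparameter type {type(hp)!r}")
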