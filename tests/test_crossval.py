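"""Nested CV: fold plans, the AUC statistic, inner tuning, leakage."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from moodhorizon.classifiers import (
    EnrHyperparams,
    ModelConfig,
    RfHyperparams,
    grid_candidates,
)
from moodhorizon.cohort import CohortDataset
from moodhorizon.crossval import (
    DayPerformance,
    FoldPlanError,
    UndefinedAUCError,
    auc,
    evaluate_day,
    inner_tune,
    make_fold_plan,
)
from moodhorizon.features import build_feature_matrix

from conftest import cohort_from_mood


def brute_force_auc(scores, labels):
    """Exhaustive case-control pair counting; ties count one half."""
    cases = [s for s, l in zip(scores, labels) if l == 1]
    controls = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for c, d in itertools.product(cases, controls):
        total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestAuc:
    def test_perfect_ranking(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.4] * 6, [1, 0, 1, 0, 0, 1]) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedAUCError):
            auc([0.1, 0.2], [1, 1])

    @settings(deadline=None, derandomize=True, max_examples=80)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=9),
                st.integers(min_value=0, max_value=1),
            ),
            min_size=2,
            max_size=25,
        ).filter(lambda rows: len({l for _, l in rows}) == 2)
    )
    def test_matches_pair_counting_and_sklearn(self, rows):
        scores = [s / 10.0 for s, _ in rows]  # coarse grid to force ties
        labels = [l for _, l in rows]
        got = auc(scores, labels)
        assert got == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestFoldPlan:
    def test_perfect_stratification(self):
        y = np.array([1] * 20 + [0] * 80)
        plan = make_fold_plan(y, seed=1)
        for r in range(plan.repeats):
            for tr, te in plan.outer[r]:
                assert len(te) == 20
                assert y[te].sum() == 4

    def test_partition_law_and_determinism(self):
        y = np.array([1] * 13 + [0] * 64)
        plan = make_fold_plan(y, seed=5)
        plan2 = make_fold_plan(y, seed=5)
        for r in range(plan.repeats):
            tests = [set(te) for _, te in plan.outer[r]]
            assert set().union(*tests) == set(range(len(y)))
            for a, b in itertools.combinations(tests, 2):
                assert not (a & b)
        for r in range(plan.repeats):
            for f in range(plan.k):
                np.testing.assert_array_equal(
                    plan.outer[r][f][1], plan2.outer[r][f][1]
                )

    def test_inner_folds_exclude_outer_test(self):
        y = np.array([1] * 15 + [0] * 60)
        plan = make_fold_plan(y, seed=2)
        for (r, f), splits in plan.inner.items():
            outer_test = set(plan.outer[r][f][1])
            for tr, va in splits:
                assert not (set(tr) | set(va)) & outer_test

    def test_too_few_cases_rejected(self):
        y = np.array([1] * 3 + [0] * 60)
        with pytest.raises(FoldPlanError, match="each class"):
            make_fold_plan(y, k=5)


def _tune_setup(n=90, informative=True, seed=0):
    """Raw features + labels + inner splits for tuning tests."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    if informative:
        y = (rng.random(n) < 1 / (1 + np.exp(-2.5 * x))).astype(int)
    else:
        y = rng.integers(0, 2, n)
    features = pd.DataFrame(
        {"f0": x, "f1": rng.standard_normal(n), "f2": rng.standard_normal(n)}
    )
    plan = make_fold_plan(y, k=5, repeats=1, inner_k=3, seed=seed)
    return features, y, plan.inner[(0, 0)]


class TestInnerTune:
    def test_singleton_grid_returned(self):
        features, y, splits = _tune_setup()
        only = EnrHyperparams(penalty=0.3, mixture=0.5)
        assert inner_tune(features, y, "ENR", [only], splits) is only

    def test_exact_tie_prefers_stronger_regularization(self):
        # Constant features force identical (all-ties, AUC 0.5) predictions
        # for every grid setting, so selection is decided by the tie-break.
        features, y, splits = _tune_setup()
        const = features * 0.0
        best = inner_tune(const, y, "ENR", grid_candidates("ENR", 3), splits)
        assert best == EnrHyperparams(penalty=1.0, mixture=1.0)
        best_rf = inner_tune(const, y, "RF", grid_candidates("RF", 3), splits)
        assert best_rf.min_node == 40
        assert best_rf.mtry == 1

    def test_strong_signal_beats_overshrinking(self):
        # A huge penalty zeroes the only informative feature; the small
        # penalty must win despite the tie-break preferring the large one.
        features, y, splits = _tune_setup(informative=True)
        grid = [
            EnrHyperparams(penalty=1e6, mixture=1.0),
            EnrHyperparams(penalty=1e-4, mixture=1.0),
        ]
        best = inner_tune(features, y, "ENR", grid, splits)
        assert best.penalty == 1e-4

    def test_exhaustive_grid_evaluation_oracle(self):
        """Selection matches independently re-running every grid cell."""
        from moodhorizon.crossval import derive_seed
        from moodhorizon.features import apply_imputation, fit_imputation
        from moodhorizon.classifiers import fit_classifier

        features, y, splits = _tune_setup(seed=4)
        grid = grid_candidates("ENR", 3)
        best = inner_tune(features, y, "ENR", grid, splits, seed=9)

        ordered = sorted(grid, key=lambda hp: hp.regularization_rank())
        scores = []
        for j, hp in enumerate(ordered):
            fold_aucs = []
            for i, (tr, va) in enumerate(splits):
                imp = fit_imputation(features.iloc[tr])
                X_tr = apply_imputation(imp, features.iloc[tr]).to_numpy(float)
                X_va = apply_imputation(imp, features.iloc[va]).to_numpy(float)
                clf = fit_classifier(X_tr, y[tr], hp,
                                     seed=derive_seed(9, j, i))
                fold_aucs.append(auc(clf.predict_proba1(X_va), y[va]))
            scores.append(np.mean(fold_aucs))
        assert best == ordered[int(np.argmax(scores))]


@pytest.fixture(scope="module")
def perf(small_cohort):
    config = ModelConfig("depression", "ENR", "mood_only")
    return evaluate_day(small_cohort, 10, config, master_seed=3)


class TestEvaluateDay:

    def test_fifteen_estimates(self, perf):
        assert len(perf.auc_estimates) == 15
        assert perf.n_dropped == 0
        assert all(0.0 <= a <= 1.0 for a in perf.auc_estimates)

    def test_se_uses_conservative_sqrt_k(self, perf):
        ests = np.array(perf.auc_estimates)
        assert perf.mean_auc == pytest.approx(ests.mean(), abs=1e-12)
        assert perf.se_auc == pytest.approx(
            ests.std(ddof=1) / math.sqrt(5), abs=1e-12
        )
        assert perf.se_auc != pytest.approx(
            ests.std(ddof=1) / math.sqrt(15), abs=1e-6
        )

    def test_constant_estimates_zero_se(self):
        config = ModelConfig("depression", "ENR", "mood_only")
        dp = DayPerformance(day=1, config=config,
                            auc_estimates=[0.7] * 15, n_folds=5)
        assert dp.mean_auc == pytest.approx(0.7)
        assert dp.se_auc == pytest.approx(0.0, abs=1e-15)

    def test_deterministic(self, small_cohort, perf):
        config = ModelConfig("depression", "ENR", "mood_only")
        again = evaluate_day(small_cohort, 10, config, master_seed=3)
        assert again.auc_estimates == perf.auc_estimates
        assert again.chosen_hyperparams == perf.chosen_hyperparams


class TestLeakage:
    def test_outer_test_perturbation_changes_nothing_trained(self, small_cohort):
        """Imputation medians and tuned hyperparameters for a split depend
        only on its training participants."""
        day = 8
        config = ModelConfig("depression", "ENR", "mood_only")
        base = evaluate_day(small_cohort, day, config, master_seed=11)

        from moodhorizon.crossval import make_fold_plan, derive_seed

        y = small_cohort.labels(config.outcome)
        plan = make_fold_plan(y, seed=derive_seed(11, day))
        test_ids = set(
            small_cohort.participant_ids.iloc[plan.outer[0][0][1]]
        )
        daily = small_cohort.daily.copy()
        mask = daily["participant_id"].isin(test_ids) & (daily["day"] <= day)
        daily.loc[mask, "mood"] = 10.0  # aggressive perturbation
        perturbed_cohort = CohortDataset(
            daily, small_cohort.outcomes, small_cohort.horizon_days
        )
        perturbed = evaluate_day(perturbed_cohort, day, config, master_seed=11)

        # Split (repeat 0, fold 0): perturbed participants are test-only.
        idx = base.fold_ids.index((0, 0))
        assert base.chosen_hyperparams[idx] == perturbed.chosen_hyperparams[idx]
        pd.testing.assert_series_equal(
            base.imputation_medians[idx], perturbed.imputation_medians[idx]
        )

    def test_no_participant_in_both_train_and_test(self, small_cohort):
        y = small_cohort.labels("depression")
        plan = make_fold_plan(y, seed=0)
        for r in range(plan.repeats):
            for tr, te in plan.outer[r]:
                assert not set(tr) & set(te)
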