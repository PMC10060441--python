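# Methods

## The analysis

The package answers a design question for intensive longitudinal studies:
given a daily mood diary and daily wearable summaries collected over a
92-day quarter, how early does a classifier trained on the data available
through day *t* approximate the predictive accuracy of the full-quarter
model for binary end-of-quarter outcomes (depression, suicidal ideation)?

For each day *t* the feature set summarizes each daily variable over days
1..*t* with three statistics: mean, sample SD (n−1 denominator) and percent
missing (100 · missing days / *t*). With the mood item and ten wearable
variables this gives 33 features in the full set, 3 in the mood-only set.
The mean requires at least two observed values and the SD at least three;
below the minimum the statistic is carried as an explicit not-a-value
sentinel until imputation. Percent missing is always defined and is itself
a predictor — adherence carries signal.

Missing summary statistics are imputed with the median of that statistic in
the *training* rows of whichever split is being fitted: the outer-training
set for outer evaluation and the inner-training subset during tuning. A
feature with no observed training value at all (possible at *t* = 1, where
no mean or SD exists for anyone) falls back to a fixed constant — 0 for SD
features, the variable-range midpoint for means — with a logged warning.
At such days the classifiers effectively see only the percent-missing
features, which is the honest information content of a one-day window.

Two algorithms are compared across two predictor sets and two outcomes
(8 configurations). Elastic-net logistic regression minimizes the mean
negative log-likelihood plus `penalty · [mixture·‖β‖₁ +
(1−mixture)/2·‖β‖₂²]` on features standardized with training statistics
(the glmnet parameterization; implemented via scikit-learn with
C = 1/(n·penalty)). The random forest uses 100 Gini-split trees with
bootstrap resampling; probabilities are mean per-tree leaf proportions.
Hyperparameters come from 3 × 3 grids: ENR penalty ∈ {1e-10, 1e-5, 1}
(3 log-uniform levels over [1e-10, 1]) × mixture ∈ {0, 0.5, 1}; RF mtry =
3 evenly spaced integers over [1, p] × minimum node size ∈ {2, 21, 40}.
Grids are overridable per call for experiments.

Performance is estimated by nested cross-validation. The outer loop is
repeated stratified 5-fold CV with 3 repeats: for each of the 15 splits,
stratified 3-fold CV *within the outer-training set* scores all 9 grid
cells by mean inner-fold AUC (fold-averaged, not pooled), the winning cell
is refitted on the full outer-training set, and the outer-test fold is
scored. AUC is the Mann–Whitney statistic (ties count one half). The
per-day summary is the mean of the 15 estimates with standard error =
sample SD / √5 — the conservative √k denominator rather than √(repeats·k),
because the 15 estimates reuse overlapping training data and are not
independent. Exact tuning ties resolve toward the stronger regularization
(larger penalty then larger mixture; larger minimum node then smaller
mtry), so selection is deterministic.

Two landmark days are read off each per-day curve:

* **one-SE convergence day** — the first day whose mean AUC is at least
  (final-day mean − final-day SE). This is the literal band-around-the-
  final-day reading; because a single noisy day can cross the band
  spuriously, a *sustained* variant (the rule must hold from the candidate
  day through the end of the grid) and a *candidate-day-SE* variant are
  available behind flags, and both landmarks can be recomputed from the
  saved curves without rerunning any model.
* **last day below acceptability** — the largest day with mean AUC < 0.70;
  absent when the curve never dips below the threshold.

Adherence subgroup analyses regroup participants *every day* by their
proportion of missing mood responses over days 1..*t* and rerun the ENR
mood-only configuration within each group. Depression uses three groups on
the missingness proportion — low [0, 1/3), medium [1/3, 2/3],
high (2/3, 1] — and suicidal ideation, whose low prevalence limits
subgroup power, uses two (high ≥ 1/2, low < 1/2). Boundaries are exact
fractions with half-open intervals so each rate lands in exactly one
group; outputs carry completion-rate aliases alongside the missingness
labels because the two conventions are easy to confuse. The
percent-missing feature remains in the predictor set within groups: the
grouping is coarse, so within-group adherence variation stays informative.

## Design choices made where the design was open

* **Fold plans are redrawn per day** from (master seed, day): each day is
  treated as an independent analysis. A shared-folds flag reuses one plan
  across days for smoother curves at the cost of correlated noise.
* **Stratified folds** (by outcome) are used throughout; at a ~7 % outcome
  prevalence unstratified 5-folds are frequently single-class, which would
  leave the fold AUC undefined. Test folds that still end up single-class
  are dropped with a warning and the day's estimate count is recorded.
* **Sample SD** (n−1) is used for both features and the per-day SE.
* **Every randomized step is seeded** from a (master seed, day, config,
  repeat, fold) lineage via a counter-based seed sequence, so the full
  sweep is bit-reproducible and any cell can be recomputed in isolation.
* **ENR intercept polish.** The saga solver's step size collapses at the
  strongest grid penalty, which can leave the (unpenalized) intercept
  short of its optimum; after each fit a few Newton steps solve the 1-d
  intercept MLE exactly. The polish is rank-preserving, so AUCs are
  unaffected; probability calibration in the total-shrinkage limit is.

## The synthetic cohort generator

There is no public cohort with this structure, so the generator produces
one with the features the analysis relies on. Per person *i*, a latent
severity u_i ~ N(0,1) drives everything:

* **Mood** (integers 1–10): round-and-clamp of baseline (7.0) + person
  intercept (SD 0.8) − mood_effect·u_i + daily Gaussian noise whose SD is
  mood_daily_sd·exp(volatility_effect·u_i) (defaults 1.2, 0.2) — severer
  people report lower and more variable mood.
* **Missingness**: each variable-day is masked independently with
  probability expit(logit(base) + 0.02·(day−1) + 0.3·u_i); mood and
  wearables share the person/day propensity terms but have separate base
  rates (0.25 and 0.35) — adherence decays over the quarter and is worse
  at higher severity.
* **Wearables**: person-level means (e.g. total sleep 420 ± 35 min,
  steps 8000 ± 2200, resting HR 62 ± 5 bpm) plus AR(1) daily deviations
  (lag-1 correlation 0.5), clipped to plausible ranges. Severity shifts
  the person means (shorter sleep, fewer steps, higher resting HR, …)
  only when the informative-wearables flag is on; otherwise the streams
  are pure noise.
* **Outcomes**: Bernoulli(expit(a + b·u_i)) with b = 1.2 (depression) and
  1.4 (SI) and intercepts calibrated by Gauss–Hermite quadrature + root
  finding so the marginal prevalence hits the targets (18.5 % and 6.8 %)
  to < 1e-4.

The generator emulates cross-sectional heterogeneity, adherence decay,
severity-linked drop-out and integer measurement. It does **not** emulate
within-quarter symptom trajectories (severity is static), weekly or
schedule-driven rhythms in the wearables, institution- or specialty-level
clustering, or item-level outcome measurement (labels are drawn directly).
Passing tests therefore demonstrate that the pipeline recovers structure
*of this kind* correctly — not that any particular real cohort would show
the same convergence days.

A `mood_signal_until` switch turns the severity→mood link off after a
cutoff day, creating curves whose information content plateaus by
construction; this is how one-SE detection is validated.

## Evaluation scenarios and problem sizes

`moodhorizon/scenarios.py` fixes three canonical configurations used by
the validation suite and the reproduction script: a no-signal cohort
(n = 500; grand mean AUC must sit in [0.45, 0.55] over seeds and days
{7, 30, 92}), a strong-signal cohort (n = 800, mood_effect 2.0, noise
wearables; day-92 AUC must exceed 0.65 and beat day-3 in ≥ 8/10 seeds,
and mood-only must sit within sampling error of mood+wearables — the
paired-difference criterion |mean diff| ≤ max(0.025, 2·SE) fixed before
any runs), and a plateau cohort (n = 500, 30-day window, signal through
day 10; the one-SE day must fall at or before day 15 in ≥ 8/10 seeds).
These sizes keep the full suite around ten minutes on one core while
leaving Monte-Carlo error well inside the asserted margins.

## Numerical notes and limitations

* AUC is computed from average ranks; it equals exhaustive case–control
  pair counting exactly, including ties.
* Percent missing is 100·k/t with integer k, exactly representable for
  the day counts involved.
* The ENR near-zero-penalty grid corner is effectively unpenalized
  maximum likelihood; saga may stop at the iteration cap there, which
  perturbs coefficients at a level immaterial for ranking.
* The one-SE rule, as defined, compares each day to the final evaluated
  day; on a sparse day grid the "final" day is the last grid point, so
  landmark days are only meaningful relative to the grid actually run.
* Runtime scales linearly in days × configurations; a full 8-config,
  92-day sweep at n ≈ 2500 is an overnight job on one core. The CLI's
  per-day cache makes such sweeps resumable and extendable.
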