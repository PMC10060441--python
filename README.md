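# moodhorizon

How many days of daily data are enough to predict a quarter-end mental
health outcome?

Intensive longitudinal studies collect a daily mood diary (one 1–10 rating
per evening) and passive wearable streams (sleep, steps, activity minutes,
resting heart rate) for weeks to months, then ask whether a binary distal
outcome — depression (PHQ-9 ≥ 10) or suicidal ideation (any endorsement of
PHQ-9 item 9) at the end of a 92-day quarter — can be predicted early.
Longer collection raises participant burden and drop-out, so the practical
question is *when the predictive accuracy curve flattens*.

`moodhorizon` implements that analysis as a reusable pipeline:

1. **Accumulating features.** For each day *t*, every daily variable
   *v* (mood + 10 wearable metrics) is summarized over days 1..*t* by its
   mean, sample SD and percent missing — 3 features per variable, 33 in the
   full set. Means require ≥ 2 observations and SDs ≥ 3; statistics that
   cannot be computed are imputed with the training-fold median inside the
   cross-validation loop, never globally.
2. **Classifiers.** Elastic-net logistic regression (ENR) with objective
   mean-NLL + λ·[α‖β‖₁ + (1−α)/2·‖β‖₂²] on standardized features, and a
   100-tree Gini random forest. Each is tuned over a 3 × 3 grid
   (ENR: penalty × mixture; RF: mtry × minimum node size).
3. **Nested cross-validation.** Inner stratified 3-fold tuning picks the
   grid cell with the greatest mean AUC; the outer loop is repeated
   stratified 5-fold CV (3 repeats), giving 15 out-of-sample AUC estimates
   per day. The per-day standard error uses the conservative denominator
   √k = √5 rather than √15.
4. **Convergence detection.** On each per-day AUC curve the package
   reports the first day whose mean AUC is within one standard error of
   the final day's mean (one-SE rule) and the last day below the
   acceptability threshold AUC = 0.70, for all 8 model configurations
   (2 outcomes × 2 algorithms × 2 predictor sets) and within adherence
   subgroups defined by daily-recomputed mood missingness.
5. **Synthetic cohorts.** A seeded generator produces cohorts with the
   statistical structure the analysis assumes — latent severity driving
   mood level/volatility, adherence decaying over time and with severity,
   calibrated outcome prevalences (18.5 % depression, 6.8 % SI) — so the
   entire pipeline is testable without access to any real cohort.

## Worked example

```python
from moodhorizon import (SyntheticConfig, generate_cohort,
                         ModelConfig, TemporalPrediction)

cohort = generate_cohort(SyntheticConfig(
    n_participants=300, mood_effect=2.0, wearable_signal=False, seed=7))
model = TemporalPrediction(
    cohort,
    configs=[ModelConfig("depression", "ENR", "mood_only")],
    days=[3, 7, 14, 30, 60, 92])
res = model.fit(seed=7)
print(res.summary())
```

```
Temporal prediction of end-of-quarter outcomes
==============================================================================
participants: 300   days evaluated: 6 (final day 92)
outer CV: 3 x 5-fold   inner CV: 3-fold   seed: 7
acceptable AUC threshold: 0.70   one-SE band: final
------------------------------------------------------------------------------
outcome    algo predictors           AUC(final)     SE 1-SE day <thr day
------------------------------------------------------------------------------
depression ENR  mood_only                 0.757  0.042        3      N/A
==============================================================================
```

Read: with 300 synthetic participants and a strong mood signal, the
mood-only elastic net reaches a final-day AUC of 0.757 (SE 0.042); its
accuracy is already within one SE of that value on day 3, the earliest
evaluated day, and no evaluated day falls below the 0.70 acceptability
threshold (N/A). `res.per_day_table()` gives the full curve and
`res.plot()` draws it with ±1 SE ribbons.

The same analysis is available from the shell:

```bash
moodhorizon simulate --out cohort/ --n 300 --seed 7
moodhorizon sweep --cohort cohort/ --out results/ --days 1-92:7 \
    --stratify depression --seed 7
moodhorizon report --results results/ --plot
```

Sweeps cache per-day results and can be resumed with an extended day grid;
a cache produced under a different seed or fold scheme is refused.

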