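# hfsense

Smartphone-based passive and active sensing for predicting heart-failure (HF)
decompensation. The package turns raw phone streams — 5-Hz tri-axial
accelerometer samples, call logs, location fixes, and weekly KCCQ-12
questionnaires — into per-event feature windows and classifies upcoming
clinical encounters as *decompensated* (volume-overloaded, the positive
class) versus *compensated*, using logistic regression under
leave-one-subject-out cross-validation with early/late multimodal fusion,
Shapley feature attribution, and prediction-horizon analyses. A synthetic
cohort generator with plantable pre-event effects makes every stage testable
end to end without access to clinical data.

It is aimed at digital-phenotyping and mHealth researchers who want a
reproducible reference implementation of this class of pipeline, and a
harness for method experiments (fusion strategies, window/lead choices,
feature attribution) on controllable synthetic cohorts.

## The model

For each clinical event at day *e*, an *N*-day window `[e − lead − N, e − lead)`
of data yields a feature vector with four blocks:

- **motion** (6): mean, SD, mode, skewness, kurtosis, and completeness of 30-s
  activity counts, where a count is the sum over an epoch of per-second maxima
  of the band-pass-filtered (Butterworth, 0.25–11 Hz, zero-phase) z-axis
  acceleration;
- **social** (5): numCalls, durCalls, durCalls_std, durNoCalls,
  durNoCalls_std from the call log;
- **location** (4): atHome, distToHome (summed Haversine km to the inferred
  home), zone1/zone2 counts inside/outside a 2-km home radius;
- **kccq** (1 or 4): the KCCQ-12 summary (mean of available domains, 0–100,
  lower = worse) or the four domain scores, as window mean or most recent
  survey.

Classification is L2 logistic regression (z-scored features) with
leave-one-subject-out folds, majority undersampling of each training fold,
and sequential forward selection of 3 features per modality. *Early fusion*
concatenates selected blocks; *late fusion* stacks per-modality
probabilities into a second-level logistic model (first-level training
probabilities come from an inner, rebalanced LOSO, so the stacker sees only
honest out-of-fold inputs). Analyses are repeated over 50 seeds; metrics
(accuracy, AUC, AUCPr, PPV, TPR, specificity) are reported as mean (SD).
Shapley values for the early-fusion model are exact on the log-odds scale.

## Worked example

```python
import hfsense as h
import hfsense.windows as W

cohort = h.generate_cohort(h.CohortConfig(seed=1))          # 28 participants, ~110 events
table = W.assemble_dataset(cohort, W.build_windows(cohort.events, 14, 0))
rows, _ = W.filter_complete_cases(table, ("kccq", "motion", "social"))

late = h.repeat_experiment(rows, h.ModelConfig(fusion="late", n_repeats=10))
print({k: round(v, 3) for k, v in late.mean.items()})
```

prints

```
{'accuracy': 0.867, 'AUC': 0.942, 'AUCPr': 0.878, 'PPV': 0.829, 'TPR': 0.852, 'specificity': 0.878}
```

i.e. on this planted-effect cohort (25-point KCCQ drop, 0.6× call rate,
1.6× call duration, 1.3× motion amplitude in the 14 days before each
decompensation) the late-fusion model separates decompensated from
compensated windows with mean AUC 0.94 across 10 seeded leave-one-subject-out
repeats, at 83% precision and 85% sensitivity for the default 0.5 threshold.
With neutral effect sizes (`h.EffectSizes.neutral()`) the same pipeline stays
at chance (AUC ≈ 0.5), and the Shapley ranking of the early-fusion model
reports the planted call-behaviour signature — higher total call duration
pushing toward decompensation, higher call counts away from it:

```python
import hfsense.explain as E
_, ranking, _ = E.explain_early_fusion(table, seed=0)
print(ranking.head(5).to_string(index=False))
```

The command line mirrors the library:

```bash
hfsense simulate --seed 1 --out runs/cohort
hfsense featurize --cohort-dir runs/cohort --out runs/features.csv
hfsense train --features runs/features.csv --out runs/metrics.csv
hfsense run --config config.yaml --seed 1 --out runs/full   # all stages
```

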