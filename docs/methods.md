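# Methods

`hfsense` implements a smartphone-sensing pipeline for predicting heart-failure
(HF) decompensation from four data modalities — passive motion, social contact
and mobility streams plus the actively reported KCCQ-12 questionnaire — and a
synthetic cohort generator that stands in for a private clinical cohort. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic validation does and does not establish.

## Feature extraction

**Motion.** Raw tri-axial accelerometer samples (nominal 5 Hz, units of g) are
reduced to 30-s *activity counts*: the z channel is filtered with a zero-phase
4th-order Butterworth band-pass (0.25–11 Hz), the per-second maxima of the
absolute filtered signal are summed over each 30-s epoch. At a 5-Hz sampling
rate the 11-Hz upper corner exceeds Nyquist (2.5 Hz), so whenever the upper
corner reaches 0.9 × Nyquist the filter degenerates to a high-pass at the lower
corner — the achievable part of the design (gravity and drift rejection) — and
a warning is emitted. The absolute value before the per-second max prevents
sign cancellation of the oscillatory filtered signal. Per analysis window the
features are the mean, SD, mode, skewness and excess kurtosis of the present
epoch counts plus the completeness fraction (`act_comp`). The mode is taken on
integer-rounded counts with ties to the smallest value; skewness/kurtosis use
the population (biased) convention and are defined as 0 for a constant series.
A window with less than 0.1% of its epochs present is treated as a missing
motion modality. Epochs are aligned to participant-local midnight.

**Social.** Five call-log features per window: call count, summed and SD of
call durations, and summed and SD of call-free gaps. Gaps are edge-inclusive
(window start → first call, inter-call gaps floored at 0 for call-waiting
overlaps, last call end → window end). A call belongs to the window iff it
*starts* inside it; durations are not truncated at the boundary. SDs are
sample (n−1) SDs, 0 when fewer than two elements. With non-overlapping
in-window calls, call time plus call-free time reconstructs the window length
exactly — a conservation identity the tests assert.

**Location.** Fixes are snapped to a 3-decimal-degree grid (~111 m of
latitude, matching the app's ~100 m update granularity); home is the centroid
of the most frequently occupied cell over the participant's full history, ties
to the earliest-occupied cell. Features: fixes in the home cell (`atHome`),
summed Haversine distance to home (IUGG radius 6371.0088 km), and fix counts
within/beyond a 2-km radius (`zone1`/`zone2`; home-cell fixes necessarily also
count in zone 1).

**KCCQ-12.** The four domain scores (0–100, lower = worse) are the input unit;
the summary score is the mean of available domains (≤ 25 ≈ NYHA IV). Per
window, either the summary (`KCCQ12_sum`) or the four domains (`KCCQ12_all`)
are aggregated as the mean of in-window surveys or the most recent in-window
survey. "Most recent" does not look back past the window start (a config
choice; the alternative is ambiguous and not implemented).

## Windows and labels

Each clinical event (compensated = 0, decompensated = 1) defines one N-day
window ending `lead_days` whole days before the event's local midnight
(default N = 14, lead 0, so the window abuts the event day and never includes
it). Windows extending before enrollment are truncated, not dropped, with the
completeness feature reflecting the shortfall; overlapping windows from
closely spaced events are kept. Fused analyses keep complete cases only (all
requested modality blocks present).

## Classification

L2-regularized logistic regression (C = 1, intercept unpenalized) on features
z-scored on the training fold. Cross-validation is leave-one-subject-out:
participants, not events, define folds, since one participant contributes
several events. Per fold the training rows are majority-undersampled to exact
class balance, then sequential forward selection (SFS) picks up to 3 features
per modality by pooled out-of-fold AUC under an inner 5-fold participant-
grouped CV (ties to feature order). Early fusion concatenates the selected
blocks into one model; late fusion feeds per-modality probabilities to a
second-level logistic model. Every analysis is repeated 50 times with
consecutive seeds (seeding the undersampling), and metrics are reported as
mean (SD): accuracy, rank-statistic AUC, AUCPr (average precision), PPV, TPR
and specificity at a 0.5 probability threshold.

The logistic fit itself is a damped Newton solver for the standard objective;
it matches `sklearn.linear_model.LogisticRegression(C=1)` to ~1e-4 in the
coefficients (asserted in the tests) but avoids per-call overhead, which
matters because the LOSO × SFS × 50-repeat design performs on the order of a
million fits on ~100-row tables.

**Late-fusion stacking.** The second-level training inputs are first-level
probabilities obtained by an inner LOSO *within* the training fold, so the
stacker never sees resubstitution probabilities. Each inner training set is
re-undersampled to exact balance: leaving one participant out of a balanced
set leaves a residual imbalance opposite to that participant's class mix, and
unbalanced first-level fits encode it as a base-rate shift that
anti-correlates with the held-out labels — without the rebalancing the
stacker learns inverted weights and null-data AUC drops systematically below
chance (~0.39 in our measurements, vs ~0.46 with it).

**Horizon analyses.** Time-to-event mode fixes N = 1 and sweeps the lead;
window-size mode sweeps N at a fixed lead. Only participants contributing a
complete-case row at every setting are retained, so the settings are compared
on a common subcohort. `lead_days` means the whole-day gap between window end
and the event's midnight.

## Attribution

Shapley values for the early-fusion model are computed exactly on the
log-odds scale, where additivity is exact for a linear decision function:
phi_j = w_j (x_j − mean_j(background)), with the undersampled training set as
background. A model-agnostic permutation sampler (with per-feature standard
errors) covers the general case and is validated against the closed form. The
summary ranking orders features by mean |phi| and reports the sign of the
Spearman correlation between feature value and contribution. The explanation
model is fit on *all* features of the chosen modalities rather than the SFS
subset, so the ranking covers the complete measured feature set.

## Synthetic cohort

The generator emulates the study conditions: 28 participants observed for 120
days, accruing ~110 clinical events (Poisson, mean 110/28 per participant) of
which ~44% are decompensated. Streams:

- **Motion** — circadian half-sine amplitude envelope between 08:00 and 22:00
  (zero activity at night, sensor noise floor 0.01 g) multiplying white noise,
  plus a 1 g gravity offset on z; participant amplitude 0.3 g × lognormal(0.15).
- **Calls** — homogeneous Poisson arrivals (4/day × lognormal(0.3) per
  participant), lognormal durations (median 120 s, sigma 0.9), a 15-contact
  pool with rank-weighted dialing probabilities.
- **Location** — home-anchored latent minute-level trajectory with Poisson(2)
  daily out-and-back excursions (exponential distances, mean 3 km, 30 km/h),
  ~13 m GPS jitter, subsampled by the app rule: a fix is emitted only after
  ≥ 100 m displacement *and* ≥ 5 min since the last emitted fix.
- **KCCQ-12** — weekly surveys (participant-specific weekday), participant
  baseline N(70, 8) clipped, per-domain offsets, survey noise SD 6, 5%
  missing domains, 10% skipped surveys.
- **Missingness** — contiguous blocks of epochs (geometric lengths, mean 2 h,
  emulating battery-death gaps) are dropped until ~10% of epochs are absent.

Pre-event effects apply over the 14 days before each decompensated event:
KCCQ drop 25 points, call rate × 0.6, call duration × 1.6, motion amplitude
× 1.3, excursion radius × 0.7. `effect_shape` selects a step change (default)
or a linear ramp peaking the day before the event; the ramp is used for the
horizon analyses, where a time-profile is the object of study. The true
pre-event dynamics of real patients are unknown — this is an explicit
modelling choice, not an estimate.

At cohort scale the motion stream is synthesized directly at the epoch level:
the per-second max of |N(0,1)| over k samples has CDF (2Φ(m)−1)^k, which is
sampled exactly by inverse transform and scaled by the same envelope. This
reproduces the count statistics of the raw 5-Hz path (filtering white noise
with a 0.25-Hz high-pass is nearly identity) at ~20× less cost; the raw path
(`motion_mode="raw"`) remains available and the two modes are compared in the
tests. Problem sizes throughout (120 study days, 50 repeats, 1-day horizon
windows over leads 1–6) are the package's default study conditions.

## What the synthetic validation shows — and does not

Passing tests establish that the pipeline is leakage-free, calibrated at
chance on null data, able to recover planted multimodality effects of
realistic size, and correct in its arithmetic (count conversion, metric
identities, Shapley axioms) — on data whose generative structure is known and
stationary. They do not establish clinical performance: real cohorts have
non-stationary behaviour, correlated missingness, label noise from chart
review, and between-participant heterogeneity far richer than lognormal
scaling of baselines. Reported metrics on synthetic cohorts characterize the
*method*, not the *population*.

## Known limitations

- The null-calibration band is tight relative to cohort-level sampling noise:
  a single 110-event cohort's LOSO AUC has an SE of ~0.05, so individual null
  cohorts can land near the band edges by chance.
- With ~4 events per participant, LOSO metrics are sensitive to which
  participants carry decompensations; the 50-repeat SD only captures
  resampling noise, not cohort noise.
- SFS with k = 3 on 4–6 candidates is close to exhaustive; its value is
  structural fidelity, not dimensionality reduction.
- The location generator emits no fixes during long stationary periods (the
  app rule never triggers), so `atHome` counts returns home rather than time
  at home — matching the app's semantics, not residence time.
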