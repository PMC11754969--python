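# Methods

`hrvstress` models a laboratory stress-reactivity study in psychiatric
populations: three diagnostic groups (major depressive disorder, panic
disorder, healthy controls) attend repeated visits, and at each visit ECG
beat intervals (RRIs) are recorded in five consecutive 5-minute phases —
rest, mental-arithmetic stress, rest, nature-scene relaxation, rest. The
package covers the full analysis chain from RRI series to group-level
claims: feature extraction, normalization, subject-wise cross-validated
classification of stress vs relaxation, Shapley attribution, and
delta-HRV statistics. Raw clinical recordings are not distributed, so a
first-class synthetic cohort generator reproduces the statistical
structure the analysis assumes.

## The RRI simulator

Beat intervals follow a two-oscillator model,

    RR(t) = base + A_LF sin(2π f_LF t + φ_LF) + A_HF sin(2π f_HF t + φ_HF) + ε,

laid down beat-by-beat (`t_{k+1} = t_k + RR(t_k)`), stopping at the first
beat whose cumulative time exceeds the phase duration. The model is the
simplest generator whose parameters map one-to-one onto the analysed
features: `f_LF ≈ 0.095 Hz` and `f_HF ≈ 0.25 Hz` place power in the LF and
HF bands, the white noise ε (SD `noise_sd_ms`) drives the entropies, and
`base` sets mean RRI. Per participant, a latent state is drawn once and
reused across visits: baseline interval (group offset + N(0, `subject_sd`)),
independent LF and HF amplitude factors (between-person sympathovagal
balance), a reactivity multiplier, and small oscillator-frequency jitter.
Per visit, a single additive drift offset N(0, `visit_drift_sd`) is shared
by all five phases — the operationalization of "daily states" that
motivates personalized scaling.

The stress phase perturbs the participant's parameters by group-specific
signed fractions: base interval down (`rri_frac`), HF amplitude down
(vagal withdrawal, `hf_frac`), LF amplitude up (`lf_frac`). Defaults give
healthy controls roughly twice the patients' reactivity
(HC −0.08/−0.35/+0.30 vs patients −0.04/−0.18/+0.15) and patients lower
overall HRV (amplitude scale 0.7) and shorter baseline intervals —
the directions reported for this population. Relaxation and rest phases
share the unperturbed parameters.

Cohort geometry defaults to the study's: 41/47/59 participants
(MDD/PD/HC), 5 visits × 5 phases × 300 s. Missingness drops whole visits:
visit 1 is always kept and later visits are retained with probability
0.8554, chosen so the expected number of retained sessions is ≈650 of the
735 scheduled (147 + 588·0.8554 ≈ 650). `subsample_sessions` instead
enforces an exact per-group pattern (e.g. 181/191/278 sessions) when exact
bookkeeping is needed. All randomness flows from a single integer seed;
identical configurations are bit-reproducible.

What the generator does *not* emulate: respiratory coupling and
respiratory-frequency drift, circadian structure beyond the visit offset,
ectopy/arrhythmia (artifacts must be injected explicitly to exercise the
correction rule), and any relationship between clinical severity and HRV
beyond the fixed group offsets. Tests passing on this cohort therefore
demonstrate that the *pipeline machinery* behaves as designed under the
assumed statistical structure — not that the classifier would reach any
particular accuracy on real recordings.

## The 20-feature battery

Each phase's (artifact-corrected) RRI series yields, in canonical order:

* **Time domain (6)** — mean RRI (s); SDNN (ms); RMSSD (ms); pNN50 (% of
  successive differences > 50 ms); TRI (count / modal bin height of the
  RRI histogram, bin width 1/128 s); TINN (ms, baseline width of the
  least-squares triangular fit to that histogram, exhaustive search of the
  two corner positions on the bin grid).
* **Frequency domain (7)** — the tachogram is cubic-spline resampled at
  4 Hz over cumulative beat time, mean-removed, and analysed with a Welch
  periodogram (Hann windows of 150 s, 50% overlap — three segments on a
  300-s phase, trading estimator variance against VLF resolution; a series
  shorter than one window falls back to a single segment with a warning).
  Band powers are trapezoidal PSD integrals over VLF [0, 0.04), LF
  [0.04, 0.15), HF [0.15, 0.4) Hz, reported as natural logs of power in
  s²; LFnu = 100·LF/(LF+HF), HFnu = 100 − LFnu, plus the LF/HF ratio.
* **Nonlinear (7, five method families)** — ApEn (Pincus definition,
  self-matches included) and SampEn (Richman–Moorman, self-matches
  excluded) with m = 2 and tolerance r = 0.2 × sample SD of the analysed
  segment (the Kubios convention for the reference scale); DFA exponents
  α1 and α2 as least-squares slopes of log F(n) vs log n over every integer
  box size in [4, 16] and [17, 64] (integrated mean-centred series,
  non-overlapping boxes, order-1 detrend, tail beats discarded);
  Grassberger–Procaccia correlation dimension (delay embedding m = 10,
  delay 1, Euclidean distances, log-spaced radius grid anchored at the 5th
  percentile of pairwise distances, slope over the middle third of radii
  with 0 < C(r) < 1); Poincaré SD1/SD2.

Conventions, stated once and applied everywhere: sample SD (ddof = 1);
SD1 = RMSSD/√2 and SD2 = √(2·SDNN² − SD1²), the algebra under which the
two classical Poincaré identities hold exactly rather than asymptotically;
degenerate zero-variance series give entropies 0, CorDim 0, TRI 1 and
NaN-flagged spectral powers; a SampEn with no template matches is reported
as NaN (never silently substituted) and such rows are dropped listwise,
with a warning, before modelling.

Artifact correction replaces beats deviating from an 11-beat running
median by more than 25% (of the median) with piecewise cubic-spline
interpolation over beat index; a series with more than 30% flagged beats
is rejected as unusable. This automated rule stands in for the manual
visual editing used on the original recordings.

## Normalization regimes

Two mutually exclusive regimes:

* **train-zscore** — per-feature mean/SD estimated on the training fold
  only and applied to the test fold; constant features pass through as 0
  with a warning.
* **personalized longitudinal scaling** — each participant's features are
  z-scored against that participant's own mean/SD across *all* of their
  rows: all five phases of all visits, before any train/test split.
  Participants with fewer than two rows are dropped (zero-filling would
  fabricate a class-informative constant). This deliberately uses each
  participant's full record, including sessions that later land in test
  folds — it is a within-person re-referencing, reproduced here as
  designed rather than "fixed"; users should note it when interpreting
  absolute accuracies.

A t-SNE embedding (perplexity 50, 5000 iterations by default) with the
mean task-label silhouette serves as a qualitative QA check that
longitudinal scaling improves task separability when day-to-day drift
dominates.

## Classification protocol

Rows are (participant, visit, task) feature vectors; stress is the
positive class. Cross-validation is subject-wise: participants (never
rows) are dealt into k = 10 folds, shuffled within diagnostic group and
assigned cyclically so fold sizes and group proportions are balanced to
±1 participant; task balance per fold is automatic because each session
contributes one stress and one relaxation row. The plan is repeated 20
times (fresh fold seed per repeat); metrics (accuracy, F1, recall,
precision, AUC of the stress-probability) are averaged over folds within
repeat — overall and on each group's test subset — and reported as
mean ± SD over repeats. A runtime guard asserts empty train∩test
participant intersections in every fold.

Hyperparameters are tuned inside each training fold by grid search with a
subject-wise 5-fold inner CV (accuracy; ties go to the simpler model):
random forest over tree counts {50, 100, 200} (otherwise library
defaults: Gini, √p features per split, unlimited depth), and an MLP over
architectures {(4, 8, 16), (4, 8, 16, 32)} × initial learning rates
{1e-4, 1e-3, 1e-2} — six combinations — with ReLU hidden layers, logistic
output, Adam, L2 1e-4, ≤1000 iterations, early stopping when the
validation score improves < 1e-4 for 10 consecutive iterations. The
early-stopping validation split is scikit-learn's internal random 10% of
the training rows (the library offers no subject-wise hook); it lives
entirely inside the training fold, so the outer evaluation stays
leak-free. The random-forest grid uses a warm-start fast path (one forest
grown 50→100→200 per inner fold), verified to reproduce the independent
fits tree-for-tree.

Optional experiments mirror the study design: random undersampling to the
smallest group's sample size (sampling whole sessions so task pairs stay
intact) and per-group models trained and tested on one group exclusively.

## Shapley attribution

Feature importance uses exact path-dependent tree Shapley values of the
forest's positive-class probability, computed on test folds only. The
recursion maintains, along each root-to-leaf path, the weighted proportion
of feature subsets of each size that would route the sample to that leaf,
marginalising absent features with the training weights stored in the tree
nodes; it satisfies local accuracy (base value + Σ attributions = model
output) to machine precision and matches an exhaustive 2^p-subset oracle
on small trees. |Attribution| is averaged within repeat and then across
repeats; features are ranked descending (ties keep canonical order), per
scope (combined / MDD / PD / HC) and scaling regime. Signed means are also
emitted; ranking uses the absolute values. MLP attribution is out of
scope.

## Delta-HRV statistics

ΔHRV = stress − relaxation within one participant-visit, computed after
any scaling (never by scaling deltas). Visits missing either task are
skipped with a logged count; visits are pooled as independent records, the
same simplification the study's session-level sample counts imply. Group
comparison per feature: Brown–Forsythe (median-centred Levene) at
α = 0.05 gates between Fisher's ANOVA + Bonferroni-adjusted pairwise
t-tests (p_adj = min(1, 3·p)) and Welch's ANOVA + Games-Howell. η² is
reported from the Fisher sums-of-squares decomposition in both routes;
pairwise effect sizes are pooled-SD Cohen's d. A direction label (e.g.
"HC > MDD; HC > PD") is assigned only where the omnibus test and the
pairwise post-hoc are significant, ordering groups by |mean Δ| (reactivity
magnitude, since Δ is signed). No multiple-testing correction is applied
across the 20 features, matching the reporting convention the tables
follow. Paired stress-vs-relaxation contrasts use two-sided paired
t-tests; zero-variance differences are flagged degenerate rather than
tested.

## Problem sizes used in the test suite

The automated tests exercise the protocol at reduced scale, chosen as the
smallest cohorts at which the studied effects are stable across generator
seeds: the drift-dominated scenario (regime comparison and per-group
ordering) uses 6/6/6 participants × 2 visits × 5 × 300-s phases with
repeats reduced to 5, and the planted-signal attribution scenario uses
6/6/6 × 2 visits with k = 5 and 2 repeats. Under those conditions
personalized longitudinal scaling lifts overall accuracy by ≈0.25 over
train-zscore and the healthy-control group ranks above both patient
groups in per-group accuracy in the large majority of seeds — the
qualitative pattern the full-scale design reports. Oracle-equivalence
checks run on ≤300-point series at 1e-9 tolerance; DFA sanity bands use
n = 10 000 points.

## Known limitations

* The simulator's sinusoidal oscillators give narrow-band spectra;
  absolute band powers and entropies are not calibrated to human values,
  only their orderings and effect directions are meaningful.
* TINN's exhaustive corner search is O(bins²) and its value on short or
  flat histograms is convention-dependent (0 for a single occupied bin).
* Correlation-dimension estimates depend on the embedding and radius-grid
  conventions (documented above; configurable), which the HRV literature
  does not standardise.
* Longitudinal scaling's use of future sessions means its accuracies are
  not estimates of prospective deployment performance.
* Welch's periodogram is the only spectral estimator (no AR/Lomb–Scargle),
  and PSD detrending is mean removal only.
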