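# Methods

This note documents the models, estimators and design choices behind
improcoord: what each statistic assumes, what the synthetic generator does
and does not emulate, and where genuinely open design questions were
settled. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A performance is T seconds of aligned 1 Hz series. Musical actions are
binary (playing/silent); directional intentions are continuous in [0, 1]
with 0.5 the slider's neutral midpoint. Intention sliders emit
timestamped on-change events; resampling to 1 Hz is sample-and-hold (the
value at second t is the last event at or before 1000·t ms, and the
neutral 0.5 before any event), because a physical slider holds its
position between events. Time is 0-based integer seconds and sequence
intervals are half-open [start, end), so durations sum exactly to T.
Summary SDs use the sample (n−1) convention and are reported as undefined
for n = 1 rather than 0. Musicians whose action row is all zeros are
flagged and excluded from pairwise analysis — they carry no information
and would otherwise produce degenerate correlations.

## Pairwise interdependence (Granger causal density)

Each directed test regresses y_t on a constant, L own lags and L lags of
x, and compares against the restricted model without the x lags by the
standard F statistic, F = ((RSS_r − RSS_u)/L) / (RSS_u/(n − 2L − 1)).
The model order defaults to L = 16 s, the order selected on the original
orchestra dataset; `select_max_lag` reproduces the selection by scanning
candidate orders, averaging AIC and BIC over all ordered pairs, and
preferring the BIC minimizer when the two disagree (BIC's heavier penalty
favors parsimony; both curves are logged).

Assumption checking follows the usual Granger workflow: each series gets
an augmented Dickey–Fuller test at level 0.05, and when non-stationarity
is not rejected the least-squares linear trend is removed. Detrending
(not differencing) is used because the group-level drifts seen in this
kind of data are slow ramps, and differencing binary series would destroy
their meaning. Detrending is applied to the 1 Hz series, once per
musician, before all pairwise fits. Constant series raise a degenerate
error; in the all-pairs driver the pair is kept in the output with a
degenerate flag and excluded from group comparisons.

The per-direction "value of causality" is the binarized significance
indicator at α = 0.05, and causal density is the mean of the two
indicators, so a pair scores 0, ½ or 1. Under this definition a
time-scrambled pair's expected density is exactly α, which is why the
surrogate means land near 0.05; a continuous alternative (mean of the two
F statistics) is available via `AnalysisConfig.density_scale="fstat"`.

Caveat: action series are binary, and the F test's homoskedastic-Gaussian
assumptions hold only approximately. Calibration on white noise is exact
(the acceptance suite verifies the false-positive rate against the 95%
binomial CI of α at 2000 directed tests), while on persistent binary
series the test is very slightly anticonservative — roughly half a
percentage point at the pair level. This is documented rather than
corrected because the linear F test is the field-standard estimator for
these data.

## Surrogates

The default surrogate is a uniform random permutation of each series'
time indices, applied independently to both members of a pair: it
preserves each musician's value distribution exactly and destroys all
autocorrelation, which makes it the correct null for "any temporal
relationship whatsoever". The number of surrogates per pair defaults to
100 (seeded); `n_surrogates=1` reproduces a single-draw design.
Phase-randomized surrogates (spectrum-preserving) are available via
`surrogate_kind="phase"` for users who want a null that keeps
autocorrelation, but they are not the default because the scrambled-null
chance levels of the correlation metrics are defined by value
permutation. Correlation p-values are the parametric Spearman/Pearson
ones and therefore ignore autocorrelation; a circular block-permutation
p-value (`block_permutation_pvalue`, 30 s blocks by default) is provided
for honest inference when that matters.

## Coordination metrics

Spearman's ρ (midrank ties) for binary actions, Pearson's ρ for
continuous intentions; a pair is classified positive or negative when
p < α, else none, so the four categories
(positive/negative/none/degenerate) always partition the n(n−1)/2 pairs.
Sonic organization is |ρ| — invariant to complementing either series,
so co-playing and turn-taking count equally. Mean slider distance is the
time-averaged absolute difference of two intention series; it is a true
metric (symmetry and the triangle inequality are property-tested).
Real-vs-null contrasts are paired t tests over pairs with
Cohen's d = mean(diff)/sd(diff); zero-variance differences are flagged
degenerate instead of producing infinite d.

## Group alignment and windows

Group alignment at one second is |#support − #change| / N with support
x > 0.5 and change x < 0.5; values exactly 0.5 are deliberately counted
in neither camp (the slider's midpoint is labeled neutral) but remain in
the denominator. The formula is invariant to permuting musicians and to
reflecting every slider around 0.5. The chance level scrambles each
musician's row independently and averages the per-second alignment over
surrogates.

Windows: middle centers are floor((start+end)/2) of each sequence;
junction centers are the internal boundaries plus the performance-end
boundary, giving one window of each kind per sequence. A window is the
halfwidth (default 16 s) on each side of its center, center excluded —
32 points per window, 256 middle points for the study's 8-sequence
segmentation. Windows are clipped to [0, T), so the end-centered junction
window keeps only its left half (240 junction points for that
segmentation); overlaps between windows are allowed and warned about.
The middle-vs-junction contrast is Welch's t test by default, with the
pooled test as an option.

## Factors and regressions

Relational: familiarity is the mean of the two directed 0/1/2 ratings;
spatial proximity is |seat_a − seat_b| − 1 along a linear seating order
(circular distance by option); instrumental proximity is the same-family
indicator. Individual: expertise is the mean of years-in-ensemble and
years-practicing-CFI; familiarity-with-others and spatial eccentricity
are the musician's means over partners; instrument family enters as the
three pairwise contrasts winds/inharmonic, winds/strings,
strings/inharmonic.

Pair-level outcomes are modeled with crossed random intercepts for the
two member musicians — the standard remedy for dyadic non-independence —
implemented as variance components over a single super-group in
statsmodels MixedLM (REML). The fitting machinery provides no
Satterthwaite degrees of freedom, so Wald tests use the normal
approximation and the downgrade is logged. Each term also gets a
likelihood-ratio χ² from ML fits of the full model versus the model
dropping that term. Musician-level tables (one row per musician) are too
small for random-effects structure and use OLS with HC3 robust errors.
All p-values are two-sided. Singular or non-converged mixed fits are
flagged but their fixed effects are still returned.

## Synthetic ensemble generator

The generator's role is to produce recordings with the statistical
structure the analysis assumes — known directed coupling, occupancy
regulation, phase-scheduled alignment — not to model music.

**Actions** follow a coupled logistic (Glauber-style) binary process:
musician i plays at t with probability
σ(b_i + Σ_j w_ij s_j(t−1) + g(K* − mean_j s_j(t−1)) + h s_i(t−1)).
Defaults: 15 musicians over T = 1159 s with the study's 8-sequence
segmentation; occupancy target K* = 0.6 (the observed ≈60% mean
occupancy); occupancy gain g = 1; persistence 0.9 (h = logit 0.9 ≈ 2.2),
giving multi-second play bouts; coupling w = ±2 logit units for four
co-playing and three turn-taking pairs, one musician independent —
strong but plausible mutual influence producing pairwise |ρ| of the
order observed in real ensembles. Baselines b_i solve the exact
two-state (hold/enter) stationarity condition
K* = (1−K*)σ(b) + K*σ(b+h), shifted by −K*Σ_j w_ij, so the stationary
occupancy sits at the target without tuning; a naive mean-field logit
centering is biased by ≈0.03 under strong persistence. Note that the
occupancy feedback is itself a weak global coupling: with g > 0 no pair
is perfectly independent, which slightly inflates measured "false alarm"
rates above the 1−(1−α)² pair-level floor of a calibrated test.

**Intentions** follow consensus-plus-attractor dynamics,
x_i(t+1) = x_i + λ(t)(m_i(t) − x_i) + c Σ_j f_ij (x_j − x_i) + ε,
clipped to [0, 1], with f the row-normalized familiarity matrix,
c = 0.05, and Gaussian ε with sd 0.08. Away from junctions every
musician relaxes slowly (λ = 0.05) toward a common support attractor at
0.75; inside ±16 s junction windows each musician relaxes faster
(λ = 0.25) toward an independent uniform draw. This yields the intended
phase structure — alignment high mid-sequence, collapsing at junctions,
positively coupled to the mean slider value — with 12 intention streams
(three sliders "lost", as in the motivating dataset).

What the generator does **not** emulate: audio, any acoustic coupling,
non-stationary slow drifts, heterogeneous per-musician baselines, or
familiarity-dependent action coupling. Passing recovery tests therefore
shows the estimators work when their assumptions hold at realistic sizes
and noise levels, not that real performances satisfy those assumptions.

## Numerical choices and degenerate inputs

Granger designs are solved by `numpy.linalg.lstsq`; rank deficiency
raises a collinearity error with the rank diagnostics. F statistics are
clipped at 0. ADF uses AIC lag selection. Spearman ties use midranks.
Scrambling uses `numpy.random.Generator.permutation` under explicit
seeds; every pipeline stage derives its randomness from the run seed, and
re-running a manifest reproduces all tables bit-identically. Constant
series, empty masks, zero-variance predictors and n = 1 summaries raise
or flag rather than returning silently wrong numbers.

## Problem sizes used in the checks

The test suite exercises study-sized objects where the quantity depends
on size (15 musicians × 1159 s for recovery, 2000 directed tests for
null calibration, 200 generator replicates for the false-alarm estimate,
2000 replicates for regression-recovery coverage) and small objects
elsewhere. The acceptance script uses 20 generator replicates for
recovery and alignment and 200 for regression recovery, which keeps a
full run near half a minute while leaving Monte Carlo error small
relative to the effects measured.

## Known limitations

- The Granger F test on binary series is mildly anticonservative under
  strong persistence (≈+0.3 percentage points per direction); an exact
  permutation Granger test would remove this at ~100× the cost.
- Pair-level false-alarm rates under "at least one direction significant"
  have a hard floor of 1−(1−α)² ≈ 9.75% at α = 0.05 even for a perfectly
  calibrated test; specificity bounds tighter than ~10% cannot be met
  under this definition.
- Correlation p-values ignore autocorrelation unless the block-permutation
  option is used, so "significant pair" counts are optimistic on strongly
  autocorrelated data.
- Mixed-model Wald p-values use a normal approximation; for ~100 dyads
  this is accurate to a few percent but slightly liberal.
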