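# Methods

This note documents the models, estimators and numerical choices behind
`smrpipe`, and what its synthetic benchmarks do and do not demonstrate.

## The analysis problem

During kinesthetic motor imagery the sensorimotor mu (8–14 Hz) and beta
(15–30 Hz) rhythms desynchronize: their amplitude drops relative to a
reference state. The pipeline quantifies this event-related
desynchronization (ERD) from 30-channel EEG recorded in a block design
where runs of twelve 6 s trials interleave six imagery trials with six
visual-attention trials (the reference, non-motor state). Sessions span
six days per subject; on days 1 and 6 the subject receives real-time
classifier feedback. The questions the inference layer answers are
whether the spatial ERD sources and the ERD strength are stable across
days and whether feedback changes them.

## Spatial sources by generalized eigendecomposition

Sources are *statistical* directions in the 30-dimensional sensor
space, not anatomical dipoles. With C_active and C_passive the sample
covariances of the 7–27 Hz band-passed signal in the imagery and
visual-attention windows, the spatial filters W solve

    C_passive^{-1} C_active W = W Λ,    W^T C_passive W = I.

Columns with the smallest eigenvalues minimise imagery-band variance
relative to the reference — the ERD sources; the largest eigenvalues
correspond to relative synchronization (e.g. posterior alpha). The
scalp projection ("forward model") of a filter is A = C_active W with
unit-norm columns; with C_passive-orthonormal W this equals W^{-T} up
to column scale, which a test verifies algebraically.

Numerical choices:

* C_passive gets trace-preserving shrinkage `(1-γ)C + γ(tr C/30)I`
  with γ = 0.01 before inversion; C_active is left untouched. With
  γ = 0 the decomposition is the exact generalized eigenproblem (tests
  use this path for the algebraic identities).
* Eigenvector signs are arbitrary; each forward-model column is flipped
  so its largest-magnitude element is positive, and the filter is
  flipped with it so A ∝ C_active W holds with positive proportionality.
* 10-fold cross-validation: GED is recomputed on 90 % of kept trials
  per fold; fold patterns are sign-aligned to the first fold and
  averaged (mean of unit-norm columns, re-normalised). The fold-mean
  filters are then applied to the full session for ERDd profiling; the
  classifier's own cross-validation handles train/test separation where
  generalisation is actually measured.
* Trials whose covariance is far from the condition's elementwise
  median covariance (Frobenius distance above mean + 2 SD of the
  distances) are rejected before the GED. Rejection never empties a
  condition and is skipped (with a warning) below 3 trials.
* The covariance window is 2–6 s after the cue, the same steady-state
  window the ERDd uses; the first 2 s are dominated by cue-evoked
  transients.

## The ERDd score

For a component and 1 Hz frequency bin, single-window spectral power
samples are collected from the imagery and reference conditions (1 s
Hann windows, 90 % overlap, windows fully inside 2–6 s post-cue). The
ERDd is

    ERDd = ±100 · TV(f_active, f_reference),

100 times the total-variation distance between the two power densities,
signed negative when the active-condition median power is lower
(desynchronization) and positive otherwise. It is distribution-free —
no Gaussian or log-normal assumption on power — and saturates at ±100
for non-overlapping distributions.

Estimation: Gaussian KDE on log power (Silverman bandwidth), evaluated
on a 512-point grid spanning the pooled range ± 3 bandwidths, each
density renormalised to unit mass, trapezoidal integration. Log scale
stabilises the heavy right tail of spectral power. Median ties fall
back to the mean difference for the sign, then to zero. The KDE-TV
estimator has a positive noise floor on null data that decays roughly
as n^(−2/5): about 7 points at 200 independent samples per side, below
4 points from ~1000. Tests and the calibration suite therefore evaluate
null behaviour at sample sizes where the floor is below the asserted
bound; with the 90 %-overlap window grid roughly every tenth window is
independent.

Closed-form anchor: for LogNormal(0,1) vs LogNormal(1,1) power the log
scale gives two unit-variance Gaussians one σ apart, whose TV is
2Φ(1/2) − 1, i.e. ERDd ≈ −38.3. The acceptance suite recomputes this.

Feature selection searches 7–26 Hz (ERD; up to 30 Hz for ERS features):
per component the peak-|ERDd| bin is found (ties toward the lower
frequency, mu priority) and extended to the maximal contiguous run of
bins with |score| ≥ 30 % of the peak and the same sign. Band power is
the mean of the squared-magnitude Fourier coefficients across the
band's bins — averaging complex coefficients would cancel phase and
destroy the power feature.

The run-level ERDd response used by the mixed models is the mean score
of the two strongest ERD sources (most negative peak ERDd; typically
the contra- and ipsilateral sensorimotor sources), each scored on its
own feature band, imagery vs visual-attention windows within that run.

## Classifier

The offline replica of the online chain: 4th-order Butterworth 6–40 Hz
(applied zero-phase offline), GED filters fitted on the training
trials, STFT band-power features for at most five (component, band)
combinations ranked by |ERDd| of the band-averaged power, and a
Gaussian naive Bayes on log band power with equal priors. The "erd"
feature set admits only negative-ERDd features (as used online); the
"erd+ers" set admits both polarities, adding e.g. the posterior-alpha
synchronization during visual attention. ERD candidates are searched in
the 8 smallest-eigenvalue components, ERS candidates in the 4 largest.

Evaluation: per 1 s window the posterior of the imagery class; the
trial score is the fraction of correctly classified windows inside
2–6 s, and the headline accuracy is its mean over test trials (a
window-majority trial accuracy is reported alongside). Two schemes:
5×2 CV (five seeded stratified halvings, both directions) and
chronological expanding-window CV (warm-up = the first run of 12
trials, each later trial classified by a model trained on all strictly
earlier trials).

## Inference

**Pattern permutation test.** Per source, one mean forward model per
day. Similarity of two days is |ρ| (pairwise sign alignment — polarity
is arbitrary; aligning all days to day 1 would make a feedback day the
reference and bias the statistic, measurably deflating the type-I
rate). The statistic is (mean |ρ| between feedback and non-feedback
days) − (mean |ρ| among non-feedback days); small values mean the
feedback-day patterns stand apart, so the test is left-tailed. The null
draws the two pseudo-feedback days uniformly from the 14 non-identity
day pairs; p = (#{null ≤ observed} + 1)/(N + 1), the add-one term
representing the identity assignment exactly once. With 6 days there
are only 15 distinct assignments, so attainable p-values are multiples
of ~1/15 and the exact type-I error at α = 0.05 is 1/15 ≈ 0.067;
the calibration run in the acceptance suite reproduces this.

**Mixed models.** Run-level ERDd tables are fitted with statsmodels
`MixedLM` (REML for estimates, ML for model comparison). The model
catalogue: day drift with random day slopes (days 2–5, familiar
imageries), its day-free reduction, feedback × subject with random
imagery-type slopes, and the three-level video/feedback/no-feedback
factor for the novel thumb imagery. Optimizers are tried in sequence
(BFGS, Powell, L-BFGS, CG) and a converged fit is preferred;
non-convergence is flagged, never silent.

Satterthwaite degrees of freedom are computed from an explicit REML
criterion on the natural scale (unique elements of the random-effect
covariance G plus the residual variance): Var(c'β̂) = c'(X'V⁻¹X)⁻¹c,
its gradient by central differences, the variance-parameter covariance
from the numerically differentiated REML Hessian (pseudo-inverse, PSD-
clipped), and df = 2f²/(g'Var(θ̂)g). Variance components whose fitted
value is numerically zero sit on the boundary and are excluded from the
uncertainty propagation; in the boundary case of a pure fixed-effects
model this reproduces the classical residual df exactly. Multi-df
terms use the eigendecomposition-combination rule (per-eigendirection
1-df Satterthwaite dfs combined through E = Σν/(ν−2),
ddf = 2E/(E−q)). The implementation is cross-checked in the test suite
against R's lmerTest on the same data (agreement to ≈4 decimals).

The "simulated likelihood ratio" is a parametric bootstrap: the
observed 2(ℓ_full − ℓ_reduced) from ML fits is compared with the
distribution obtained by simulating responses from the reduced ML fit
(fixed effects + Gaussian random effects + residual), refitting both
models; p uses the add-one rule with a Clopper–Pearson 95 % interval.

Classifier accuracies are compared with additive fixed-effects ANOVA
(type-II SS) over subject, feedback and CV-scheme factors — the
additive layout reproduces the denominator-df structure of the study
design (42 cells → 34 df two-way; 84 → 75 df three-way).

## Synthetic data

Each source is a fixed unit-norm scalp topography (smooth dipole-like
bumps centred on C3/C4 for the mu pair, the posterior midline for the
optional alpha source — only the unit norm matters to the algebra)
driving Gaussian noise band-passed to its rhythm (zero-phase 4th-order
Butterworth), the standard phenomenological model of sensorimotor
rhythms. ERD is planted multiplicatively: the source envelope is scaled
by 1 − depth during its active condition, with 100 ms raised-cosine
gates at trial boundaries to avoid filter ringing. The background is
per-channel 1/f noise (power exponent 1) plus white noise at 10 % of
its RMS. Trials are cut from a continuously rendered run (1 s lead-in,
2–3 s inter-stimulus intervals), so file export and direct epoching
agree exactly.

Defaults mirror the emulated study design: 7 subjects × 6 days; days
1–4 have 6 FR + 3 each FL/SR/SL runs (15 familiar runs/day, so the
familiar-imagery models see ~630 runs); days 5–6 add 3 TR + 3 TRv
runs; feedback flags on days 1 and 6, never on video-guided TRv.
Default source amplitude 20 µV RMS against a 10 µV background;
recovery claims are made at amplitude 30 µV (SNR 3). The run-level
table generator uses intercept −50 ERDd points, between-subject SD 15
and residual SD 9, sized so a per-subject feedback contrast (30
feedback vs 60 no-feedback runs) has a standard error near 2 ERDd
points (σ√(1/30 + 1/60)), the regime in which a +13-point effect is
detected decisively while null subjects stay null.

What the synthetic benchmarks do **not** show: the generator has no
head-model leadfield (topographies are cosmetic), no ocular/muscle
artifacts, no non-stationarities beyond the planted ones, and no
between-day electrode-placement variability. Passing recovery and
calibration tests therefore validates the estimators and their
couplings under the assumed signal model, not robustness to real-world
artifacts. No trials are lost to rejection in clean synthetic data by
construction; the rejection rule is exercised with planted outliers.

## Problem sizes in the validation suite

Benchmarks are sized to be decisive yet quick: ERDd oracles at 10⁵
samples; GED recovery from a 3-run session at SNR 3; classifier CV on
2-run sessions; permutation calibration with 1000 null repetitions of
999 draws; mixed-model coverage with 100 study-sized simulations;
bootstrap-LRT demonstrations on reduced layouts with random-intercept
models (the operation defaults to the full 1000 simulations). These
are the package's validation choices and can be scaled up freely via
the respective function arguments.

## Known limitations

* The permutation test's 15-assignment granularity is inherent to the
  6-day/2-feedback-day design; p-values below ~1/15 are unattainable
  at the day level.
* Satterthwaite dfs rely on numerical differentiation; for variance
  structures fitted exactly on a boundary the df of between-subject
  contrasts can degenerate (reported as infinite, with a χ² fallback
  for the p-value).
* The EDF+ writer targets the subset of the format the pipeline needs
  (16-bit samples, 1 s records, one annotation channel); it is verified
  against the MNE reader, not against every EDF consumer.
* `cv_timeseries` refits the full chain per evaluated trial; it is
  O(n²) in trials and intended for run-sized datasets.
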