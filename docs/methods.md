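# Methods

## Problem setting

Motor-imagery brain–computer interfaces classify short multi-channel EEG
epochs by the event-related desynchronization (ERD) of the sensorimotor mu
rhythm: imagining a hand movement attenuates an 8–13 Hz oscillation over the
contralateral sensorimotor cortex.  Two design choices dominate accuracy:
*where* to look (a spatial filter combining channels) and *at which
frequencies* (the reactive band is subject-specific and rarely wider than
3 Hz).  This package optimizes both jointly against the quantity that
actually matters — held-out classification error.

## Time–frequency decomposition (BMFLC-KF)

Each channel is modeled as a truncated Fourier series on a fixed grid
f₁…f_n with spacing Δf:

    y_k = x_kᵀ w_k + v_k,      w_{k+1} = w_k + η_k,

where x_k stacks sin(2π f_i k/f_s) and cos(2π f_i k/f_s) terms and w_k
holds the 2n sine/cosine coefficients.  A Kalman filter with random-walk
state tracks w_k sample by sample; the amplitude of bin i at instant k is
√(a_ik² + b_ik²).  Defaults: f₁ = 6 Hz, f_n = 14 Hz, Δf = 0.5 Hz (17 bins),
measurement noise R = 1, process noise Q = 0.01·I, initial weights 0,
initial covariance I.  R and Q are exposed in `BMFLCConfig`; their ratio
sets the adaptation bandwidth (smaller q/R → smoother, slower tracking) and
the defaults give steady-state amplitudes within 5 % of a batch
least-squares Fourier fit on noiseless on-grid signals after a 1 s burn-in.

Implementation note: the state transition is the identity, so the error
covariance and Kalman gain depend only on the reference sequence, not the
measurements.  One covariance recursion per trial therefore serves all
channels, and per-channel updates vectorize; this is exact, not an
approximation (pinned by a test against the per-sample scalar recursion).
The weight state resets at each trial start because trials are independent
cue-locked epochs.  The phase convention is sample-indexed, ω_i k meaning
2π f_i k/f_s.

## Preprocessing

A fifth-order Butterworth band-pass to [f₁, f_n], designed as second-order
sections for numerical stability, applied forward–backward (zero phase) for
offline analysis; a causal single-pass mode exists for real-time parity.
Trials are reflect-padded by three filter-order lengths to suppress edge
transients.  No artifact rejection or re-referencing is performed.

## Spatial filtering baselines (CSP / TRCSP)

The configuration-2 front-end maximizes, for each class c,

    wᵀ C_c w / (wᵀ (C₁+C₂) w + α‖w‖²),

solved one eigenvector at a time from the generalized problem
C_c v = ν (C₁+C₂+αI) v.  Class covariances are per-trial, trace-normalized,
averaged within class.  α = 0 recovers classical CSP; α is chosen on the
training set by inner cross-validation of the full TRCSP→BMFLC→LDA chain
over the grid {0, 10⁻³, 10⁻², 10⁻¹, 1}, ties resolving to the smallest α.
Filters are unit-norm with the largest-magnitude coefficient positive
(eigenvectors are sign-ambiguous).  Rows alternate
best-for-class-1/best-for-class-2, so pair j sits in rows 2j, 2j+1; a
22-channel montage admits at most 11 pairs.

The number of pairs to keep is selected by a generalization index: each
subject's training accuracies across candidate pair counts are
unity-normalized (min→0, max→1) so every subject's optimum scores 1, then
averaged over subjects; the argmax wins, ties favoring fewer pairs.  A
subject with a constant row is mapped to all ones (indifferent) and logged.

## Solution encoding and fitness

A candidate is the flat vector [sf₁₁…sf₁M, sf₂₁…sf₂M, …, FS, BW] of length
P·M+2 (P filters over M channels, P defaulting to the class count).
Decoding snaps FS to the nearest grid point and BW to whole grid steps;
infeasible values are repaired by projection onto FS ∈ [f₁, f_n−BW],
BW ∈ (0, 3], so the fitness landscape remains pure classification error
with no penalty terms.  Per trial, the amplitude map is sliced to the
selected bins, averaged over the analysis window, projected through the
P×M bank (projection and mean commute, so the mean map is precomputed
once), and flattened to a P·n_selected feature vector.

Fitness is the stratified k-fold (default 10) cross-validated error of a
two-class LDA on these features.  The partition is fixed once per
optimization run so the fitness is deterministic for the engines; a noisy
fitness would confound the engine comparison.  Features are z-scored with
fold-train statistics before LDA — this makes the error exactly invariant
to positive rescaling of any filter row (LDA then sees the same
standardized inputs) and keeps the problem well-posed when a feature has
zero variance.  The inner-loop LDA is a closed-form two-class discriminant
with fixed shrinkage 0.1 of the per-class covariances toward tr(S)/p·I,
prediction-equivalent to the estimator-based `classify.lda_fit` route
(pinned by a test) but an order of magnitude faster, which matters at
10⁴ fitness calls per run.

## Evolutionary engines

**CMA-ES** — standard (μ/μ_w, λ) covariance-matrix-adaptation with the
usual tutorial constants (log-rank recombination weights, cumulation and
learning rates c_c, c_σ, c₁, c_μ, step-size damping).  The offspring count
defaults to λ = 5·dim (230 for the 46-dimensional 22-channel problem),
μ = λ/2.  Spatial-filter coordinates are unconstrained (initialized in
[−1, 1]); FS/BW samples outside their boxes are repaired by reflection,
which preserves the sampling distribution's local shape better than
clipping.  Non-finite fitness values rank worst and are logged.

**GLGA** — steady-state real-coded GA.  Per iteration: the female parent is
the least-recently-used member of the n_f best (uniform fertility
selection, ties to better fitness); the male parent is the most distant of
five candidates drawn by fitness-proportional roulette from the male pool
(negative assortative mating; the wheel weight is worst_error − error + ε,
since lower error is better and the mapping from error to weight must be
chosen — roulette is underdetermined for minimization).  One offspring per
iteration via parent-centric BLX-α (uniform in [female ± α·|female−male|],
α = 0.5, clipped to the box) replaces the worst member if better.  The
female/male pools are N/2 and N for the first 25 % of the 10,000-evaluation
budget (global search), then 5 and 100 (local search); population N = 100
so the printed local male-pool size is attainable without capping (capped
with a log message otherwise).  The budget counts every fitness call
including the initial population, and the run stops at exactly the budget.

Both engines record per-checkpoint best/mean/std fitness; the best-so-far
series is non-increasing by construction, and the error-improvement metric
is its max minus min.

## Evaluation protocol

Outer evaluation is repeated stratified 10-fold cross-validation ("10-times
cross-validation" read as 10-fold; a `repeats` parameter covers the
10-random-holdouts reading).  All feature optimization — CSP fitting, α
selection, the EA run — happens inside each training split; accuracy comes
from the untouched held-out split.  A label-permutation canary (optimize on
shuffled labels, score held-out) sits in the test suite to certify the
absence of leakage.  Configuration comparisons aggregate paired accuracies
into win-count matrices (ties count for neither side).

## Synthetic data

The generator plants one discriminative latent source: a narrowband
Gaussian process (band-pass-filtered white noise, so the decomposer sees a
band rather than a spectral line) confined to a sub-band of 6–14 Hz,
projected to sensors through a fixed, spatially localized mixing column,
with amplitude A in class 1 and (1−d)·A in class 0 — the ERD contrast,
depth d ∈ [0, 1].  Background sources are class-independent 1/f processes;
sensor noise is 0.8·(1/f) + 0.2·white.  Defaults mirror a 22-channel,
250 Hz recording with 72 trials per class of 4 s.  Cohorts randomize the
band center in [7.5, 12.5] Hz (a 3 Hz window always fits) and the mixing
per subject.

What the generator does **not** emulate: volume-conducted correlated
artifacts (EOG/EMG), non-stationarity across a session, realistic forward
models, or multi-class structure.  Passing tests therefore demonstrate the
machinery recovers planted spatio-spectral structure under EEG-like noise,
not performance on real recordings.

## Problem sizes in tests and the acceptance script

Test and acceptance runs use desk-scale conditions chosen once: 6-channel
subjects, 16 trials per class, 2 s at 160 Hz, ERD depth 0.9, noise level
2.5 for band-recovery runs (high enough that only bands overlapping the
planted one reach low error, which makes the band identifiable) and 2.0
for cohort comparisons; CMA-ES runs 15–30 generations there.  Structural
rules (bin counts, λ = 5·dim, the 10,000-evaluation GLGA budget) are
verified at full scale since they cost nothing.

## Known limitations

- Band selection is a single contiguous window; multi-band effects are out
  of scope.
- One spatial-filter bank serves all selected bins; per-frequency filters
  are not modeled.
- When the fitness plateaus at zero error (very strong effects, little
  noise), the decoded band is identifiable only up to overlap with the
  true band — many solutions are exactly optimal.
- The EDF adapter requires uniform per-channel sampling rates and the
  optional `mne` dependency.
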