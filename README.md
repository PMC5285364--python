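# evobci

Evolutionary joint optimization of spatial filters and a subject-specific
frequency band for motor-imagery EEG classification.

## The problem

Motor-imagery brain–computer interfaces decode imagined movements from the
event-related desynchronization (ERD) of the sensorimotor mu rhythm — a
task-related amplitude drop of an 8–13 Hz oscillation, confined to a narrow
subject-specific band and a subset of scalp channels.  A classifier
therefore needs a **spatial filter** (which channel combination to watch)
and a **band selection** (which frequencies).  These are usually tuned
separately and by proxies (signal variance for CSP, visual inspection for
the band); this package tunes them *jointly* against the criterion that
matters, the cross-validated classification error.

## The method

1. **BMFLC-KF decomposition.**  Each channel is modeled as a truncated
   Fourier series on a fixed grid (6–14 Hz in 0.5 Hz steps, n = 17 bins):
   y_k = x_kᵀw_k + v_k with a random-walk weight model w_{k+1} = w_k + η_k.
   A Kalman filter tracks the 2n sine/cosine coefficients per sample; bin
   amplitudes are W_k(i) = √(a_ik² + b_ik²).  On a 22-channel montage this
   yields a 374-dimensional instantaneous feature space.
2. **Solution encoding.**  A candidate packs P spatial filters over M
   channels plus a starting frequency FS and bandwidth BW (≤ 3 Hz) into one
   real vector [sf₁₁…sf₁M, sf₂₁…sf₂M, …, FS, BW] of length P·M + 2.
3. **Fitness.**  Decode → slice the amplitude maps to the selected bins →
   average over the trial window → project through the P×M bank (SFᵀF_k) →
   stratified 10-fold CV error of a shrinkage LDA.
4. **Engines.**  A (μ/μ_w, λ) CMA-ES with λ = 5·dim, or a global/local
   steady-state real-coded GA (GLGA: uniform fertility selection, negative
   assortative mating, parent-centric BLX-α crossover with α = 0.5,
   replace-worst; 10,000 evaluations, 25 % global).
5. **Baselines.**  Manual channel-pair selection (configuration 1) and a
   Tikhonov-regularized CSP front-end (configuration 2), plus the
   generalization-performance-index procedure for choosing the number of
   CSP filter pairs.

A synthetic ERD generator (narrowband latent source with class-dependent
amplitude, 1/f background) makes every stage testable without external
recordings; an HDF5 epoch container and an optional EDF reader handle I/O.

## Worked example

```python
from evobci import SynthConfig, generate_subject, optimize, error_improvement

cfg = SynthConfig(channels=6, trials_per_class=16, rate_hz=160.0,
                  duration_s=2.0, planted_band_hz=(9.0, 11.0),
                  erd_depth=0.9, noise_level=5.0, seed=42)
epochs, truth = generate_subject(cfg)
res = optimize(epochs, engine="cmaes", seed=0, max_generations=30)
print(f"planted band : {truth.band_hz[0]:.1f}-{truth.band_hz[1]:.1f} Hz")
print(f"decoded band : {res.band_hz[0]:.1f}-{res.band_hz[1]:.1f} Hz")
print(f"CV error     : {res.best_error:.3f}")
print(f"improvement  : {error_improvement(res.trace):.3f}")
```

prints

```
planted band : 9.0-11.0 Hz
decoded band : 8.5-11.5 Hz
CV error     : 0.000
improvement  : 0.033
```

The optimizer recovered a 3 Hz window centered on the planted 10 Hz source
(decoded centers within 1 Hz of truth in ≥ 8/10 seeded runs at this effect
size), drove the inner cross-validated error to zero, and improved on the
best random initial candidate by 3.3 percentage points of error — the
max-minus-min spread of the best-error series over the run.

The same pipeline is scriptable from the shell:

```
evobci simulate --subjects 9 --seed 7 --out cohort/
evobci optimize --in cohort/subject_00.h5 --engine cmaes --out sol
evobci evaluate --data cohort/ --configurations 1,2,3 --out accuracy.csv
evobci compare  --table accuracy.csv --out wincount.csv
```

## Container layout

`evobci.io` writes epochs to HDF5 with datasets `X` (trials × channels ×
samples), `y` (labels), `channels` (names) and root attributes `rate_hz`
plus provenance metadata (seed, resolved configuration).  Accuracy tables
and evolution traces are CSV with mandatory header rows.
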