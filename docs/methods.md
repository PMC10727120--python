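# Methods

## The model

Event-locked EEG trials are reduced to a two-dimensional component space
and split into an evoked part and a fluctuation part.  For trial *i* in
condition *j*, the residual is

```
x_ij(t) = s_ij(t) − s̄_j(t)
```

the single-trial latent activity minus the same-condition trial average.
The residual's relaxation back to the mean is modeled as a first-order
linear dynamical system,

```
x(t+1) = A x(t) + ε(t),      ε(t) i.i.d. Gaussian,
```

with `A` a real 2×2 matrix fit by ordinary least squares (closed form via
the 2×2 normal equations, no intercept — residuals are mean-zero by
construction) to transition pairs pooled over trials and conditions inside
a 100-ms moving window.  At the 30 Hz analysis rate a 100-ms window holds
3 samples per trial, i.e. 2 transition pairs per trial.  The eigenvalues of
`A` are the per-sample decay factors of the two fluctuation modes: values
near 0 mean fast relaxation (a steep attractor basin), values near 1 mean
integrator-like persistence.  The developmental hypothesis is that these
decay factors shrink with age during task-related processing.

### Pipeline stages

1. **Conditioning** — zero-phase lowpass (4th-order Butterworth applied
   forward–backward; only the 15 Hz cutoff is canonical, the filter family
   and order are this package's documented default) and polyphase
   resampling to 30 Hz.  Trials are re-segmented around the fixation cue
   (−600…500 ms), flanker stimulus (−400…600 ms), or button response
   (−500…500 ms), windows inclusive of both endpoints
   (`round((end−start)/1000·fs)+1` samples).  Only trials with a response
   are kept (correct and commission errors); recordings need ≥ 50 trials
   per lock, judged per lock.
2. **Component space** — PCA of the sensors × sensors covariance of the
   time-concatenated, time-mean-centered grand-average condition ERPs from
   the stimulus- and response-locked segments.  The top two eigenvectors
   are kept, signs fixed so each component's largest-|loading| sensor is
   positive.  The space is fit once and reused for every recording and age.
3. **Standardization** — each recording's projected data are z-scored with
   one mean and one SD per component pooled over *all* trials and time
   points of the session (all three lock segmentations).  A per-timepoint
   z-score would flatten exactly the time-resolved variance structure the
   AR(1) model measures, so it is deliberately not offered.
4. **Dynamics** — condition means subtracted per session and lock
   (single-trial conditions are flagged and excluded), then the window
   sweep at one-sample steps.  Windows need ≥ 4 pairs (identifiability of
   the 4 entries of `A`); failed windows propagate as NaN, never as zeros.
   Eigenvalues are reported as moduli — the decay rate of a mode, equal to
   the eigenvalue itself when real — and complex-conjugate pairs share one
   modulus and set a flag.  Eigenpairs are labeled by which principal
   component their eigenvector loads on most strongly; when both claim the
   same component the larger loading wins and the other takes the
   remaining slot.
5. **Inference** — per window, a linear mixed model with a participant
   random intercept (longitudinal recordings), e.g.
   `eigenvalue = β₀ + β₁·age + u_participant + ε`.  The fixed-effect
   t statistics are enhanced with one-dimensional threshold-free cluster
   enhancement (E = 0.5, H = 2, the method's standard defaults; dh =
   max|t|/100), one-tailed in the stated direction.  The family-wise null
   resamples the predictor (outcome time courses intact), refits every
   window, applies TFCE, and keeps the extreme score; 10,000 replicates
   canonically.  Because the design is longitudinal, single recordings
   are not exchangeable: the slope's information lives largely in
   within-participant contrasts, and resampling recordings individually
   produces a null whose predictor has a different within/between-
   participant variance split than the observed one (measurably liberal
   under strong participant-level heterogeneity).  The default therefore
   resamples in participant blocks — whole wave-aligned predictor
   trajectories are permuted among participants with the same set of
   observed waves, and the values within each trajectory are permuted
   across waves — which preserves the predictor's longitudinal structure
   while breaking the predictor-outcome link.  Recording-level
   with-replacement resampling (`resample="bootstrap"`) and plain
   permutation (`"permutation"`) remain available.  Cluster p-values use
   the add-one convention `(1 + #{null ≥ observed})/(1 + reps)` and are
   compared with the Bonferroni-corrected level (0.05/6 = 0.0083 for the
   age family, 0.05/18 = 0.0027 for the behavior family).

### The mixed-model solver

The bootstrap refits the random-intercept model tens of thousands of times
per test, so the single variance component is profiled analytically:
with `V = I + γZZ'`, grouped-data identities give `a'V⁻¹b`, `log|V|` and
`log|X'V⁻¹X|` in O(n) per candidate γ, and the REML criterion is minimized
over γ by grid search plus golden-section refinement, vectorized across
bootstrap replicates and windows simultaneously.  `statsmodels.MixedLM` is
the reference implementation in the test suite: fixed effects and variance
components agree to ~1e-6; standard errors follow the model-based GLS
covariance `σ̂²(X'V̂⁻¹X)⁻¹` (statsmodels' `bse_fe` additionally includes
variance-parameter uncertainty and is a few percent larger).  Because
observed and null statistics use the identical estimator, small
optimizer-accuracy differences cannot bias the cluster test.

## The synthetic cohort generator

The generator is the package's study system: a three-wave longitudinal
flanker cohort (target ages 12/15/18, default 179 subjects, 38% wave
missingness, 384 trials/session, 104 sensors at 250 Hz) with known
ground-truth dynamics.

* **Trials** — cue at 0, stimulus after a 300–600 ms uniform delay,
  response at stimulus + RT.  RTs are Gaussian (congruent 354 ms,
  incongruent 404 ms, −8 ms/year, subject shifts, 70 ms trial SD) clipped
  to [250, 900] ms — sub-250-ms flanker responses would be anticipatory.
  Accuracy rises with age (congruent 0.97, incongruent 0.77 at age 15);
  2% of trials are omissions (no response).
* **Evoked templates** — sums of Gaussian-windowed deflections per
  condition per component: an early visual wave on component 1, a
  congruency-sensitive later wave, and error-sensitive post-response waves
  on component 2.  Amplitudes put the evoked response at roughly 5–10% of
  single-trial variance — single-trial EEG is noise-dominated; ERPs emerge
  only by averaging.  Between-subject amplitude (lognormal CV 0.3) and
  latency (SD 40 ms) variability, plus within-subject between-session
  variability (CV 0.25, 15 ms), reflect ERP test–retest reliability being
  well below 1.  The evoked share and heterogeneity levels are the
  generator's realism calibration: they are the parameters that decide how
  strongly latency jitter masquerades as dynamics, and they are set so the
  jitter control reproduces its expected qualitative outcome while leaving
  the dynamics-gradient analyses (which subtract the evoked response)
  untouched.
* **Dynamics** — residuals evolve on the 30-Hz analysis grid by the AR(1)
  law with per-epoch eigenvalues: `eig(age) = eig_ref + slope·(age−15)`.
  Defaults: (0.60, 0.50) in task epochs with slope −0.025/year in the
  stimulus- and response-processing epochs only (a 0.15 drop across
  12→18), flat around the cue, (0.55, 0.45) baseline.  Processing epochs
  follow *processing* time, not the analysis windows: the age-graded
  stimulus law engages 250–850 ms after stimulus onset (decision-stage
  processing rather than the sensory transient) and the response law
  0–500 ms after the button press.  Because the cue-locked analysis window
  ends 500 ms post-cue and the delay is at least 300 ms, cue-locked
  windows are governed by the age-flat law — matching the epoch
  specificity the pipeline is meant to detect.  Innovation SD 0.4 makes
  the z-scored latent SD ≈ 1.  Stability (spectral radius < 1) is
  validated over ages 10–20 before any simulation.
* **Sensor space** — a rank-2 smooth mixing (anterior–posterior gradient
  and a central focal pattern, orthonormalized) plus white sensor noise
  (SD 0.2 in latent units).  The true sensor-noise level of real
  recordings is unknown; this is a configuration choice, not an inference.
* **Behavior coupling** — session mean RT follows the eigenvalue at a
  standardized slope of 0.233 (z-units; eigenvalues referenced to mean
  0.5, SD 0.1), with subject intercepts (SD 0.35) and residual SD 0.90 so
  the session-level z(RT) variance is ≈ 1.  Accuracy decreases with the
  eigenvalue and increases with age, clipped to [0, 1].
* **Determinism** — one global seed fans out through per-subject
  `SeedSequence` substreams, so any subject subset is reproducible.

### What the generator does not emulate

No head-model forward simulation, no artifacts (blinks, muscle), no
oscillatory background (alpha/gamma), no autocorrelated sensor noise, no
condition-specific dynamics beyond mean subtraction, and the "true"
dynamics switch discretely between epochs rather than evolving smoothly.
Passing tests therefore show that the *pipeline* recovers what this
generative family injects under realistic amplitude/noise ratios — not
that real EEG obeys a 2-D AR(1) law.

## The latency-jitter control

Trials are rebuilt as `s̄_j(t + τ) + ε(t)` with `τ ~ N(0, σ_age)` per
trial (σ = 97/76/72 ms for ages 12/15/18 — the age groups' RT
variability) and i.i.d. Gaussian ε; there are no true dynamics anywhere.
Each session jitters *its own* empirical condition-mean latent ERPs,
measured on a matched reference cohort pushed through the standard front
end, and the ε SD defaults to the average residual SD of that reference
data.  Each trial is built once on the whole-trial timeline — one τ per
trial, applied to the full condition-mean waveform by linear
interpolation with nearest-value edge padding — and then segmented per
lock by the identical machinery, so event-locked features of the
jittered data carry exactly the smearing the condition mean has (a
per-lock re-jittering of already-locked averages would make stimulus- and
response-locked features unrealistically crisp).  The jittered cohort
then runs through the identical z-scoring, residual, AR(1), and
cluster-inference stages.  Jitter does create nonzero apparent
eigenvalues (a time-shifted mean is an autocorrelated residual) and a
slight age ordering via the age-graded σ, but at realistic
evoked-to-residual ratios these differences stay below the
cluster-corrected significance threshold — the qualitative control
outcome: timing variability alone does not explain the developmental
gradient.

## Desk-scale experiment profile

The validation experiments (`eegdyn.experiments`, run by both the test
suite and `scripts/acceptance.py`) use reduced problem sizes chosen once:
cohorts of 40 subjects × 3 waves (60 for the behavior-coupling study),
15% missingness, 64 trials/session, 16 sensors, data generated directly on
the 30-Hz analysis grid (the filter/resampler stage is exercised on
250-Hz fixtures in the unit tests), and 500 bootstrap replicates.
Calibration uses 200 pipeline runs; power/specificity and the jitter
control use 50; eigenvalue recovery uses 100 replicates of 2500 trials
(5000 pooled pairs); behavior recovery uses 200 cohorts.

## Numerical choices and degenerate inputs

* Window fits refuse < 4 pairs and singular second-moment matrices;
  skipped windows are NaN and are excluded from cluster extent (treated
  as zero height in TFCE).
* TFCE thresholds are the ladder `h = k·dh, k = 1…round(max/dh)`; the
  same ladder is used by the brute-force reference so the two agree to
  float precision.
* Bootstrap replicates that draw a constant predictor are redrawn (and
  counted); p-values can never be exactly zero by the add-one rule.
* The bootstrap uses complete-case recordings (a recording missing any
  window is dropped from that test); the per-window `fit_lmm_timecourse`
  path drops missing values pairwise instead.
* A sign/permutation resampling alternative is available
  (`resample="permutation"`) since resampling-with-replacement vs.
  permutation of the predictor is a judgment call; both are valid under
  exchangeability and agree in calibration tests.
* Corrected alpha levels are displayed truncated to 4 decimals (0.0083,
  0.0027); the untruncated values are used in comparisons.
* Zero jitter with zero noise is refused (all-zero residuals would make
  the AR fit degenerate), as are flat components in z-scoring (named in
  the error).

## Known limitations

* Complex eigenvalue pairs are summarized by their modulus; the analysis
  does not model rotational dynamics explicitly (windows are flagged).
* The participant-blocked null treats whole predictor trajectories as
  exchangeable among participants sharing a wave signature; participants
  with a unique signature contribute only within-trajectory permutations,
  slightly enriching the null with partially-unbroken draws (a
  conservative direction).
* Covariate-adjusted cluster tests (e.g. sex adjusted for age) go through
  the slower per-window path, not the vectorized bootstrap.
* The generator's epoch-switching dynamics are piecewise-constant in
  trial time; estimated eigenvalue time courses therefore change more
  abruptly at epoch boundaries than real data would.
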