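# eegdyn

Attractor dynamics of event-locked EEG across adolescent development.

## The problem

During adolescence, cortical networks are pruned and task performance
improves.  One mechanistic prediction is that pruning steepens the
attractor basins of cortical dynamics: fluctuations of neural activity
around the evoked trajectory should relax back to the mean *faster* in
older adolescents, specifically during task-related processing.

`eegdyn` implements the analysis that tests this on epoched, event-locked
EEG from a longitudinal flanker task (recordings at target ages 12, 15,
and 18).  Writing the single-trial activity in condition *j* as
`s_ij(t) = s̄_j(t) + x_ij(t)`, the residual `x(t)` — projected into the
first two principal components of the grand-average ERPs and z-scored per
subject — is modeled as a first-order linear dynamical system

    x(t+1) = A x(t) + ε(t)

fit by OLS in 100-ms moving windows (3 samples per trial at the 30 Hz
analysis rate).  The eigenvalues of `A` are per-sample decay factors:
near 0 = fast relaxation (steep basin), near 1 = integrator.  Age and
behavior effects on the eigenvalue time courses are tested per window with
random-intercept mixed models (`eigenvalue ~ age + (1|participant)`),
corrected over time by threshold-free cluster enhancement with a
10,000-replicate bootstrap null, one-tailed Bonferroni over the test
family (α = 0.05/6 for the age tests, 0.05/18 for behavior).

Because the raw recordings are not distributable, the package ships a
first-class synthetic cohort generator with known ground-truth dynamics
(age-graded eigenvalues in stimulus/response processing epochs, flat
around the cue) and the latency-jitter control: datasets whose trials are
time-shifted copies of the mean ERP (shift SD 97/76/72 ms by age group),
used to check that trial-timing variability alone cannot mimic the
developmental effect.

For whom: researchers analyzing trial-resolved dynamics of evoked EEG/MEG
responses, and anyone needing a calibrated 1-D TFCE + bootstrap +
mixed-model inference stack for short time series.

## Worked example

```python
from eegdyn import RunConfig, run_pipeline
from eegdyn.synth import CohortConfig

cfg = RunConfig(
    cohort=CohortConfig(n_subjects=40, n_trials=64, n_sensors=16,
                        fs_raw=30.0, missingness=0.15),
    cutoff_hz=None,          # cohort already at the 30 Hz analysis rate
    reps=500, seed=7,
)
res = run_pipeline(cfg)
print(res.space.explained_fraction.round(3))
for key, ci in res.inferences.items():
    print(key, ci.clusters() or "no clusters")
```

Output:

```
[0.794 0.18 ]
eigenvalue~age|eig1|cue no clusters
eigenvalue~age|eig1|stimulus [(333.33333333333337, 566.6666666666666)]
eigenvalue~age|eig1|response [(-33.333333333333314, 466.66666666666663)]
eigenvalue~age|eig2|cue no clusters
eigenvalue~age|eig2|stimulus [(266.66666666666663, 566.6666666666666)]
eigenvalue~age|eig2|response [(-133.33333333333331, 466.66666666666663)]
```

The two components carry ~97% of the grand-average ERP variance (the
generator's spatial structure is rank-2 by construction).  The injected
age gradient — decay factors falling 0.025/year during stimulus and
response processing — is detected as significant clusters (start/end ms
of each cluster relative to the lock event, on the 33-ms window grid) in
the stimulus- and response-locked tests and nowhere in the cue-locked
tests: the epoch specificity the analysis is designed to resolve.

The `analysis/` scripts run the same story as a narrative sequence
(simulate → fit dynamics → age inference → jitter control), writing
tables and a figure under `results/`.  A `eegdyn` console script exposes
the stages (`simulate`, `prep`, `fit-space`, `fit-dynamics`, `infer`,
`run`, `jitter-control`, `show-defaults`) for shell use.

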