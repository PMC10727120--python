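"""Canonical validation experiments at desk scale.

These drivers define the package's reference simulation studies: closed-form
constants, estimator cross-checks against independent oracles, parameter
recovery, type-I calibration of the cluster test, power/specificity of an
injected age gradient, the latency-jitter control, and recovery of the
RT-eigenvalue coupling.  The test suite and ``scripts/acceptance.py`` both
run them, so the numbers they report are always recomputed from scratch.

Desk-scale profile: 40-subject cohorts (60 for the behavior study), 3
waves, 64 trials/session, 16 sensors, data generated directly on the 30-Hz
analysis grid, 500 bootstrap replicates.  The filtering stage is exercised
separately on raw-rate fixtures in the unit tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import optimize, stats

from .dynamics import ResidualTrials, eig_order, fit_ar1_pairs, fit_window_ar1, window_samples_per_trial
from .inference import LmmSpec, correct_family, tfce_1d, tfce_brute_force
from .lmm import fit_random_intercept
from .pipeline import RunConfig, default_age_tests, run_jitter_control, run_pipeline
from .prep import RecordingMeta
from .synth import (
    ANALYSIS_FS,
    CohortConfig,
    GroundTruthDynamics,
    JitterConfig,
    simulate_ar1_trials,
    simulate_behavior,
)

_DUMMY_META = RecordingMeta("sim", "sim", 15.0, "F", 15)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def null_truth() -> GroundTruthDynamics:
    """Ground truth with no age dependence anywhere: flat dynamics AND flat
    behavior (an age-graded RT would move the response-locked ERP templates
    with age, a real if tiny age pathway that a type-I experiment must not
    contain)."""
    return GroundTruthDynamics(
        age_slope_by_epoch={
            "cue": (0.0, 0.0), "stimulus": (0.0, 0.0),
            "response": (0.0, 0.0), "baseline": (0.0, 0.0)},
        rt_age_slope=0.0, acc_age_slopes=(0.0, 0.0))


def desk_cohort(seed: int = 0, n_subjects: int = 40) -> CohortConfig:
    """Reduced cohort used by the calibration/power/jitter studies."""
    return CohortConfig(
        n_subjects=n_subjects, waves=(12.0, 15.0, 18.0), missingness=0.15,
        n_trials=64, n_sensors=16, fs_raw=ANALYSIS_FS, sensor_noise_sd=0.2,
        seed=seed)


def desk_config(
    seed: int,
    truth: GroundTruthDynamics,
    locks: tuple[str, ...],
    tests: tuple[LmmSpec, ...] | None = None,
    reps: int = 500,
) -> RunConfig:
    return RunConfig(
        cohort=desk_cohort(), truth=truth, locks=locks,
        cutoff_hz=None, target_fs=ANALYSIS_FS, min_trials=50,
        pca_locks=tuple(l for l in ("stimulus", "response") if l in locks) or locks,
        tests=tests, reps=reps, alpha=0.05, n_tests=6, seed=seed)


def analytic_constants() -> dict:
    """The three closed-form quantities of the analysis design.

    Corrected alphas are displayed truncated to 4 decimals, the
    conventional way one-sided corrected levels are printed (a truncated
    level never overstates the correction)."""
    import math

    return {
        "window_samples": window_samples_per_trial(30.0, 100.0),
        "alpha_6": math.floor(correct_family(0.05, 6) * 1e4) / 1e4,
        "alpha_18": math.floor(correct_family(0.05, 18) * 1e4) / 1e4,
    }


def ar1_oracle_max_diff(n_instances: int = 100, seed: int = 0) -> float:
    """Closed-form window fit vs. brute-force numerical least squares."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        A = rng.uniform(-0.9, 0.9, (2, 2))
        rho = np.max(np.abs(np.linalg.eigvals(A)))
        if rho >= 0.95:
            A *= 0.9 / rho
        x0 = rng.normal(0.0, 1.0, (2, 60))
        x1 = A @ x0 + rng.normal(0.0, 0.5, (2, 60))
        closed = fit_ar1_pairs(x0, x1)

        def resid(a_flat):
            return (x1 - a_flat.reshape(2, 2) @ x0).ravel()

        brute = optimize.least_squares(
            resid, np.zeros(4), xtol=1e-15, ftol=1e-15, gtol=1e-15
        ).x.reshape(2, 2)
        worst = max(worst, float(np.max(np.abs(closed - brute))))
    return worst


def eig_recovery(
    n_seeds: int = 100,
    true_eigs: tuple[float, float] = (0.8, 0.4),
    n_trials: int = 2500,
    tol: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recovery of generating eigenvalue moduli from pooled window fits.

    Each replicate simulates stationary AR(1) trials with A =
    diag(true_eigs), fits one 100-ms window pooling 2 pairs/trial
    (>= 5000 pairs), and scores whether both moduli land within ``tol``.
    """
    A = np.diag(true_eigs)
    n_success = 0
    errors = []
    for s in _spawn_seeds(seed, n_seeds):
        x = simulate_ar1_trials(A, n_trials, 3, noise_sd=0.4, seed=s)
        resid = ResidualTrials(
            values=x, fs=ANALYSIS_FS, lock="stimulus", start_ms=0.0,
            conditions=np.array(["congruent_correct"] * n_trials),
            recording=_DUMMY_META)
        times = resid.times_ms
        A_hat, n_pairs = fit_window_ar1(resid, float(times[1]), width_ms=100.0)
        assert n_pairs >= 5000
        moduli, _, _ = eig_order(A_hat)
        err = np.abs(moduli - np.asarray(true_eigs))
        errors.append(err)
        n_success += int(np.all(err <= tol))
    return {"n_success": n_success, "n_seeds": n_seeds,
            "mean_abs_error": float(np.mean(errors))}


def tfce_oracle(seed: int = 0, n_series: int = 5, length: int = 50) -> dict:
    """Fast TFCE vs. the explicit threshold/run double loop, plus the
    isolated-peak closed form h^3/3 approached as dh -> 0."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_series):
        s = rng.normal(0.0, 1.0, length)
        dh = max(s.max(), 0.1) / 100.0
        worst = max(worst, float(np.max(np.abs(
            tfce_1d(s, dh=dh) - tfce_brute_force(s, dh=dh)))))
    h = 2.0
    peak = np.zeros(21)
    peak[10] = h
    target = h**3 / 3.0
    rel_errors = [abs(tfce_1d(peak, dh=h / n).max() - target) / target
                  for n in (100, 1000, 5000)]
    return {"max_diff": worst, "peak_rel_errors": rel_errors,
            "peak_value": float(tfce_1d(peak, dh=h / 5000).max()),
            "peak_target": target}


def type1_calibration(n_runs: int = 200, reps: int = 500, seed: int = 0) -> dict:
    """Family-wise rejection rate of the age test on null cohorts.

    Each run simulates a 40-subject cohort with identical dynamics at every
    age, runs the full pipeline on the stimulus lock, and tests the first
    eigenvalue at the corrected level alpha/6.  The rejection rate should
    sit at the nominal corrected alpha.
    """
    tests = (LmmSpec(outcome="eigenvalue", fixed_predictor="age",
                     tail="negative", lock="stimulus", eig_index=1),)
    n_reject = 0
    for s in _spawn_seeds(seed, n_runs):
        cfg = desk_config(s, null_truth(), locks=("stimulus",), tests=tests,
                          reps=reps)
        res = run_pipeline(cfg)
        n_reject += int(next(iter(res.inferences.values())).any_significant)
    alpha_corr = correct_family(0.05, 6)
    lo, hi = stats.binom.interval(0.95, n_runs, alpha_corr)
    return {"n_reject": n_reject, "n_runs": n_runs, "rate": n_reject / n_runs,
            "nominal": alpha_corr, "binom95": (int(lo), int(hi))}


def power_specificity(n_runs: int = 50, reps: int = 500, seed: int = 0) -> dict:
    """Detection of an age gradient injected only in stimulus/response epochs.

    Success in a run = significant clusters (either eigenvalue) in both the
    stimulus- and response-locked tests and none in the cue-locked tests.
    """
    n_success = n_stim = n_resp = n_cue_fp = 0
    for s in _spawn_seeds(seed, n_runs):
        cfg = desk_config(s, GroundTruthDynamics(),
                          locks=("cue", "stimulus", "response"),
                          tests=default_age_tests(), reps=reps)
        res = run_pipeline(cfg)
        stim = res.significant("stimulus")
        resp = res.significant("response")
        cue = res.significant("cue")
        n_stim += int(stim)
        n_resp += int(resp)
        n_cue_fp += int(cue)
        n_success += int(stim and resp and not cue)
    return {"n_success": n_success, "n_runs": n_runs,
            "n_stimulus_detected": n_stim, "n_response_detected": n_resp,
            "n_cue_false_positives": n_cue_fp}


def jitter_null(n_runs: int = 50, reps: int = 500, seed: int = 0) -> dict:
    """Latency-jitter control: age-graded jitter SDs but no true dynamics
    gradient should produce no significant age clusters."""
    n_success = 0
    for s in _spawn_seeds(seed, n_runs):
        cfg = desk_config(s, null_truth(),
                          locks=("cue", "stimulus", "response"),
                          tests=default_age_tests(), reps=reps)
        res = run_jitter_control(cfg, JitterConfig())
        n_success += int(not res.any_significant)
    return {"n_success": n_success, "n_runs": n_runs}


def behavior_recovery(n_cohorts: int = 200, seed: int = 0,
                      n_subjects: int = 60) -> dict:
    """Recovery of the standardized RT-eigenvalue coupling (default 0.233).

    Each cohort simulates session eigenvalues with no age gradient, couples
    mean RT to them through ``simulate_behavior``, fits the mixed model
    z(RT) = b * z(eigenvalue) + (1|participant), and checks whether the
    generating slope lies in the fit's 95% CI.
    """
    truth = GroundTruthDynamics()
    n_covered = 0
    slopes = []
    for s in _spawn_seeds(seed, n_cohorts):
        rng = np.random.default_rng(s)
        rows = []
        for subj in range(n_subjects):
            shift = rng.normal(0.0, 0.35)
            for wave in (12.0, 15.0, 18.0):
                if rng.random() < 0.15:
                    continue
                age = wave + rng.normal(0.4, 0.5)
                eig = float(np.clip(rng.normal(*truth.rt_eig_ref), 0.01, 0.95))
                rt, _ = simulate_behavior(truth, eig, age, rng,
                                          subject_shift=shift)
                rows.append((subj, eig, rt))
        subj_ids, eigs, rts = map(np.asarray, zip(*rows))
        z_eig = (eigs - eigs.mean()) / eigs.std()
        z_rt = (rts - rts.mean()) / rts.std()
        fit = fit_random_intercept(z_rt, np.column_stack([np.ones_like(z_eig), z_eig]),
                                   subj_ids)
        lo, hi = fit.conf_int()[1]
        slopes.append(fit.params[1])
        n_covered += int(lo <= truth.rt_coupling <= hi)
    return {"n_covered": n_covered, "n_cohorts": n_cohorts,
            "mean_slope": float(np.mean(slopes))}


def jitter_tau_sd(n_trials: int = 10_000, age: float = 12.0, seed: int = 0) -> dict:
    """Empirical SD of the drawn latency shifts vs. the configured sigma."""
    from .synth import make_jittered_dataset

    jit = JitterConfig(eps_sd=0.0)
    erps = {"congruent_correct": np.vstack([np.sin(np.linspace(0, 6, 31)),
                                            np.cos(np.linspace(0, 6, 31))])}
    lt = make_jittered_dataset(erps, jit, n_trials, age, seed=seed)
    taus = lt.trials["tau_ms"].to_numpy()
    return {"empirical_sd": float(taus.std()), "sigma": jit.sigma(age)}
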