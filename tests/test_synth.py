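"""The synthetic cohort generator and the latency-jitter construction."""

import numpy as np
import pytest

from eegdyn.prep import CONDITIONS, RecordingMeta
from eegdyn.synth import (
    ANALYSIS_FS,
    Bump,
    CohortConfig,
    GroundTruthDynamics,
    JitterConfig,
    cohort_plan,
    epoch_of,
    latent_templates,
    make_jittered_dataset,
    simulate_ar1_trials,
    simulate_behavior,
    simulate_cohort,
    simulate_session,
)

META = RecordingMeta("r0", "p0", 15.0, "F", 15)


def small_config(**kw):
    defaults = dict(n_subjects=4, n_trials=12, n_sensors=6, fs_raw=30.0,
                    missingness=0.2, seed=0)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestConfigsAndTruth:
    def test_condition_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CohortConfig(condition_probs=(0.5, 0.5, 0.5, 0.5))

    def test_missingness_bounds(self):
        with pytest.raises(ValueError):
            CohortConfig(missingness=1.0)

    def test_unstable_dynamics_rejected(self):
        truth = GroundTruthDynamics(A_override=lambda e, a: 1.05 * np.eye(2))
        with pytest.raises(ValueError, match="spectral radius"):
            simulate_cohort(small_config(), truth)

    def test_rank_deficient_loadings_rejected(self):
        truth = GroundTruthDynamics(sensor_loadings=np.ones((6, 2)))
        with pytest.raises(ValueError, match="rank"):
            simulate_cohort(small_config(), truth)

    def test_age_gradient_parameterization(self):
        truth = GroundTruthDynamics()
        e12 = truth.eigs_at("stimulus", 12.0)
        e18 = truth.eigs_at("stimulus", 18.0)
        assert np.allclose(e12 - e18, 0.15)  # 0.025/year over 6 years
        assert np.allclose(truth.eigs_at("cue", 12.0), truth.eigs_at("cue", 18.0))


class TestEpochAssignment:
    def test_precedence_and_boundaries(self):
        stim, resp = 450.0, 830.0
        assert epoch_of(-300.0, stim, resp) == "cue"
        assert epoch_of(500.0, stim, resp) == "cue"  # before stim span onset
        assert epoch_of(750.0, stim, resp) == "stimulus"
        assert epoch_of(900.0, stim, resp) == "response"
        assert epoch_of(1400.0, stim, resp) == "baseline"

    def test_missing_response_never_labels_response(self):
        assert epoch_of(900.0, 450.0, np.nan) == "stimulus"


class TestSimulateCohort:
    def test_seeded_determinism_byte_identical(self):
        truth = GroundTruthDynamics()
        a = simulate_cohort(small_config(), truth)
        b = simulate_cohort(small_config(), truth)
        assert len(a) == len(b)
        for da, db in zip(a, b):
            assert np.array_equal(da.data, db.data)
            assert da.trials.equals(db.trials)
            assert da.recording == db.recording

    def test_zero_noise_trials_equal_templates(self):
        truth = GroundTruthDynamics(noise_sd=0.0, subject_amp_cv=0.0,
                                    session_amp_cv=0.0, subject_latency_sd=0.0,
                                    session_latency_sd=0.0)
        cfg = small_config(sensor_noise_sd=0.0, omission_prob=0.0)
        rng = np.random.default_rng(1)
        ds = simulate_session(cfg, truth, META, rng)
        L = truth.loadings(cfg.n_sensors)
        tmpl = latent_templates(ds.times_ms,
                                ds.trials["condition"].to_numpy(),
                                ds.trials["stimulus_ms"].to_numpy(),
                                ds.trials["response_ms"].to_numpy(),
                                truth.bumps)
        expected = np.einsum("sk,nkt->nst", L, tmpl)
        assert np.allclose(ds.data, expected, atol=1e-6)

    def test_longitudinal_structure(self):
        cfg = small_config(n_subjects=30, missingness=0.3, seed=5)
        plan = cohort_plan(cfg)
        ids = [p.meta.recording_id for p in plan]
        assert len(set(ids)) == len(ids)
        waves = {p.meta.wave for p in plan}
        assert waves <= {12, 15, 18}
        # missingness removes roughly the configured share of sessions
        assert 0.5 < len(plan) / (30 * 3) < 0.9
        for p in plan:
            assert abs(p.meta.age - p.meta.wave) < 3.0

    def test_metadata_carried_through(self):
        ds = simulate_cohort(small_config(), GroundTruthDynamics())[0]
        assert set(ds.trials["condition"]) <= set(CONDITIONS)
        resp = ds.trials["responded"]
        assert ds.trials.loc[resp, "rt_ms"].gt(0).all()

    def test_explicit_condition_probs_used(self):
        cfg = small_config(n_trials=400,
                           condition_probs=(1.0, 0.0, 0.0, 0.0))
        ds = simulate_cohort(cfg, GroundTruthDynamics())[0]
        assert set(ds.trials["condition"]) == {"congruent_correct"}


class TestSimulateAr1Trials:
    def test_stationary_variance_matches_lyapunov(self):
        A = np.array([[0.7, 0.2], [0.0, 0.5]])
        x = simulate_ar1_trials(A, 20000, 2, noise_sd=0.5, seed=0)
        from scipy.linalg import solve_discrete_lyapunov

        cov = solve_discrete_lyapunov(A, 0.25 * np.eye(2))
        emp = np.cov(x[:, :, 0].T)
        assert np.allclose(emp, cov, atol=0.02)

    def test_unstable_matrix_rejected(self):
        with pytest.raises(ValueError):
            simulate_ar1_trials(np.eye(2), 5, 3, 0.1)

    def test_zero_noise_zero_start_stays_zero(self):
        x = simulate_ar1_trials(0.5 * np.eye(2), 4, 6, noise_sd=0.0)
        assert np.all(x == 0.0)


class TestSimulateBehavior:
    def test_zero_coupling_decorrelates_rt_from_eigenvalue(self):
        truth = GroundTruthDynamics(rt_coupling=0.0)
        rng = np.random.default_rng(0)
        eigs = rng.uniform(0.3, 0.7, 300)
        rts = [simulate_behavior(truth, e, 15.0, rng)[0] for e in eigs]
        assert abs(np.corrcoef(eigs, rts)[0, 1]) < 0.12

    def test_default_coupling_recovered_by_regression(self):
        from eegdyn.experiments import behavior_recovery

        out = behavior_recovery(n_cohorts=25, seed=7)
        assert out["mean_slope"] == pytest.approx(0.233, abs=0.04)
        assert out["n_covered"] >= 21

    def test_accuracy_clipped_to_unit_interval(self):
        truth = GroundTruthDynamics(acc_coupling=-50.0)
        _, acc = simulate_behavior(truth, 0.9, 18.0, 0)
        assert acc == 1.0
        truth = GroundTruthDynamics(acc_coupling=50.0)
        _, acc = simulate_behavior(truth, 0.9, 12.0, 0)
        assert acc == 0.0

    def test_eigenvalue_domain_enforced(self):
        with pytest.raises(ValueError):
            simulate_behavior(GroundTruthDynamics(), 1.2, 15.0, 0)


class TestJitter:
    def erps(self, T=31):
        t = np.linspace(0, 4 * np.pi, T)
        return {"congruent_correct": np.vstack([np.sin(t), np.cos(t)]),
                "incongruent_correct": np.vstack([0.5 * np.sin(t), t / t.size])}

    def test_zero_jitter_zero_noise_reproduces_the_mean(self):
        jit = JitterConfig(sigma_by_age={12.0: 0.0}, eps_sd=0.0)
        lt = make_jittered_dataset(self.erps(), jit, 6, 12.0, seed=0)
        for i, cond in enumerate(lt.conditions):
            assert np.allclose(lt.values[i], self.erps()[cond])

    def test_age_group_sigmas_default_to_the_rt_sds(self):
        jit = JitterConfig()
        assert (jit.sigma(12.0), jit.sigma(15.0), jit.sigma(18.0)) == (97.0, 76.0, 72.0)

    def test_unknown_age_group_rejected(self):
        with pytest.raises(KeyError):
            JitterConfig().sigma(14.0)

    def test_empirical_tau_sd_close_to_sigma(self):
        from eegdyn.experiments import jitter_tau_sd

        out = jitter_tau_sd(n_trials=10_000, age=12.0, seed=0)
        assert abs(out["empirical_sd"] - out["sigma"]) / out["sigma"] < 0.03

    def test_shift_uses_edge_padding(self):
        jit = JitterConfig(sigma_by_age={12.0: 0.0}, eps_sd=0.0)
        erps = {"congruent_correct": np.vstack([np.arange(10.0), np.arange(10.0)])}
        lt = make_jittered_dataset(erps, jit, 1, 12.0, seed=0, fs=30.0)
        assert np.isfinite(lt.values).all()

    def test_unset_eps_requires_reference_data(self):
        with pytest.raises(ValueError, match="eps_sd"):
            make_jittered_dataset(self.erps(), JitterConfig(), 4, 12.0, seed=0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            JitterConfig(sigma_by_age={12.0: -1.0})
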