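"""Residuals, windowed AR(1) fits, eigenvalue ordering, and the sweep."""

import numpy as np
import pytest
from scipy import optimize, stats

from eegdyn.dynamics import (
    ResidualTrials,
    compute_residuals,
    eig_order,
    fit_ar1_pairs,
    fit_window_ar1,
    sweep_dynamics,
    window_samples_per_trial,
)
from eegdyn.latent import LatentTrials
from eegdyn.prep import RecordingMeta
from eegdyn.synth import simulate_ar1_trials

META = RecordingMeta("r0", "p0", 15.0, "F", 15)


def latent(values, conditions=None):
    values = np.asarray(values, dtype=float)
    conds = (np.asarray(conditions) if conditions is not None
             else np.array(["congruent_correct"] * values.shape[0]))
    return LatentTrials(values=values, fs=30.0, lock="stimulus", start_ms=0.0,
                        conditions=conds, recording=META)


def residuals(values, conditions=None):
    lt = latent(values, conditions)
    return compute_residuals(lt)


class TestComputeResiduals:
    def test_two_trial_condition_split_around_mean(self):
        a, b = 3.0, 7.0
        vals = np.zeros((2, 2, 5))
        vals[0], vals[1] = a, b
        res = residuals(vals)
        assert np.allclose(res.values[0], a - (a + b) / 2)
        assert np.allclose(res.values[1], b - (a + b) / 2)

    def test_per_condition_mean_is_zero(self):
        rng = np.random.default_rng(0)
        conds = np.array(["congruent_correct"] * 5 + ["incongruent_error"] * 4)
        res = residuals(rng.normal(size=(9, 2, 7)), conds)
        for c in np.unique(res.conditions):
            m = res.values[res.conditions == c].mean(axis=0)
            assert np.allclose(m, 0.0, atol=1e-12)

    def test_single_trial_condition_flagged_and_excluded(self):
        conds = np.array(["congruent_correct"] * 4 + ["congruent_error"])
        res = residuals(np.random.default_rng(1).normal(size=(5, 2, 6)), conds)
        assert res.n_single_trial_excluded == 1
        assert res.n_trials == 4
        assert "congruent_error" not in res.conditions


class TestFitWindowAr1:
    def test_noiseless_half_identity_recovered_exactly(self):
        x = simulate_ar1_trials(0.5 * np.eye(2), 20, 5, noise_sd=0.0)
        x[:, :, 0] = np.random.default_rng(2).normal(size=(20, 2))
        for t in range(4):
            x[:, :, t + 1] = 0.5 * x[:, :, t]
        res = ResidualTrials(values=x, fs=30.0, lock="stimulus", start_ms=0.0,
                             conditions=np.array(["congruent_correct"] * 20),
                             recording=META)
        A, n_pairs = fit_window_ar1(res, res.times_ms[2], width_ms=150.0)
        assert n_pairs == 80
        assert np.allclose(A, 0.5 * np.eye(2), atol=1e-12)

    def test_closed_form_matches_brute_force_least_squares(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x0 = rng.normal(size=(2, 40))
            x1 = rng.normal(size=(2, 40))
            closed = fit_ar1_pairs(x0, x1)
            brute = optimize.least_squares(
                lambda a: (x1 - a.reshape(2, 2) @ x0).ravel(),
                np.zeros(4), xtol=1e-15, ftol=1e-15, gtol=1e-15).x.reshape(2, 2)
            assert np.max(np.abs(closed - brute)) < 1e-8

    def test_generating_eigenvalues_recovered(self):
        hits = 0
        for seed in range(10):
            x = simulate_ar1_trials(np.diag([0.8, 0.4]), 2500, 3,
                                    noise_sd=0.4, seed=seed)
            res = ResidualTrials(values=x, fs=30.0, lock="stimulus",
                                 start_ms=0.0,
                                 conditions=np.array(["congruent_correct"] * 2500),
                                 recording=META)
            A, n_pairs = fit_window_ar1(res, res.times_ms[1], width_ms=100.0)
            assert n_pairs == 5000
            moduli, _, _ = eig_order(A)
            hits += int(np.all(np.abs(moduli - [0.8, 0.4]) <= 0.05))
        assert hits >= 9

    def test_too_few_pairs_refused(self):
        x = np.random.default_rng(4).normal(size=(1, 2, 3))
        res = ResidualTrials(values=x, fs=30.0, lock="stimulus", start_ms=0.0,
                             conditions=np.array(["congruent_correct"]),
                             recording=META)
        with pytest.raises(ValueError, match="pairs"):
            fit_window_ar1(res, res.times_ms[1], width_ms=100.0)

    def test_singular_moment_matrix_refused(self):
        x = np.zeros((5, 2, 3))
        res = ResidualTrials(values=x, fs=30.0, lock="stimulus", start_ms=0.0,
                             conditions=np.array(["congruent_correct"] * 5),
                             recording=META)
        with pytest.raises(np.linalg.LinAlgError):
            fit_window_ar1(res, res.times_ms[1], width_ms=100.0)


class TestEigOrder:
    def test_diagonal_matrix_keeps_axis_order(self):
        moduli, vecs, cflag = eig_order(np.diag([0.7, 0.3]))
        assert np.allclose(moduli, [0.7, 0.3])
        assert np.allclose(np.abs(vecs), np.eye(2))
        assert not cflag

    def test_swapped_loadings_swap_labels(self):
        # eigenvector of 0.7 lies on axis 2, of 0.3 on axis 1
        A = np.diag([0.3, 0.7])
        moduli, vecs, _ = eig_order(A)
        assert np.allclose(moduli, [0.3, 0.7])

    def test_rotation_pair_shares_modulus_and_flags_complex(self):
        r, th = 0.6, 0.8
        A = r * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moduli, _, cflag = eig_order(A)
        assert cflag
        assert np.allclose(moduli, [r, r], atol=1e-12)

    def test_both_claiming_same_axis_resolved_by_loading(self):
        # both eigenvectors load mostly on axis 1; stronger claimant wins
        A = np.array([[0.6, 0.3], [0.05, 0.2]])
        w, V = np.linalg.eig(A)
        moduli, vecs, _ = eig_order(A)
        assert sorted(moduli) == pytest.approx(sorted(np.abs(w)))


class TestSweepDynamics:
    def test_three_samples_per_window_at_30hz(self):
        assert window_samples_per_trial(30.0, 100.0) == 3

    def test_pairs_per_window(self):
        x = simulate_ar1_trials(np.diag([0.5, 0.5]), 12, 31, 0.3, seed=0)
        res = ResidualTrials(values=x, fs=30.0, lock="stimulus",
                             start_ms=-400.0,
                             conditions=np.array(["congruent_correct"] * 12),
                             recording=META)
        tc = sweep_dynamics(res)
        assert tc.window_centers_ms.size == 29
        assert np.all(tc.n_pairs == 24)  # 2 pairs x 12 trials

    def test_stationary_truth_gives_flat_timecourse(self):
        x = simulate_ar1_trials(np.diag([0.6, 0.6]), 3000, 31, 0.4, seed=1)
        res = ResidualTrials(values=x, fs=30.0, lock="stimulus",
                             start_ms=-400.0,
                             conditions=np.array(["congruent_correct"] * 3000),
                             recording=META)
        tc = sweep_dynamics(res)
        assert np.nanstd(tc.eig_moduli[:, 0]) < 0.03
        assert abs(np.nanmean(tc.eig_moduli[:, 0]) - 0.6) < 0.03

    def test_nonoverlapping_step_counts_windows(self):
        x = np.random.default_rng(5).normal(size=(10, 2, 31))
        res = ResidualTrials(values=x, fs=30.0, lock="stimulus",
                             start_ms=-400.0,
                             conditions=np.array(["congruent_correct"] * 10),
                             recording=META)
        tc = sweep_dynamics(res, step_samples=3)
        assert tc.window_centers_ms.size == 10  # centers 1,4,...,28

    def test_sweep_matches_single_window_fit(self):
        x = np.random.default_rng(6).normal(size=(8, 2, 31))
        res = ResidualTrials(values=x, fs=30.0, lock="stimulus",
                             start_ms=-400.0,
                             conditions=np.array(["congruent_correct"] * 8),
                             recording=META)
        tc = sweep_dynamics(res)
        for wi in (0, 10, 28):
            A, _ = fit_window_ar1(res, tc.window_centers_ms[wi])
            assert np.allclose(tc.A_hat[wi], A, atol=1e-10)

    def test_estimated_moduli_increase_with_generating_coefficient(self):
        grid = [0.1, 0.3, 0.5, 0.7, 0.9]
        means = []
        for i, a in enumerate(grid):
            x = simulate_ar1_trials(np.diag([a, a]), 4000, 3, 0.4, seed=10 + i)
            res = ResidualTrials(values=x, fs=30.0, lock="stimulus",
                                 start_ms=0.0,
                                 conditions=np.array(["congruent_correct"] * 4000),
                                 recording=META)
            A, _ = fit_window_ar1(res, res.times_ms[1])
            means.append(np.mean(eig_order(A)[0]))
        assert stats.spearmanr(grid, means).statistic > 0.99999

    def test_ols_estimate_nearly_unbiased_with_pooling(self):
        A_true = np.diag([0.8, 0.4])
        acc = np.zeros((2, 2))
        n_sim = 120
        for seed in range(n_sim):
            x = simulate_ar1_trials(A_true, 2500, 3, 0.4, seed=1000 + seed)
            x0 = x[:, :, :2].transpose(1, 0, 2).reshape(2, -1)
            x1 = x[:, :, 1:].transpose(1, 0, 2).reshape(2, -1)
            acc += fit_ar1_pairs(x0, x1)
        assert np.max(np.abs(acc / n_sim - A_true)) < 0.02
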