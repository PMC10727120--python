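"""TFCE, family-wise correction, bootstrap cluster test, behavior tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eegdyn.inference import (
    LmmSpec,
    behavior_tables,
    bootstrap_cluster_test,
    correct_family,
    fit_lmm_timecourse,
    tfce_1d,
    tfce_2d,
    tfce_brute_force,
)
from eegdyn.prep import RecordingMeta


def eig_table(n_subj=30, waves=(12.0, 15.0, 18.0), n_windows=12,
              age_slope=0.0, seed=0, lock="stimulus", noise=0.05,
              subj_sd=0.05):
    """Synthetic long-format eigenvalue table with a known age slope."""
    rng = np.random.default_rng(seed)
    rows = []
    centers = np.arange(n_windows) * 33.0
    for s in range(n_subj):
        u = rng.normal(0.0, subj_sd)
        for w in waves:
            age = w + rng.normal(0.0, 0.3)
            base = 0.5 + age_slope * (age - 15.0) + u
            eigs1 = base + rng.normal(0.0, noise, n_windows)
            eigs2 = base - 0.1 + rng.normal(0.0, noise, n_windows)
            for c, e1, e2 in zip(centers, eigs1, eigs2):
                rows.append({
                    "recording_id": f"s{s}w{int(w)}", "participant": f"s{s}",
                    "age": age, "sex": "F" if s % 2 else "M", "wave": int(w),
                    "lock": lock, "window_center_ms": c, "eig1": e1,
                    "eig2": e2, "n_pairs": 96, "complex_flag": False,
                    "accuracy": 0.85, "mean_rt": 380.0, "rt_sd": 70.0,
                })
    return pd.DataFrame(rows)


class TestCorrectFamily:
    def test_six_tests_give_the_printed_level(self):
        assert correct_family(0.05, 6) == pytest.approx(0.05 / 6)
        assert f"{correct_family(0.05, 6):.4f}" == "0.0083"

    def test_eighteen_tests(self):
        a = correct_family(0.05, 18)
        assert a == pytest.approx(0.05 / 18)
        assert int(a * 1e4) / 1e4 == 0.0027  # printed truncated

    def test_single_test_identity(self):
        assert correct_family(0.05, 1) == 0.05

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            correct_family(0.05, 0)


class TestTfce:
    def test_all_zero_series_scores_zero(self):
        assert np.all(tfce_1d(np.zeros(30)) == 0.0)

    def test_negative_values_do_not_contribute(self):
        s = -np.abs(np.random.default_rng(0).normal(size=20)) - 0.1
        assert np.all(tfce_1d(s) == 0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_on_random_series(self, seed):
        s = np.random.default_rng(seed).normal(size=50)
        dh = s.max() / 100.0
        assert np.max(np.abs(tfce_1d(s, dh=dh)
                             - tfce_brute_force(s, dh=dh))) < 1e-6

    def test_isolated_peak_approaches_closed_form(self):
        h = 2.0
        s = np.zeros(15)
        s[7] = h
        target = h**3 / 3.0  # integral of h'^2 dh' with unit extent
        errs = [abs(tfce_1d(s, dh=h / n)[7] - target) for n in (50, 500, 5000)]
        assert errs[2] < errs[0]
        assert errs[2] / target < 1e-3

    def test_nonpositive_dh_rejected(self):
        with pytest.raises(ValueError):
            tfce_1d(np.ones(5), dh=0.0)

    def test_missing_values_count_as_zero_extent(self):
        s = np.array([2.0, np.nan, 2.0])
        scores = tfce_1d(s, dh=0.01)
        ref = tfce_1d(np.array([2.0, 0.0, 2.0]), dh=0.01)
        assert np.allclose(np.nan_to_num(scores), ref)

    def test_rowwise_stack_matches_1d(self):
        rng = np.random.default_rng(3)
        S = rng.normal(size=(8, 25))
        dh = 0.03
        ref = np.stack([tfce_1d(r, dh=dh) for r in S])
        assert np.allclose(tfce_2d(S, dh=dh), ref)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 5.0), min_size=3, max_size=20),
           st.integers(0, 19), st.floats(0.01, 2.0))
    def test_monotonicity_raising_a_value_never_lowers_scores(self, vals, i, incr):
        s = np.asarray(vals)
        i = i % s.size
        dh = 0.05
        before = tfce_1d(s, dh=dh)
        s2 = s.copy()
        s2[i] += incr
        after = tfce_1d(s2, dh=dh)
        assert np.all(after >= before - 1e-9)


class TestLmmSpec:
    def test_outcome_equal_predictor_rejected(self):
        with pytest.raises(ValueError):
            LmmSpec("eigenvalue", "eigenvalue", "negative", "cue")

    def test_tail_must_be_stated(self):
        with pytest.raises(ValueError):
            LmmSpec("eigenvalue", "age", "both", "cue")


class TestFitLmmTimecourse:
    def test_recovers_injected_age_slope(self):
        tb = eig_table(age_slope=-0.02, seed=1)
        out = fit_lmm_timecourse(
            tb, LmmSpec("eigenvalue", "age", "negative", "stimulus", 1))
        assert (out["t"] < -3).mean() > 0.9
        assert out["beta"].mean() == pytest.approx(-0.02, abs=0.005)

    def test_engines_agree(self):
        tb = eig_table(age_slope=-0.02, seed=2, n_windows=3)
        spec = LmmSpec("eigenvalue", "age", "negative", "stimulus", 1)
        fast = fit_lmm_timecourse(tb, spec, engine="fast")
        ref = fit_lmm_timecourse(tb, spec, engine="statsmodels")
        assert np.allclose(fast["beta"], ref["beta"], atol=1e-5)

    def test_sex_predictor_with_age_covariate(self):
        tb = eig_table(age_slope=-0.01, seed=9, n_windows=4)
        spec = LmmSpec("eigenvalue", "sex", "positive", "stimulus", 1,
                       covariates=("age",))
        out = fit_lmm_timecourse(tb, spec)
        assert np.isfinite(out["t"]).all()
        assert np.abs(out["t"]).max() < 4  # no sex effect was generated

    def test_needs_two_participants(self):
        tb = eig_table(n_subj=1)
        with pytest.raises(ValueError):
            fit_lmm_timecourse(
                tb, LmmSpec("eigenvalue", "age", "negative", "stimulus", 1))


class TestBootstrapClusterTest:
    def spec(self, tail="negative"):
        return LmmSpec("eigenvalue", "age", tail, "stimulus", 1)

    def test_detects_strong_negative_slope(self):
        tb = eig_table(age_slope=-0.02, seed=3)
        ci = bootstrap_cluster_test(tb, self.spec(), reps=200, seed=0,
                                    alpha=0.05, n_tests=6)
        assert ci.any_significant
        assert len(ci.clusters()) >= 1

    def test_wrong_tail_sees_nothing(self):
        tb = eig_table(age_slope=-0.02, seed=3)
        ci = bootstrap_cluster_test(tb, self.spec("positive"), reps=200, seed=0)
        assert not ci.any_significant
        assert np.all(ci.tfce_series == 0.0)
        assert np.all(ci.p_series == 1.0)  # add-one convention upper bound

    def test_null_table_rarely_significant(self):
        hits = 0
        for seed in range(5):
            tb = eig_table(age_slope=0.0, seed=50 + seed)
            ci = bootstrap_cluster_test(tb, self.spec(), reps=300, seed=seed,
                                        alpha=0.05, n_tests=6)
            hits += int(ci.any_significant)
        assert hits <= 1

    def test_deterministic_given_seed(self):
        tb = eig_table(age_slope=-0.01, seed=4)
        a = bootstrap_cluster_test(tb, self.spec(), reps=150, seed=42)
        b = bootstrap_cluster_test(tb, self.spec(), reps=150, seed=42)
        assert np.array_equal(a.null_max, b.null_max)
        assert np.array_equal(a.p_series, b.p_series)

    def test_permutation_alternative_runs(self):
        tb = eig_table(age_slope=-0.02, seed=5)
        ci = bootstrap_cluster_test(tb, self.spec(), reps=150, seed=1,
                                    resample="permutation")
        assert ci.any_significant

    def test_bonferroni_dominance(self):
        tb = eig_table(age_slope=-0.015, seed=6)
        un = bootstrap_cluster_test(tb, self.spec(), reps=200, seed=2,
                                    alpha=0.05, n_tests=1)
        corr = bootstrap_cluster_test(tb, self.spec(), reps=200, seed=2,
                                      alpha=0.05, n_tests=6)
        assert set(np.flatnonzero(corr.sig_mask)) <= set(np.flatnonzero(un.sig_mask))

    def test_too_few_reps_rejected(self):
        tb = eig_table(seed=7)
        with pytest.raises(ValueError):
            bootstrap_cluster_test(tb, self.spec(), reps=50)

    def test_behavior_outcome_uses_eigenvalue_predictor(self):
        tb = eig_table(seed=8)
        # couple RT to eig1 across recordings
        per_rec = tb.groupby("recording_id")["eig1"].mean()
        tb["mean_rt"] = tb["recording_id"].map(380.0 + 450.0 * per_rec)
        spec = LmmSpec("rt", "eigenvalue", "positive", "stimulus", 1)
        ci = bootstrap_cluster_test(tb, spec, reps=200, seed=3)
        assert ci.any_significant


class TestBehaviorTables:
    def test_all_correct_trials_give_accuracy_one(self, epochs_factory):
        ep = epochs_factory(np.zeros((6, 1, 10)),
                            conditions=["congruent_correct"] * 6)
        tab = behavior_tables([ep])
        assert tab.loc[0, "accuracy"] == 1.0

    def test_identical_rts_give_zero_sd(self, epochs_factory):
        ep = epochs_factory(np.zeros((5, 1, 10)), rts=[300.0] * 5)
        tab = behavior_tables([ep])
        assert tab.loc[0, "rt_sd"] == 0.0

    def test_congruency_split_present(self, epochs_factory):
        conds = ["congruent_correct"] * 3 + ["incongruent_error"] * 3
        ep = epochs_factory(np.zeros((6, 1, 10)), conditions=conds)
        tab = behavior_tables([ep])
        assert tab.loc[0, "accuracy_congruent"] == 1.0
        assert tab.loc[0, "accuracy_incongruent"] == 0.0

    def test_age_trend_in_simulated_accuracy_detected(self):
        from eegdyn.lmm import fit_random_intercept
        from eegdyn.synth import CohortConfig, GroundTruthDynamics, simulate_cohort

        cfg = CohortConfig(n_subjects=40, n_trials=120, n_sensors=4,
                           fs_raw=30.0, missingness=0.1, seed=3)
        sessions = simulate_cohort(cfg, GroundTruthDynamics())
        tab = behavior_tables(sessions)
        X = np.column_stack([np.ones(len(tab)), tab["age"].to_numpy()])
        fit = fit_random_intercept(tab["accuracy"].to_numpy(), X,
                                   tab["participant"].to_numpy())
        assert fit.params[1] > 0
        assert fit.tvalues[1] > 3
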