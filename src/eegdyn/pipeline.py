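"""End-to-end runs: configuration, stage chaining, artifacts, and the two
canonical experiments (synthetic-cohort recovery; latency-jitter control).

Every stage parameter defaults to the analysis's canonical value (15 Hz
lowpass, 30 Hz analysis rate, the three lock windows, 100-ms AR window,
50-trial inclusion, 10,000 bootstrap reps, alpha 0.05 over 6 age tests),
and every artifact is regenerable from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import DynamicsTimecourse, compute_residuals, sweep_dynamics
from .inference import ClusterInference, LmmSpec, behavior_tables, bootstrap_cluster_test
from .latent import (
    ComponentSpace,
    LatentTrials,
    fit_component_space,
    grand_average_erps,
    project_and_zscore,
    zscore_latent_session,
)
from .prep import (
    LOCKS,
    EpochedDataset,
    LockWindows,
    apply_inclusion_rule,
    lowpass_and_downsample,
    segment,
)
from .synth import (
    ANALYSIS_FS,
    CohortConfig,
    GroundTruthDynamics,
    JitterConfig,
    cohort_plan,
    latent_templates,
    make_jittered_dataset,
)

logger = logging.getLogger(__name__)


def default_age_tests(locks=LOCKS) -> tuple[LmmSpec, ...]:
    """The six canonical age tests: 2 eigenvalues x 3 locks, negative tail."""
    return tuple(
        LmmSpec(outcome="eigenvalue", fixed_predictor="age", tail="negative",
                lock=lock, eig_index=eig)
        for eig in (1, 2) for lock in locks
    )


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    truth: GroundTruthDynamics = field(default_factory=GroundTruthDynamics)
    locks: tuple[str, ...] = LOCKS
    lock_windows: LockWindows = field(default_factory=LockWindows)
    cutoff_hz: float | None = 15.0
    target_fs: float = ANALYSIS_FS
    min_trials: int = 50
    pca_locks: tuple[str, ...] = ("stimulus", "response")
    window_ms: float = 100.0
    step_samples: int = 1
    min_pairs: int = 4
    tests: tuple[LmmSpec, ...] | None = None  # None -> the six age tests
    reps: int = 10_000
    alpha: float = 0.05
    n_tests: int = 6
    resample: str = "participant"  # or "bootstrap" / "permutation"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.locks:
            raise ValueError("at least one lock window must be configured")
        unknown = set(self.locks) - set(LOCKS)
        if unknown:
            raise ValueError(f"unknown locks {sorted(unknown)}")
        if any(l not in self.locks for l in self.pca_locks):
            raise ValueError("pca_locks must be a subset of locks")

    def resolved_tests(self) -> tuple[LmmSpec, ...]:
        return self.tests if self.tests is not None else default_age_tests(self.locks)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["truth"].pop("A_override", None)
        if self.truth.sensor_loadings is not None:
            d["truth"]["sensor_loadings"] = np.asarray(
                self.truth.sensor_loadings).tolist()
        d["tests"] = (None if self.tests is None
                      else [dataclasses.asdict(t) for t in self.tests])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        from .synth import Bump

        d = dict(d)
        cohort = CohortConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                 for k, v in d.pop("cohort").items()})
        tr = dict(d.pop("truth"))
        tr.pop("A_override", None)
        if tr.get("sensor_loadings") is not None:
            tr["sensor_loadings"] = np.asarray(tr["sensor_loadings"])
        if "bumps" in tr:
            tr["bumps"] = tuple(
                b if isinstance(b, Bump) else Bump(
                    anchor=b["anchor"], latency_ms=b["latency_ms"],
                    width_ms=b["width_ms"], amplitude=tuple(b["amplitude"]),
                    condition_scale=dict(b.get("condition_scale", {})),
                ) for b in tr["bumps"])
        for key in ("eig_by_epoch", "age_slope_by_epoch"):
            if key in tr:
                tr[key] = {k: tuple(v) for k, v in tr[key].items()}
        for key in ("rt_eig_ref", "acc_age_slopes"):
            if key in tr:
                tr[key] = tuple(tr[key])
        truth = GroundTruthDynamics(**tr)
        lw = d.pop("lock_windows")
        lock_windows = (lw if isinstance(lw, LockWindows)
                        else LockWindows(**{k: tuple(v) for k, v in lw.items()}))
        tests = d.pop("tests", None)
        if tests is not None:
            tests = tuple(t if isinstance(t, LmmSpec) else LmmSpec(
                **{k: (tuple(v) if k == "covariates" else v) for k, v in t.items()})
                for t in tests)
        for key in ("locks", "pca_locks"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(cohort=cohort, truth=truth, lock_windows=lock_windows,
                   tests=tests, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def test_key(spec: LmmSpec) -> str:
    return f"{spec.outcome}~{spec.fixed_predictor}|eig{spec.eig_index}|{spec.lock}"


@dataclass
class PipelineResult:
    """In-memory artifacts of one end-to-end run."""

    config: RunConfig
    space: ComponentSpace
    eig_table: pd.DataFrame
    behavior: pd.DataFrame
    inferences: dict[str, ClusterInference]
    n_sessions: int
    exclusions: dict[str, int]

    def significant(self, lock: str, eig_index: int | None = None) -> bool:
        """Any significant cluster among the tests on this lock."""
        hits = [
            inf.any_significant for key, inf in self.inferences.items()
            if inf.spec.lock == lock
            and (eig_index is None or inf.spec.eig_index == eig_index)
        ]
        return any(hits)


def _prep_sessions(
    sessions: list[EpochedDataset],
    config: RunConfig,
) -> dict[str, list[EpochedDataset]]:
    by_lock: dict[str, list[EpochedDataset]] = {l: [] for l in config.locks}
    for ds in sessions:
        if config.cutoff_hz is not None or ds.fs != config.target_fs:
            ds = lowpass_and_downsample(ds, cutoff=config.cutoff_hz,
                                        target_fs=config.target_fs)
        for lock in config.locks:
            try:
                by_lock[lock].append(segment(ds, lock, config.lock_windows))
            except ValueError as err:
                logger.warning("recording %s, %s lock: %s",
                               ds.recording.recording_id, lock, err)
    return by_lock


def build_eigenvalue_table(
    latents: list[dict[str, LatentTrials]],
    window_ms: float = 100.0,
    step_samples: int = 1,
    min_pairs: int = 4,
    return_timecourses: bool = False,
):
    """Residuals -> windowed AR(1) sweep -> tidy long table, per recording.

    With ``return_timecourses`` the full :class:`DynamicsTimecourse`
    objects (including the A-matrix tensors) are returned alongside.
    """
    frames = []
    tcs: list[DynamicsTimecourse] = []
    for by_lock in latents:
        for lt in by_lock.values():
            resid = compute_residuals(lt)
            tc = sweep_dynamics(resid, width_ms=window_ms,
                                step_samples=step_samples, min_pairs=min_pairs)
            frames.append(tc.to_frame())
            tcs.append(tc)
    if not frames:
        raise ValueError("no recordings produced dynamics time courses")
    table = pd.concat(frames, ignore_index=True)
    return (table, tcs) if return_timecourses else table


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """simulate -> prep -> latent space -> dynamics -> inference.

    Deterministic given ``config.seed``: the cohort and the bootstrap draws
    derive from independent substreams of the one seed.
    """
    master = np.random.SeedSequence(config.seed)
    s_cohort, s_boot = master.spawn(2)
    cohort_cfg = replace(config.cohort,
                         seed=int(s_cohort.generate_state(1)[0] % (2**31)))
    config.truth.validate()
    from .synth import simulate_cohort

    sessions = simulate_cohort(cohort_cfg, config.truth)
    behavior = behavior_tables(sessions)
    by_lock = _prep_sessions(sessions, config)
    n_before = {l: len(v) for l, v in by_lock.items()}
    by_lock = apply_inclusion_rule(by_lock, min_trials=config.min_trials)
    exclusions = {l: n_before[l] - len(by_lock[l]) for l in by_lock}

    ga_arrays = []
    for lock in config.pca_locks:
        ga = grand_average_erps(by_lock[lock])
        ga_arrays.extend(ga[c] for c in sorted(ga))
    space = fit_component_space(
        ga_arrays, provenance={"locks": list(config.pca_locks)})

    # group each recording's included locks for session-pooled z-scoring
    per_recording: dict[str, dict[str, EpochedDataset]] = {}
    for lock, group in by_lock.items():
        for ds in group:
            per_recording.setdefault(ds.recording.recording_id, {})[lock] = ds
    latents = [project_and_zscore(locks_map, space)
               for locks_map in per_recording.values()]

    table = build_eigenvalue_table(latents, window_ms=config.window_ms,
                                   step_samples=config.step_samples,
                                   min_pairs=config.min_pairs)
    table = table.merge(
        behavior.drop(columns=["participant", "age", "sex", "wave"]),
        on="recording_id", how="left")

    inferences: dict[str, ClusterInference] = {}
    specs = config.resolved_tests()
    test_seeds = s_boot.spawn(len(specs))
    for spec, sseq in zip(specs, test_seeds):
        inferences[test_key(spec)] = bootstrap_cluster_test(
            table, spec, reps=config.reps, seed=np.random.default_rng(sseq),
            alpha=config.alpha, n_tests=config.n_tests,
            resample=config.resample)

    result = PipelineResult(
        config=config, space=space, eig_table=table, behavior=behavior,
        inferences=inferences, n_sessions=len(sessions), exclusions=exclusions)
    if out_dir is not None:
        write_artifacts(result, Path(out_dir))
    return result


def write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    """CSV/JSON artifacts plus a manifest with parameters and stage hashes."""
    out_dir.mkdir(parents=True, exist_ok=True)
    eig_csv = result.eig_table.to_csv(index=False)
    beh_csv = result.behavior.to_csv(index=False)
    (out_dir / "eigenvalue_timecourses.csv").write_text(eig_csv)
    (out_dir / "behavior.csv").write_text(beh_csv)
    inf = {
        key: {
            "window_centers_ms": ci.window_centers_ms.tolist(),
            "t": ci.t_series.tolist(),
            "tfce": ci.tfce_series.tolist(),
            "p": ci.p_series.tolist(),
            "significant": ci.sig_mask.tolist(),
            "clusters_ms": ci.clusters(),
            "alpha_corrected": ci.alpha_corrected,
            "reps": ci.reps,
            "null_quantiles": {
                q: float(np.quantile(ci.null_max, float(q)))
                for q in ("0.5", "0.95", "0.99")},
        }
        for key, ci in result.inferences.items()
    }
    inf_json = json.dumps(inf, indent=1)
    (out_dir / "inference.json").write_text(inf_json)
    manifest = {
        "eegdyn_version": __version__,
        "python": platform.python_version(),
        "seed": result.config.seed,
        "config": result.config.to_dict(),
        "n_sessions": result.n_sessions,
        "exclusions": result.exclusions,
        "hashes": {
            "eigenvalue_timecourses.csv": hashlib.sha256(eig_csv.encode()).hexdigest(),
            "behavior.csv": hashlib.sha256(beh_csv.encode()).hexdigest(),
            "inference.json": hashlib.sha256(inf_json.encode()).hexdigest(),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def canonical_lock_erps(
    config: RunConfig,
    age: float | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-lock, per-condition mean latent ERPs from the generating templates,
    evaluated with canonical event timing (median cue->stimulus delay, mean RT)."""
    from .prep import CONDITIONS, window_n_samples

    delay = 450.0
    rt = 380.0 if age is None else 380.0 - 8.0 * (age - 15.0)
    anchor = {"cue": 0.0, "stimulus": delay, "response": delay + rt}
    out: dict[str, dict[str, np.ndarray]] = {}
    for lock in config.locks:
        start, end = config.lock_windows.window(lock)
        n = window_n_samples(start, end, config.target_fs)
        times = anchor[lock] + start + np.arange(n) * 1000.0 / config.target_fs
        erps = {}
        for cond in CONDITIONS:
            tmpl = latent_templates(
                times, np.array([cond]), np.array([delay]),
                np.array([delay + rt]), config.truth.bumps)
            erps[cond] = tmpl[0]
        out[lock] = erps
    return out


@dataclass
class JitterControlResult:
    """Age-test statistics on jitter-only datasets."""

    config: RunConfig
    jitter: JitterConfig
    eig_table: pd.DataFrame
    inferences: dict[str, ClusterInference]

    def significant(self, lock: str) -> bool:
        return any(inf.any_significant for inf in self.inferences.values()
                   if inf.spec.lock == lock)

    @property
    def any_significant(self) -> bool:
        return any(inf.any_significant for inf in self.inferences.values())


def run_jitter_control(
    config: RunConfig,
    jitter: JitterConfig | None = None,
    erps: dict[str, dict[str, np.ndarray]] | None = None,
) -> JitterControlResult:
    """The latency-jitter control analysis.

    Builds a cohort matched in subjects and trials to ``config.cohort``
    where every trial is a condition-mean ERP shifted by a per-trial
    Gaussian latency (SD set per age group) plus i.i.d. noise — no true
    dynamics — then pushes it through the identical z-scoring, residual,
    AR(1), and cluster-inference stages.

    By default each session's trials are built from that session's own
    empirical condition-mean latent ERPs, measured on a matched reference
    cohort simulated from ``config``, and the additive noise SD is set to
    the average residual SD of that reference data.  Passing ``erps``
    (per-lock, per-condition arrays) instead uses one shared ERP set for
    every session.
    """
    jitter = jitter or JitterConfig()
    eff_eps = jitter.eps_sd
    if (jitter.eps_sd == 0
            and all(s == 0 for s in jitter.sigma_by_age.values())):
        raise ValueError(
            "zero jitter and zero noise give identically-zero residuals; "
            "the AR(1) fit would be degenerate")

    master = np.random.SeedSequence(config.seed)
    s_cohort, s_jit, s_boot = master.spawn(3)
    cohort_cfg = replace(config.cohort,
                         seed=int(s_cohort.generate_state(1)[0] % (2**31)))

    latents: list[dict[str, LatentTrials]] = []
    if erps is not None:
        # shared-ERP path: every session jitters the same mean waveforms
        if all(np.allclose(e, 0) for lock_erps in erps.values()
               for e in lock_erps.values()):
            raise ValueError("all mean ERPs are zero; nothing to jitter")
        if eff_eps is None:
            jitter = replace(jitter, eps_sd=0.5)
        for p, sseq in zip(cohort_plan(cohort_cfg),
                           s_jit.spawn(len(cohort_plan(cohort_cfg)))):
            rng = np.random.default_rng(sseq)
            by_lock = {}
            for lock in config.locks:
                start, _ = config.lock_windows.window(lock)
                by_lock[lock] = make_jittered_dataset(
                    erps[lock], jitter, cohort_cfg.n_trials,
                    float(p.meta.wave), seed=rng, fs=config.target_fs,
                    start_ms=start, lock=lock, recording=p.meta)
            latents.append(zscore_latent_session(by_lock))
    else:
        # Reference cohort through the standard front end.  The jittered
        # trials are built once per trial on the whole-trial timeline
        # (each trial = the session's condition-mean latent ERP evaluated
        # at t + tau, plus i.i.d. noise) and then segmented per lock by
        # the identical machinery — so event-locked features of the
        # jittered data carry exactly the smearing the condition mean has.
        from .latent import project
        from .synth import simulate_cohort

        config.truth.validate()
        sessions = simulate_cohort(cohort_cfg, config.truth)
        by_lock_all = _prep_sessions(sessions, config)
        by_lock_all = apply_inclusion_rule(by_lock_all,
                                           min_trials=config.min_trials)
        ga_arrays = []
        for lock in config.pca_locks:
            ga = grand_average_erps(by_lock_all[lock])
            ga_arrays.extend(ga[c] for c in sorted(ga))
        space = fit_component_space(ga_arrays)

        # full-trial latents (z-scored per session) and condition means
        ref = []
        sds = []
        for ds in sessions:
            if config.cutoff_hz is not None or ds.fs != config.target_fs:
                ds = lowpass_and_downsample(ds, cutoff=config.cutoff_hz,
                                            target_fs=config.target_fs)
            lat = project(ds, space)
            mean = lat.transpose(1, 0, 2).reshape(2, -1).mean(axis=1)
            sd = lat.transpose(1, 0, 2).reshape(2, -1).std(axis=1)
            z = (lat - mean[None, :, None]) / sd[None, :, None]
            conds = ds.trials["condition"].to_numpy()
            erps = {c: z[conds == c].mean(axis=0) for c in np.unique(conds)}
            resid = z - np.stack([erps[c] for c in conds])
            sds.append(float(resid.std()))
            ref.append((ds, z, erps))
        if eff_eps is None:
            eff_eps = float(np.mean(sds))
        jitter = replace(jitter, eps_sd=eff_eps)

        session_seeds = s_jit.spawn(len(ref))
        for (ds, z, erps), sseq in zip(ref, session_seeds):
            rng = np.random.default_rng(sseq)
            conds = ds.trials["condition"].to_numpy()
            sigma = jitter.sigma(float(ds.recording.wave))
            taus = rng.normal(0.0, sigma, ds.n_trials)
            times = ds.times_ms
            vals = np.empty((ds.n_trials, 2, times.size))
            for i, (cond, tau) in enumerate(zip(conds, taus)):
                erp = erps[cond]
                for k in range(2):
                    vals[i, k] = np.interp(times + tau, times, erp[k],
                                           left=erp[k, 0], right=erp[k, -1])
            vals += rng.normal(0.0, jitter.eps_sd, vals.shape)
            full = EpochedDataset(
                data=vals, fs=ds.fs, lock="trial", start_ms=ds.start_ms,
                trials=ds.trials.copy(), recording=ds.recording)
            by_lock_j = {}
            for lock in config.locks:
                try:
                    seg = segment(full, lock, config.lock_windows)
                except ValueError:
                    continue
                by_lock_j[lock] = LatentTrials(
                    values=seg.data, fs=seg.fs, lock=lock,
                    start_ms=seg.start_ms,
                    conditions=seg.trials["condition"].to_numpy(),
                    recording=seg.recording, trials=seg.trials)
            if by_lock_j:
                latents.append(zscore_latent_session(by_lock_j))

    table = build_eigenvalue_table(latents, window_ms=config.window_ms,
                                   step_samples=config.step_samples,
                                   min_pairs=config.min_pairs)
    inferences: dict[str, ClusterInference] = {}
    specs = config.resolved_tests()
    test_seeds = s_boot.spawn(len(specs))
    for spec, sseq in zip(specs, test_seeds):
        inferences[test_key(spec)] = bootstrap_cluster_test(
            table, spec, reps=config.reps, seed=np.random.default_rng(sseq),
            alpha=config.alpha, n_tests=config.n_tests,
            resample=config.resample)
    return JitterControlResult(config=config, jitter=jitter,
                               eig_table=table, inferences=inferences)
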