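"""Synthetic longitudinal EEG cohorts with known ground-truth dynamics.

The generator emulates the structure of a three-wave adolescent flanker
study: subjects recorded at target ages 12/15/18 with per-wave missingness,
~hundreds of trials per session in four conditions (congruency x
correctness), trial-level reaction times, a rank-2 latent spatial
structure, and residual fluctuations that evolve by a time-varying 2x2
AR(1) law whose eigenvalues can decrease with age in chosen task epochs.
Because the truth is known, every downstream stage (projection, residuals,
window fits, cluster inference) is testable without external data.

It also builds the latency-jitter control: single trials that are pure
time-shifted copies of the condition-mean ERP plus i.i.d. noise, used to
ask whether trial-timing variability alone can mimic dynamics effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .latent import LatentTrials
from .prep import (
    CONDITIONS,
    EpochedDataset,
    LockWindows,
    RecordingMeta,
    window_n_samples,
)

ANALYSIS_FS = 30.0  # Hz; grid on which the AR(1) truth is defined

_EPOCHS = ("cue", "stimulus", "response", "baseline")


@dataclass(frozen=True)
class Bump:
    """One Gaussian-windowed ERP deflection anchored to a task event."""

    anchor: str  # 'cue' | 'stimulus' | 'response'
    latency_ms: float
    width_ms: float
    amplitude: tuple[float, float]  # per latent component
    condition_scale: Mapping[str, float] = field(default_factory=dict)

    def scale(self, condition: str) -> float:
        return float(self.condition_scale.get(condition, 1.0))


#: morphology: an early visual deflection on component 1, a congruency-
#: sensitive later wave, and an error-sensitive post-response wave on
#: component 2 (exact shapes are configuration, not science).  Amplitudes
#: put the evoked response at roughly 5-10% of single-trial variance:
#: single-trial EEG is noise-dominated and ERPs only emerge by averaging.
DEFAULT_BUMPS: tuple[Bump, ...] = (
    Bump("cue", 150.0, 80.0, (0.21, 0.06)),
    Bump("stimulus", 100.0, 50.0, (-0.42, 0.10)),
    Bump("stimulus", 300.0, 90.0, (0.17, 0.25),
         {"incongruent_correct": 1.25, "incongruent_error": 1.25}),
    Bump("response", 60.0, 100.0, (0.08, 0.21),
         {"congruent_error": 2.0, "incongruent_error": 2.0}),
    Bump("response", 300.0, 150.0, (0.04, 0.34),
         {"congruent_error": 1.8, "incongruent_error": 1.8,
          "congruent_correct": 0.6, "incongruent_correct": 0.6}),
)


@dataclass
class CohortConfig:
    """Study-design parameters of the simulated cohort."""

    n_subjects: int = 179
    waves: tuple[float, ...] = (12.0, 15.0, 18.0)
    missingness: float = 0.38  # probability a subject skips a wave
    n_trials: int = 384
    n_sensors: int = 104
    fs_raw: float = 250.0
    condition_probs: tuple[float, float, float, float] | None = None
    seed: int = 0
    sensor_noise_sd: float = 0.2
    omission_prob: float = 0.02  # trials without a button press
    epoch_start_ms: float = -700.0
    epoch_end_ms: float = 2100.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")
        if self.condition_probs is not None:
            p = np.asarray(self.condition_probs, dtype=float)
            if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("condition_probs must be 4 probabilities summing to 1")


def default_sensor_loadings(n_sensors: int) -> np.ndarray:
    """Rank-2 smooth topographies: an anterior-posterior gradient and a
    centrally focal pattern, orthonormalized."""
    i = np.arange(n_sensors)
    u1 = np.cos(np.pi * i / max(n_sensors - 1, 1))
    u2 = np.exp(-(((i - (n_sensors - 1) / 2.0) / (n_sensors / 5.0)) ** 2))
    q, _ = np.linalg.qr(np.column_stack([u1, u2]))
    for k in range(2):
        if q[np.argmax(np.abs(q[:, k])), k] < 0:
            q[:, k] = -q[:, k]
    return q


@dataclass
class GroundTruthDynamics:
    """Generating model: AR(1) law, spatial mixing, ERP templates, couplings.

    Eigenvalues of the dynamics matrix are parameterized per task epoch as
    ``eig(age) = eig_ref + slope * (age - reference_age)`` (decay factor
    per 30-Hz sample).  By default the age gradient acts only in the
    stimulus- and response-locked epochs and is flat around the cue.
    """

    eig_by_epoch: dict = field(default_factory=lambda: {
        "cue": (0.60, 0.50), "stimulus": (0.60, 0.50),
        "response": (0.60, 0.50), "baseline": (0.55, 0.45)})
    age_slope_by_epoch: dict = field(default_factory=lambda: {
        "cue": (0.0, 0.0), "stimulus": (-0.025, -0.025),
        "response": (-0.025, -0.025), "baseline": (0.0, 0.0)})
    reference_age: float = 15.0
    rotation_deg: float = 0.0  # latent coordinates of the AR law vs PC axes
    sensor_loadings: np.ndarray | None = None
    bumps: tuple[Bump, ...] = DEFAULT_BUMPS
    noise_sd: float = 0.4  # innovation SD of eps(t); z-scored latent SD ~ 1
    rt_coupling: float = 0.233  # standardized slope eigenvalue -> mean RT
    rt_resid_sd: float = 0.90  # session-level RT noise, z-units
    acc_coupling: float = 0.3  # accuracy decrease per unit eigenvalue
    rt_eig_ref: tuple[float, float] = (0.5, 0.1)  # eig mean/SD for z-scaling
    rt_age_slope: float = -8.0  # trial RT change, ms per year of age
    acc_age_slopes: tuple[float, float] = (0.008, 0.015)  # per congruency, /year
    subject_amp_cv: float = 0.3  # between-subject lognormal CV of ERP amplitude
    #: within-subject, between-session amplitude variability (state, cap
    #: placement, impedance); ERP test-retest reliability is well below 1
    session_amp_cv: float = 0.25
    #: between-subject and between-session spread of ERP component latency
    #: (ms); individual peak latencies differ by tens of milliseconds
    subject_latency_sd: float = 40.0
    session_latency_sd: float = 15.0
    A_override: Callable[[str, float], np.ndarray] | None = None

    def eigs_at(self, epoch: str, age: float) -> np.ndarray:
        base = np.asarray(self.eig_by_epoch[epoch], dtype=float)
        slope = np.asarray(self.age_slope_by_epoch.get(epoch, (0.0, 0.0)), dtype=float)
        return base + slope * (age - self.reference_age)

    def A_of_t(self, epoch: str, age: float) -> np.ndarray:
        """Dynamics matrix in latent coordinates for one epoch and age."""
        if self.A_override is not None:
            return np.asarray(self.A_override(epoch, age), dtype=float)
        lam = np.diag(self.eigs_at(epoch, age))
        if self.rotation_deg:
            th = np.deg2rad(self.rotation_deg)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            return R @ lam @ R.T
        return lam

    def loadings(self, n_sensors: int) -> np.ndarray:
        L = (self.sensor_loadings if self.sensor_loadings is not None
             else default_sensor_loadings(n_sensors))
        L = np.asarray(L, dtype=float)
        if L.shape != (n_sensors, 2):
            raise ValueError("sensor_loadings must be (n_sensors, 2)")
        if np.linalg.matrix_rank(L) < 2:
            raise ValueError("sensor_loadings must have rank 2")
        return L

    def validate(self, ages: Sequence[float] = (10.0, 12.0, 15.0, 18.0, 20.0)) -> None:
        for epoch in _EPOCHS:
            for age in ages:
                A = self.A_of_t(epoch, age)
                rho = np.max(np.abs(np.linalg.eigvals(A)))
                if rho >= 1.0:
                    raise ValueError(
                        f"unstable dynamics: spectral radius {rho:.3f} >= 1 "
                        f"for epoch {epoch!r} at age {age}"
                    )


@dataclass(frozen=True)
class JitterConfig:
    """Latency-jitter control: per-age-group SD of the trialwise shift."""

    sigma_by_age: Mapping[float, float] = field(
        default_factory=lambda: {12.0: 97.0, 15.0: 76.0, 18.0: 72.0})
    #: SD of the additive i.i.d. noise, in latent units; None means "match
    #: the average residual SD of the reference data", the default recipe
    eps_sd: float | None = None

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigma_by_age.values()):
            raise ValueError("jitter sigmas must be >= 0")
        if self.eps_sd is not None and self.eps_sd < 0:
            raise ValueError("eps_sd must be >= 0")

    def sigma(self, age: float) -> float:
        if age not in self.sigma_by_age:
            raise KeyError(f"age {age} not in the sigma_by_age map")
        return float(self.sigma_by_age[age])


#: trial-time spans (ms relative to the event) in which each processing
#: epoch's dynamics law applies.  Stimulus-epoch dynamics engage 200 ms
#: after stimulus onset (decision-stage processing rather than the sensory
#: transient), which keeps the cue-locked analysis windows governed by the
#: age-flat cue law even though they extend past stimulus onset on
#: short-delay trials (cue windows end 500 ms post-cue; the cue-stimulus
#: delay is at least 300 ms).
DYN_EPOCH_SPANS = {"stimulus": (250.0, 850.0), "response": (0.0, 500.0)}


def epoch_of(t_ms: float, stim_ms: float, resp_ms: float) -> str:
    """Processing epoch governing the dynamics at trial time ``t_ms``.

    Epochs follow processing time, not the analysis lock windows; the
    response span takes precedence over the stimulus span.  Everything
    before the stimulus span belongs to the cue epoch, late post-response
    time to the baseline.
    """
    lo, hi = DYN_EPOCH_SPANS["response"]
    if np.isfinite(resp_ms) and resp_ms + lo <= t_ms <= resp_ms + hi:
        return "response"
    lo, hi = DYN_EPOCH_SPANS["stimulus"]
    if stim_ms + lo <= t_ms <= stim_ms + hi:
        return "stimulus"
    if t_ms < stim_ms + lo:
        return "cue"
    return "baseline"


def latent_templates(
    times_ms: np.ndarray,
    conditions: np.ndarray,
    stim_ms: np.ndarray,
    resp_ms: np.ndarray,
    bumps: Sequence[Bump] = DEFAULT_BUMPS,
    latency_shift_ms: float = 0.0,
) -> np.ndarray:
    """Noise-free latent ERPs, (n_trials, 2, n_times).

    ``latency_shift_ms`` displaces every deflection by a common amount,
    modeling a subject's overall component timing.
    """
    n = len(conditions)
    out = np.zeros((n, 2, times_ms.size))
    anchors = {"cue": np.zeros(n), "stimulus": np.asarray(stim_ms, dtype=float),
               "response": np.asarray(resp_ms, dtype=float)}
    for bump in bumps:
        center = anchors[bump.anchor] + bump.latency_ms + latency_shift_ms  # (n,)
        valid = np.isfinite(center)
        if not valid.any():
            continue
        prof = np.zeros((n, times_ms.size))
        prof[valid] = np.exp(
            -0.5 * ((times_ms[None, :] - center[valid, None]) / bump.width_ms) ** 2
        )
        scales = np.array([bump.scale(c) for c in conditions])
        for k in range(2):
            out[:, k, :] += bump.amplitude[k] * scales[:, None] * prof
    return out


def _simulate_residuals(
    rng: np.random.Generator,
    truth: GroundTruthDynamics,
    age: float,
    times_ms: np.ndarray,
    stim_ms: np.ndarray,
    resp_ms: np.ndarray,
) -> np.ndarray:
    """AR(1) residual trajectories on the analysis grid, (n_trials, 2, T)."""
    n, T = stim_ms.size, times_ms.size
    A_by_epoch = {e: truth.A_of_t(e, age) for e in _EPOCHS}
    x = np.zeros((n, 2, T))
    if truth.noise_sd > 0:
        # start from the (diagonal-approximation) stationary spread
        lam0 = np.clip(np.abs(np.diag(A_by_epoch["baseline"])), 0.0, 0.999)
        sd0 = truth.noise_sd / np.sqrt(1.0 - lam0**2)
        x[:, :, 0] = rng.normal(0.0, 1.0, (n, 2)) * sd0[None, :]

    # epoch label codes per (trial, time): processing epochs, later events
    # taking precedence (see epoch_of)
    t = times_ms[None, :]
    s = stim_ms[:, None]
    codes = np.full((n, T), 3, dtype=np.int8)  # 3 = baseline
    lo, hi = DYN_EPOCH_SPANS["stimulus"]
    codes[np.broadcast_to(t, (n, T)) < s + lo] = 0  # cue: pre-stimulus-span
    codes[(t >= s + lo) & (t <= s + hi)] = 1
    lo, hi = DYN_EPOCH_SPANS["response"]
    r = np.where(np.isfinite(resp_ms), resp_ms, np.inf)[:, None]
    codes[(t >= r + lo) & (t <= r + hi)] = 2
    order = ("cue", "stimulus", "response", "baseline")

    eps = rng.normal(0.0, truth.noise_sd, (n, 2, T - 1)) if truth.noise_sd > 0 else None
    for ti in range(T - 1):
        step = codes[:, ti]
        nxt = np.empty((n, 2))
        for ci, e in enumerate(order):
            m = step == ci
            if m.any():
                nxt[m] = x[m, :, ti] @ A_by_epoch[e].T
        if eps is not None:
            nxt += eps[:, :, ti]
        x[:, :, ti + 1] = nxt
    return x


def simulate_session(
    config: CohortConfig,
    truth: GroundTruthDynamics,
    meta: RecordingMeta,
    rng: np.random.Generator,
    subject_rt_shift_ms: float = 0.0,
    subject_amp_z: tuple[float, float] = (0.0, 0.0),
    subject_latency_z: float = 0.0,
) -> EpochedDataset:
    """One recording session: cue-anchored trial epochs in sensor space.

    Sensor signal = loadings @ (template + AR residual) + sensor noise.
    The AR residual evolves on the 30 Hz analysis grid on which the truth
    is defined; when ``fs_raw`` differs, the smooth templates are evaluated
    on the raw grid directly and the residual is linearly interpolated.
    """
    n = config.n_trials
    age = meta.age

    delay = rng.uniform(300.0, 600.0, n)  # cue -> stimulus
    if config.condition_probs is not None:
        conditions = rng.choice(CONDITIONS, size=n, p=config.condition_probs)
    else:
        congruent = rng.random(n) < 0.5
        acc = np.where(
            congruent,
            np.clip(0.97 + truth.acc_age_slopes[0] * (age - 15.0), 0.5, 0.999),
            np.clip(0.77 + truth.acc_age_slopes[1] * (age - 15.0), 0.5, 0.999),
        )
        correct = rng.random(n) < acc
        conditions = np.array([
            f"{'congruent' if c else 'incongruent'}_{'correct' if k else 'error'}"
            for c, k in zip(congruent, correct)
        ])
    responded = rng.random(n) >= config.omission_prob
    base_rt = np.where(np.char.startswith(conditions.astype(str), "congruent"),
                       354.0, 404.0)
    rt = (base_rt + truth.rt_age_slope * (age - 15.0)
          + subject_rt_shift_ms + rng.normal(0.0, 70.0, n))
    rt = np.clip(rt, 250.0, 900.0)  # sub-250-ms flanker responses are anticipatory
    rt[~responded] = np.nan
    stim_ms = delay
    resp_ms = stim_ms + rt

    n30 = window_n_samples(config.epoch_start_ms, config.epoch_end_ms, ANALYSIS_FS)
    grid30 = config.epoch_start_ms + np.arange(n30) * 1000.0 / ANALYSIS_FS
    resid30 = _simulate_residuals(rng, truth, age, grid30, stim_ms, resp_ms)

    amp = np.exp(truth.subject_amp_cv * np.asarray(subject_amp_z, dtype=float)
                 + truth.session_amp_cv * rng.normal(0.0, 1.0, 2))
    lat_shift = (truth.subject_latency_sd * subject_latency_z
                 + truth.session_latency_sd * rng.normal())
    if config.fs_raw == ANALYSIS_FS:
        times = grid30
        latent = latent_templates(times, conditions, stim_ms, resp_ms,
                                  truth.bumps, latency_shift_ms=lat_shift)
        latent *= amp[None, :, None]
        latent += resid30
    else:
        n_raw = window_n_samples(config.epoch_start_ms, config.epoch_end_ms,
                                 config.fs_raw)
        times = config.epoch_start_ms + np.arange(n_raw) * 1000.0 / config.fs_raw
        latent = latent_templates(times, conditions, stim_ms, resp_ms,
                                  truth.bumps, latency_shift_ms=lat_shift)
        latent *= amp[None, :, None]
        # linear interpolation of the residual onto the raw grid
        pos = np.clip((times - grid30[0]) / (1000.0 / ANALYSIS_FS), 0, n30 - 1)
        i0 = np.minimum(pos.astype(int), n30 - 2)
        frac = pos - i0
        latent += (resid30[:, :, i0] * (1.0 - frac)[None, None, :]
                   + resid30[:, :, i0 + 1] * frac[None, None, :])

    L = truth.loadings(config.n_sensors)
    data = np.einsum("sk,nkt->nst", L, latent)
    if config.sensor_noise_sd > 0:
        data = data + rng.normal(0.0, config.sensor_noise_sd, data.shape)

    trials = pd.DataFrame({
        "condition": conditions,
        "rt_ms": rt,
        "responded": responded,
        "cue_ms": 0.0,
        "stimulus_ms": stim_ms,
        "response_ms": resp_ms,
    })
    return EpochedDataset(
        data=data.astype(np.float32),
        fs=config.fs_raw,
        lock="trial",
        start_ms=config.epoch_start_ms,
        trials=trials,
        recording=meta,
    )


@dataclass
class SessionPlan:
    """Demographics and random substream of one planned recording session."""

    meta: RecordingMeta
    rt_shift_ms: float
    amp_z: tuple[float, float]  # subject's latent ERP-amplitude z scores
    latency_z: float  # subject's overall component-latency z score
    seed: np.random.SeedSequence


def cohort_plan(config: CohortConfig) -> list[SessionPlan]:
    """Longitudinal sampling plan; deterministic given ``config.seed``.

    A single global seed fans out to per-subject substreams, so any subject
    subset is reproducible regardless of cohort size.  Wave skips are
    independent Bernoulli draws; subjects missing every wave are absent.
    """
    master = np.random.SeedSequence(config.seed)
    plan: list[SessionPlan] = []
    for si, sseq in enumerate(master.spawn(config.n_subjects)):
        rng = np.random.default_rng(sseq)
        sex = "F" if rng.random() < 0.58 else "M"
        rt_shift = rng.normal(0.0, 25.0)
        amp_z = tuple(rng.normal(0.0, 1.0, 2))
        latency_z = rng.normal()
        wave_seeds = sseq.spawn(len(config.waves))
        for wi, wave in enumerate(config.waves):
            skip = rng.random() < config.missingness
            age = wave + rng.normal(0.4, 0.5)
            if skip:
                continue
            plan.append(SessionPlan(
                meta=RecordingMeta(
                    recording_id=f"sub{si:03d}_w{int(wave)}",
                    participant=f"sub{si:03d}",
                    age=float(age),
                    sex=sex,
                    wave=int(wave),
                ),
                rt_shift_ms=rt_shift,
                amp_z=amp_z,
                latency_z=latency_z,
                seed=wave_seeds[wi],
            ))
    return plan


def simulate_cohort(
    config: CohortConfig,
    truth: GroundTruthDynamics,
) -> list[EpochedDataset]:
    """Simulate every planned session of the cohort (see :func:`cohort_plan`)."""
    truth.validate(ages=tuple(w + 2.0 for w in config.waves)
                   + tuple(w - 2.0 for w in config.waves))
    return [
        simulate_session(config, truth, p.meta, np.random.default_rng(p.seed),
                         subject_rt_shift_ms=p.rt_shift_ms,
                         subject_amp_z=p.amp_z,
                         subject_latency_z=p.latency_z)
        for p in cohort_plan(config)
    ]


def simulate_ar1_trials(
    A: np.ndarray,
    n_trials: int,
    n_times: int,
    noise_sd: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Stationary AR(1) trials ``x(t+1) = A x(t) + eps``, (n_trials, 2, T).

    The initial state is drawn from the exact stationary distribution
    (discrete Lyapunov solution); with ``noise_sd=0`` trials start and stay
    at zero.
    """
    from scipy import linalg

    A = np.asarray(A, dtype=float)
    if np.max(np.abs(np.linalg.eigvals(A))) >= 1.0:
        raise ValueError("A must be stable (spectral radius < 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    x = np.zeros((n_trials, 2, n_times))
    if noise_sd > 0:
        cov0 = linalg.solve_discrete_lyapunov(A, noise_sd**2 * np.eye(2))
        x[:, :, 0] = rng.multivariate_normal(np.zeros(2), cov0, n_trials)
    for t in range(n_times - 1):
        x[:, :, t + 1] = x[:, :, t] @ A.T
        if noise_sd > 0:
            x[:, :, t + 1] += rng.normal(0.0, noise_sd, (n_trials, 2))
    return x


def simulate_behavior(
    truth: GroundTruthDynamics,
    per_session_eigenvalue: float,
    age: float,
    seed: int | np.random.Generator | None = None,
    subject_shift: float = 0.0,
) -> tuple[float, float]:
    """Session-level (mean RT in ms, accuracy fraction) from an eigenvalue.

    RT increases with the eigenvalue at the standardized slope
    ``rt_coupling`` (z-units; eigenvalues referenced to ``rt_eig_ref``),
    accuracy decreases with it and increases with age, clipped to [0, 1].
    """
    eig = float(per_session_eigenvalue)
    if not 0.0 <= eig < 1.0:
        raise ValueError("eigenvalue must be in [0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mu, sd = truth.rt_eig_ref
    z_eig = (eig - mu) / sd
    rt_z = (truth.rt_coupling * z_eig + subject_shift
            + rng.normal(0.0, truth.rt_resid_sd))
    mean_rt = max(380.0 + 45.0 * rt_z, 150.0)
    accuracy = float(np.clip(
        0.85 + 0.012 * (age - 15.0) - truth.acc_coupling * (eig - mu)
        + rng.normal(0.0, 0.05),
        0.0, 1.0,
    ))
    return float(mean_rt), accuracy


def make_jittered_dataset(
    mean_erps: Mapping[str, np.ndarray],
    jitter: JitterConfig,
    n_trials: int,
    age: float,
    seed: int | np.random.Generator | None = None,
    times_ms: np.ndarray | None = None,
    fs: float = ANALYSIS_FS,
    start_ms: float = 0.0,
    lock: str = "stimulus",
    conditions: np.ndarray | None = None,
    recording: RecordingMeta | None = None,
) -> LatentTrials:
    """Trials that are time-shifted copies of the condition-mean ERP.

    Each trial is the condition mean evaluated at ``t + tau`` with
    ``tau ~ N(0, sigma_age)`` drawn per trial, by linear interpolation with
    nearest-value edge padding, plus i.i.d. Gaussian noise of SD ``eps_sd``.
    """
    sigma = jitter.sigma(age)
    if jitter.eps_sd is None:
        raise ValueError(
            "eps_sd is unset; supply a value or let run_jitter_control match "
            "it to the reference data's residual SD")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    conds = sorted(mean_erps)
    T = np.asarray(mean_erps[conds[0]]).shape[1]
    if times_ms is None:
        times_ms = start_ms + np.arange(T) * 1000.0 / fs
    if conditions is None:
        conditions = np.array([conds[i % len(conds)] for i in range(n_trials)])
    values = np.empty((n_trials, 2, T))
    taus = rng.normal(0.0, sigma, n_trials)
    for i in range(n_trials):
        erp = np.asarray(mean_erps[conditions[i]], dtype=float)
        for k in range(2):
            values[i, k] = np.interp(times_ms + taus[i], times_ms, erp[k],
                                     left=erp[k, 0], right=erp[k, -1])
    if jitter.eps_sd > 0:
        values += rng.normal(0.0, jitter.eps_sd, values.shape)
    if recording is None:
        recording = RecordingMeta("jitter", "jitter", float(age), "F",
                                  int(round(age)))
    return LatentTrials(
        values=values,
        fs=fs,
        lock=lock,
        start_ms=float(times_ms[0]),
        conditions=conditions,
        recording=recording,
        trials=pd.DataFrame({"condition": conditions, "tau_ms": taus}),
    )
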