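"""Time-resolved mixed-effects tests with TFCE clustering and a bootstrap
family-wise null.

Each window of the eigenvalue time course is tested with a random-intercept
mixed model (repeated recordings per participant).  The per-window
fixed-effect t statistics are enhanced with one-dimensional threshold-free
cluster enhancement (TFCE), and family-wise significance is assessed
against the distribution of the extreme enhanced score under resampling of
the predictor: each replicate redraws the fixed-effect variable (by
default in participant blocks that preserve the longitudinal
within/between-participant structure of the predictor), refits every
window, applies TFCE, and keeps the maximum.  Tests are one-tailed with a stated direction
and Bonferroni-corrected across the test family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from . import lmm
from .prep import EpochedDataset

logger = logging.getLogger(__name__)

OUTCOMES = ("eigenvalue", "rt", "accuracy", "rt_sd")
PREDICTORS = ("age", "sex", "eigenvalue")
TAILS = ("negative", "positive")

_OUTCOME_COLS = {"rt": "mean_rt", "accuracy": "accuracy", "rt_sd": "rt_sd"}


@dataclass(frozen=True)
class LmmSpec:
    """One hypothesis test: outcome ~ predictor (+ covariates) + (1|participant)."""

    outcome: str
    fixed_predictor: str
    tail: str
    lock: str
    eig_index: int = 1  # which eigenvalue when outcome or predictor is one
    covariates: tuple[str, ...] = ()
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.fixed_predictor not in PREDICTORS:
            raise ValueError(f"unknown predictor {self.fixed_predictor!r}")
        if self.outcome == self.fixed_predictor:
            raise ValueError("outcome and fixed predictor must differ")
        if self.tail not in TAILS:
            raise ValueError("tail must be stated ('negative' or 'positive')")
        if self.eig_index not in (1, 2):
            raise ValueError("eig_index must be 1 or 2")


@dataclass
class ClusterInference:
    """Observed statistics, enhanced scores, and bootstrap null for one test."""

    spec: LmmSpec
    window_centers_ms: np.ndarray
    t_series: np.ndarray
    tfce_series: np.ndarray
    null_max: np.ndarray
    p_series: np.ndarray
    sig_mask: np.ndarray
    alpha_corrected: float
    reps: int
    n_redrawn: int = 0

    @property
    def any_significant(self) -> bool:
        return bool(self.sig_mask.any())

    def clusters(self) -> list[tuple[float, float]]:
        """(start_ms, end_ms) of each significant contiguous run."""
        out = []
        m = self.sig_mask
        i = 0
        while i < m.size:
            if m[i]:
                j = i
                while j + 1 < m.size and m[j + 1]:
                    j += 1
                out.append((float(self.window_centers_ms[i]),
                            float(self.window_centers_ms[j])))
                i = j + 1
            else:
                i += 1
        return out


def correct_family(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Bonferroni-corrected per-test alpha level."""
    if int(n_tests) < 1 or int(n_tests) != n_tests:
        raise ValueError("n_tests must be a positive integer")
    return alpha / int(n_tests)


def tfce_1d(
    t_series: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
) -> np.ndarray:
    """One-dimensional threshold-free cluster enhancement.

    ``score(p) = sum_{h = dh, 2dh, ...} extent(h, p)^E * h^H * dh`` where
    ``extent(h, p)`` is the length of the contiguous run containing ``p``
    with values >= h.  Only positive values contribute; negate the series
    first for a negative-tail test.  Missing values count as zero for
    cluster extent.  ``dh`` defaults to max(series)/100.
    """
    s = np.nan_to_num(np.asarray(t_series, dtype=float), nan=0.0)
    if s.ndim != 1:
        raise ValueError("t_series must be one-dimensional")
    if dh is not None and dh <= 0:
        raise ValueError("dh must be positive")
    score = np.zeros_like(s)
    smax = s.max() if s.size else 0.0
    if smax <= 0:
        return score
    if dh is None:
        dh = smax / 100.0
    n_h = int(np.floor(smax / dh + 0.5))
    for k in range(1, n_h + 1):
        h = k * dh
        idx = np.flatnonzero(s >= h)
        if idx.size == 0:
            continue
        run_id = np.concatenate([[0], np.cumsum(np.diff(idx) > 1)])
        extents = np.bincount(run_id)[run_id]
        score[idx] += extents**E * h**H * dh
    return score


def tfce_2d(
    series: np.ndarray, E: float = 0.5, H: float = 2.0, dh: float | None = None
) -> np.ndarray:
    """Row-wise 1-D TFCE for a stack of series, (R, W) -> (R, W).

    Identical to applying :func:`tfce_1d` to every row with a shared ``dh``;
    vectorized for the bootstrap null, where thousands of short series are
    enhanced per test.
    """
    s = np.nan_to_num(np.asarray(series, dtype=float), nan=0.0)
    if s.ndim != 2:
        raise ValueError("series must be (n_series, n_windows)")
    R, W = s.shape
    out = np.zeros_like(s)
    smax = s.max() if s.size else 0.0
    if smax <= 0:
        return out
    if dh is None:
        dh = smax / 100.0
    elif dh <= 0:
        raise ValueError("dh must be positive")
    rows = np.arange(R)[:, None]
    n_h = int(np.floor(smax / dh + 0.5))
    for k in range(1, n_h + 1):
        h = k * dh
        m = s >= h
        if not m.any():
            break
        starts = m.copy()
        starts[:, 1:] &= ~m[:, :-1]
        run_id = np.cumsum(starts, axis=1)  # 1-based run index within row
        key = (rows * (W // 2 + 2) + run_id)[m]
        counts = np.bincount(key, minlength=R * (W // 2 + 2))
        out[m] += counts[key] ** E * h**H * dh
    return out


def tfce_brute_force(
    t_series: np.ndarray, E: float = 0.5, H: float = 2.0, dh: float = None
) -> np.ndarray:
    """Reference TFCE by an explicit double loop over thresholds and runs."""
    s = np.nan_to_num(np.asarray(t_series, dtype=float), nan=0.0)
    score = np.zeros_like(s)
    if s.size == 0 or s.max() <= 0:
        return score
    if dh is None:
        dh = s.max() / 100.0
    n_h = int(np.floor(s.max() / dh + 0.5))
    for k in range(1, n_h + 1):  # h = k*dh, never accumulated sums
        h = k * dh
        for p in range(s.size):
            if s[p] >= h:
                extent = 1
                q = p - 1
                while q >= 0 and s[q] >= h:
                    extent += 1
                    q -= 1
                q = p + 1
                while q < s.size and s[q] >= h:
                    extent += 1
                    q += 1
                score[p] += extent**E * h**H * dh
    return score


def _predictor_values(table: pd.DataFrame, spec: LmmSpec) -> pd.Series:
    if spec.fixed_predictor == "age":
        return table["age"].astype(float)
    if spec.fixed_predictor == "sex":
        return (table["sex"].astype(str) == "M").astype(float)
    return table[f"eig{spec.eig_index}"].astype(float)


def _outcome_values(table: pd.DataFrame, spec: LmmSpec) -> pd.Series:
    if spec.outcome == "eigenvalue":
        return table[f"eig{spec.eig_index}"].astype(float)
    return table[_OUTCOME_COLS[spec.outcome]].astype(float)


def fit_lmm_timecourse(
    table: pd.DataFrame,
    spec: LmmSpec,
    engine: str = "fast",
) -> pd.DataFrame:
    """Per-window random-intercept LMM; returns the fixed-effect t series.

    ``table`` is the tidy long format produced by the dynamics stage
    (one row per recording x window, behavior columns merged).  Windows
    where the model cannot be fit are returned as NaN with a warning, never
    silently as zero.  ``engine='statsmodels'`` routes the fit through
    ``statsmodels.MixedLM`` (slower; used for cross-validation).
    """
    sub = table[table["lock"] == spec.lock]
    if sub.empty:
        raise ValueError(f"no rows for lock {spec.lock!r}")
    if sub["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    rows = []
    for center, win in sub.groupby("window_center_ms", sort=True):
        y = _outcome_values(win, spec).to_numpy()
        x = _predictor_values(win, spec).to_numpy()
        cov_cols = [_predictor_values(win, LmmSpec(
            outcome=spec.outcome, fixed_predictor=c, tail=spec.tail,
            lock=spec.lock, eig_index=spec.eig_index)).to_numpy()
            for c in spec.covariates]
        ok = np.isfinite(y) & np.isfinite(x)
        for c in cov_cols:
            ok &= np.isfinite(c)
        y, x = y[ok], x[ok]
        cov_cols = [c[ok] for c in cov_cols]
        groups = win["participant"].to_numpy()[ok]
        if spec.standardize:
            y = (y - y.mean()) / y.std() if y.std() > 0 else y
            x = (x - x.mean()) / x.std() if x.std() > 0 else x
        X = np.column_stack([np.ones_like(x), x, *cov_cols])
        t = beta = se = gamma = np.nan
        nobs = int(ok.sum())
        if nobs >= X.shape[1] + 1 and np.std(x) > 0:
            if engine == "statsmodels":
                import statsmodels.api as sm

                try:
                    fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
                    beta, se = fit.fe_params[1], fit.bse_fe[1]
                    t, gamma = beta / se, np.nan
                except Exception:  # non-convergence stays NaN
                    logger.warning("window %.0f ms: statsmodels fit failed", center)
            else:
                fit = lmm.fit_random_intercept(y, X, groups)
                if fit.converged:
                    beta, se, t = fit.params[1], fit.bse[1], fit.tvalues[1]
                    gamma = fit.gamma
                else:
                    logger.warning("window %.0f ms: REML fit did not converge", center)
        rows.append({"window_center_ms": center, "t": t, "beta": beta,
                     "se": se, "gamma": gamma, "nobs": nobs})
    return pd.DataFrame(rows)


def _wide_arrays(table: pd.DataFrame, spec: LmmSpec):
    """Pivot the long table into (W, n) outcome/predictor matrices."""
    sub = table[table["lock"] == spec.lock].copy()
    if sub.empty:
        raise ValueError(f"no rows for lock {spec.lock!r}")
    sub["_y"] = _outcome_values(sub, spec)
    sub["_x"] = _predictor_values(sub, spec)
    ymat = sub.pivot_table(index="window_center_ms", columns="recording_id",
                           values="_y", sort=True)
    xmat = sub.pivot_table(index="window_center_ms", columns="recording_id",
                           values="_x", sort=True)
    xmat = xmat.reindex(columns=ymat.columns)
    meta = (sub[["recording_id", "participant", "wave"]]
            .drop_duplicates("recording_id").set_index("recording_id")
            .reindex(ymat.columns))
    centers = ymat.index.to_numpy(dtype=float)
    Y = ymat.to_numpy()
    X = xmat.to_numpy()
    complete = np.isfinite(Y).all(axis=0) & np.isfinite(X).all(axis=0)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("dropping %d recordings with missing windows from the "
                    "bootstrap test", n_drop)
    return (centers, Y[:, complete], X[:, complete],
            meta["participant"].to_numpy()[complete],
            meta["wave"].to_numpy()[complete])


def _participant_resample_idx(
    rng: np.random.Generator,
    participants: np.ndarray,
    waves: np.ndarray,
    reps: int,
) -> np.ndarray:
    """Participant-blocked resampling indices, (reps, n).

    The longitudinal design makes single recordings non-exchangeable: the
    mixed model's age information lives largely in within-participant
    contrasts, so a valid null must scramble the predictor while keeping
    its within/between-participant variance structure.  Each replicate
    (a) permutes whole wave-aligned predictor trajectories among
    participants with the same set of observed waves, and (b) permutes the
    predictor values within each trajectory (wave order scrambled).
    Participants with a unique wave signature keep their own trajectory
    and only get the within-trajectory permutation.
    """
    n = participants.size
    idx = np.broadcast_to(np.arange(n), (reps, n)).copy()
    per_part: dict = {}
    for i, (p, w) in enumerate(zip(participants, waves)):
        per_part.setdefault(p, {})[w] = i
    by_sig: dict = {}
    for p, wmap in per_part.items():
        by_sig.setdefault(frozenset(wmap), []).append(p)
    for sig, plist in by_sig.items():
        m = len(plist)
        k = len(sig)
        wave_list = sorted(sig)
        # (m, k) column indices of each participant's recordings
        cols = np.array([[per_part[p][w] for w in wave_list] for p in plist])
        if m > 1:
            src = np.argsort(rng.random((reps, m)), axis=1)
            traj = cols[src]  # (reps, m, k)
        else:
            traj = np.broadcast_to(cols, (reps, m, k)).copy()
        if k > 1:
            wperm = np.argsort(rng.random((reps, m, k)), axis=2)
            traj = np.take_along_axis(traj, wperm, axis=2)
        idx[:, cols.reshape(-1)] = traj.reshape(reps, -1)
    return idx


def bootstrap_cluster_test(
    table: pd.DataFrame,
    spec: LmmSpec,
    reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    n_tests: int = 1,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    resample: str = "participant",
) -> ClusterInference:
    """Cluster-corrected test of one hypothesis over the window time course.

    The null resamples the fixed-effect variable with replacement across
    participants (default ``resample='participant'``: whole wave-aligned
    predictor trajectories are reassigned, preserving the longitudinal
    within/between-participant structure the mixed model's slope relies
    on).  ``resample='bootstrap'`` resamples single recordings instead and
    ``'permutation'`` permutes them.  Each replicate refits the mixed
    model at every window, enhances the oriented t series with TFCE, and
    records the extreme score.  Cluster p values use the add-one
    convention ``p = (1 + #{null >= observed}) / (1 + reps)`` and are
    compared with the Bonferroni-corrected alpha.  Deterministic given the
    seed.  Recordings with missing windows are dropped (complete-case).
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if resample not in ("participant", "bootstrap", "permutation"):
        raise ValueError(
            "resample must be 'participant', 'bootstrap' or 'permutation'")
    if spec.covariates:
        raise NotImplementedError(
            "covariate-adjusted cluster tests go through fit_lmm_timecourse"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers, Y, X, participants, waves = _wide_arrays(table, spec)
    W, n = Y.shape
    if n < 4:
        raise ValueError("too few complete recordings for a bootstrap test")
    codes, nj = lmm.group_codes(participants)
    x_const = bool(np.all(X == X[0]))  # predictor constant across windows?

    # observed t per window
    if x_const:
        t_obs = lmm.fit_slope_boot(Y, X[0][None, :], codes, nj)["t"][0]
    else:
        t_obs = np.array([
            lmm.fit_slope_boot(Y[w][None, :], X[w][None, :], codes, nj)["t"][0, 0]
            for w in range(W)])

    sign = -1.0 if spec.tail == "negative" else 1.0
    s_obs = sign * t_obs
    if dh is None:
        m = np.nanmax(s_obs) if np.isfinite(s_obs).any() else 0.0
        dh = m / 100.0 if m > 0 else 0.1
    tfce_obs = tfce_1d(s_obs, E=E, H=H, dh=dh)

    # resampled predictor assignments, one per replicate, shared across windows
    def draw(r: int) -> np.ndarray:
        if resample == "permutation":
            return np.argsort(rng.random((r, n)), axis=1)
        if resample == "participant":
            return _participant_resample_idx(rng, participants, waves, r)
        return rng.integers(0, n, size=(r, n))

    n_redrawn = 0
    idx = draw(reps)
    for _ in range(100):
        # degenerate replicate: resampled predictor constant across recordings
        xv = X[0][idx]
        bad = xv.max(axis=1) == xv.min(axis=1)
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        idx[bad] = draw(int(bad.sum()))
    else:
        logger.warning("could not avoid degenerate resamples after 100 rounds")

    if x_const:
        t_null = lmm.fit_slope_boot(Y, X[0][idx], codes, nj)["t"]  # (reps, W)
    else:
        t_null = np.empty((reps, W))
        for w in range(W):
            t_null[:, w] = lmm.fit_slope_many(Y[w], X[w][idx], codes, nj)["t"]

    null_max = tfce_2d(sign * t_null, E=E, H=H, dh=dh).max(axis=1, initial=0.0)

    p_series = (1.0 + (null_max[None, :] >= tfce_obs[:, None]).sum(axis=1)) / (1.0 + reps)
    alpha_corrected = correct_family(alpha, n_tests)
    sig_mask = p_series <= alpha_corrected
    return ClusterInference(
        spec=spec,
        window_centers_ms=centers,
        t_series=t_obs,
        tfce_series=tfce_obs,
        null_max=null_max,
        p_series=p_series,
        sig_mask=sig_mask,
        alpha_corrected=alpha_corrected,
        reps=reps,
        n_redrawn=n_redrawn,
    )


def behavior_tables(sessions: Iterable[EpochedDataset]) -> pd.DataFrame:
    """Per-recording behavioral summaries feeding the behavior LMMs.

    Accuracy is the fraction of correct trials among responded trials;
    mean RT and RT SD are over responded trials.  Congruent/incongruent
    splits are retained alongside the overall values.
    """
    rows = []
    for ds in sessions:
        tr = ds.trials
        resp = tr["responded"].to_numpy(dtype=bool)
        cond = tr["condition"].astype(str)
        correct = cond.str.endswith("_correct").to_numpy()
        congruent = cond.str.startswith("congruent").to_numpy()
        rts = tr["rt_ms"].to_numpy(dtype=float)
        row = {
            "recording_id": ds.recording.recording_id,
            "participant": ds.recording.participant,
            "age": ds.recording.age,
            "sex": ds.recording.sex,
            "wave": ds.recording.wave,
            "accuracy": correct[resp].mean() if resp.any() else np.nan,
            "mean_rt": rts[resp].mean() if resp.any() else np.nan,
            "rt_sd": rts[resp].std() if resp.any() else np.nan,
        }
        for label, m in (("congruent", congruent), ("incongruent", ~congruent)):
            mm = m & resp
            row[f"accuracy_{label}"] = correct[mm].mean() if mm.any() else np.nan
            row[f"mean_rt_{label}"] = rts[mm].mean() if mm.any() else np.nan
            row[f"rt_sd_{label}"] = rts[mm].std() if mm.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
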