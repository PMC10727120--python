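"""Time-resolved 2-D AR(1) dynamics of single-trial residual activity.

Residuals are single-trial latent series minus the same-condition trial
mean; they quantify fluctuation around the evoked trajectory.  A first-order
linear model ``x(t+1) = A x(t) + eps(t)`` is fit to residual transition
pairs pooled over trials and conditions inside a short moving window, and
the eigenvalues of ``A`` give the per-mode decay factor of fluctuations:
near 0 means fast relaxation back to the mean (a steep attractor basin),
near 1 means integrator-like persistence.

The window fits are ordinary least squares in closed form via the 2x2
normal equations; no intercept is included because the residuals are
mean-zero by construction.  Eigenvalues are reported as moduli (the decay
rate of the mode, equal to the eigenvalue itself when real) and windows
with complex-conjugate pairs are flagged rather than guessed at.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .latent import LatentTrials
from .prep import RecordingMeta

logger = logging.getLogger(__name__)

_COMPLEX_TOL = 1e-12


@dataclass
class ResidualTrials:
    """Trials x 2 x time residuals after condition-mean subtraction."""

    values: np.ndarray  # (n_trials, 2, n_times)
    fs: float
    lock: str
    start_ms: float
    conditions: np.ndarray
    recording: RecordingMeta
    n_single_trial_excluded: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != 2:
            raise ValueError("values must be (n_trials, 2, n_times)")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return self.start_ms + np.arange(self.values.shape[2]) * 1000.0 / self.fs


@dataclass
class DynamicsTimecourse:
    """Per-window dynamics matrices and ordered eigen-structure."""

    window_centers_ms: np.ndarray  # (W,)
    A_hat: np.ndarray  # (W, 2, 2); NaN where the window was skipped
    eig_moduli: np.ndarray  # (W, 2) ordered by principal-component association
    eig_vectors: np.ndarray  # (W, 2, 2), columns are the ordered eigenvectors
    n_pairs: np.ndarray  # (W,)
    complex_flag: np.ndarray  # (W,) bool
    lock: str
    recording: RecordingMeta

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table, one row per window."""
        return pd.DataFrame(
            {
                "recording_id": self.recording.recording_id,
                "participant": self.recording.participant,
                "age": self.recording.age,
                "sex": self.recording.sex,
                "wave": self.recording.wave,
                "lock": self.lock,
                "window_center_ms": self.window_centers_ms,
                "eig1": self.eig_moduli[:, 0],
                "eig2": self.eig_moduli[:, 1],
                "n_pairs": self.n_pairs,
                "complex_flag": self.complex_flag,
            }
        )


def compute_residuals(latent: LatentTrials) -> ResidualTrials:
    """Subtract the same-condition, same-lock trial mean from each trial.

    Conditions represented by a single trial would give identically-zero
    residuals; those trials are flagged and excluded from fitting.
    """
    if latent.n_trials < 1:
        raise ValueError("need at least one trial")
    values = latent.values
    conds = latent.conditions
    resid = np.empty_like(values)
    keep = np.ones(len(conds), dtype=bool)
    n_single = 0
    for cond in np.unique(conds):
        mask = conds == cond
        if mask.sum() == 1:
            resid[mask] = 0.0
            keep[mask] = False
            n_single += 1
            logger.info("condition %s has a single trial; residual dropped", cond)
        else:
            resid[mask] = values[mask] - values[mask].mean(axis=0, keepdims=True)
    return ResidualTrials(
        values=resid[keep],
        fs=latent.fs,
        lock=latent.lock,
        start_ms=latent.start_ms,
        conditions=conds[keep],
        recording=latent.recording,
        n_single_trial_excluded=n_single,
    )


def fit_ar1_pairs(x0: np.ndarray, x1: np.ndarray) -> np.ndarray:
    """Closed-form OLS fit of ``x1 = A x0`` over pooled pairs.

    ``x0``, ``x1`` are (2, n_pairs).  Solves the 2x2 normal equations
    ``A = (x1 x0') (x0 x0')^-1``; raises on a singular second-moment matrix.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    s00 = x0 @ x0.T
    s10 = x1 @ x0.T
    det = s00[0, 0] * s00[1, 1] - s00[0, 1] * s00[1, 0]
    scale = max(s00[0, 0], s00[1, 1], 1e-300)
    if not np.isfinite(det) or abs(det) < 1e-12 * scale**2:
        raise np.linalg.LinAlgError("singular pooled second-moment matrix")
    return np.linalg.solve(s00.T, s10.T).T


def _window_indices(times_ms: np.ndarray, center_ms: float, width_ms: float) -> np.ndarray:
    half = width_ms / 2.0 + 1e-9
    return np.flatnonzero(np.abs(times_ms - center_ms) <= half)


def window_samples_per_trial(fs: float, width_ms: float = 100.0) -> int:
    """Number of samples each trial contributes to one fitting window."""
    return int(np.floor(width_ms / 2.0 / (1000.0 / fs) + 1e-9)) * 2 + 1


def fit_window_ar1(
    residuals: ResidualTrials,
    window_center_ms: float,
    width_ms: float = 100.0,
    min_pairs: int = 4,
) -> tuple[np.ndarray, int]:
    """Fit the AR(1) model in one window; returns (A_hat, n_pairs).

    Transition pairs with both endpoints inside the window are pooled over
    all trials and conditions.  Windows with fewer than ``min_pairs`` pairs
    are refused (4 pairs are the minimum to identify the 4 entries of A).
    """
    idx = _window_indices(residuals.times_ms, window_center_ms, width_ms)
    if idx.size < 2 or np.any(np.diff(idx) != 1):
        raise ValueError("window does not cover at least two contiguous samples")
    x0 = residuals.values[:, :, idx[:-1]].transpose(1, 0, 2).reshape(2, -1)
    x1 = residuals.values[:, :, idx[1:]].transpose(1, 0, 2).reshape(2, -1)
    n_pairs = x0.shape[1]
    if n_pairs < min_pairs:
        raise ValueError(f"only {n_pairs} transition pairs; need >= {min_pairs}")
    return fit_ar1_pairs(x0, x1), n_pairs


def eig_order(
    A_hat: np.ndarray,
    prev_vectors: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Label the eigenpairs of a real 2x2 by principal-component association.

    Eigenpair k is the one whose eigenvector loads most strongly on PC k;
    when both claim the same PC the larger |loading| wins and the other
    takes the remaining slot.  A complex-conjugate pair shares one modulus,
    is flagged, and is assigned by real-part loadings.
    Returns (moduli (2,), vectors (2,2) columns, complex_flag).
    """
    A_hat = np.asarray(A_hat, dtype=float)
    w, V = np.linalg.eig(A_hat)
    is_complex = bool(np.any(np.abs(w.imag) > _COMPLEX_TOL))
    load = np.abs(V.real) if is_complex else np.abs(V)
    # claimed PC of each eigenvector (columns of V)
    claims = np.argmax(load, axis=0)
    if claims[0] != claims[1]:
        assign = np.empty(2, dtype=int)
        assign[claims[0]] = 0
        assign[claims[1]] = 1
    else:
        pc = claims[0]
        winner = int(np.argmax(load[pc, :]))
        assign = np.empty(2, dtype=int)
        assign[pc] = winner
        assign[1 - pc] = 1 - winner
    moduli = np.abs(w)[assign]
    vectors = V[:, assign].real
    return moduli, vectors, is_complex


def sweep_dynamics(
    residuals: ResidualTrials,
    width_ms: float = 100.0,
    step_samples: int = 1,
    min_pairs: int = 4,
) -> DynamicsTimecourse:
    """Slide the AR(1) window across the lock segment.

    Windows are labeled by their center time and advanced by
    ``step_samples`` grid steps; only windows fully inside the segment are
    fit.  At 30 Hz with a 100-ms window each trial contributes 3 samples,
    hence 2 transition pairs.  Windows that fail to fit (too few pairs,
    singular moments) are reported as NaN, never as zeros.
    """
    times = residuals.times_ms
    k = window_samples_per_trial(residuals.fs, width_ms)
    half_samples = (k - 1) // 2
    if half_samples < 1:
        raise ValueError("window shorter than one sample step; widen it")
    center_idx = np.arange(half_samples, times.size - half_samples, step_samples)
    if center_idx.size == 0:
        raise ValueError("segment too short for the fitting window")

    # pairwise second moments per transition, summed over trials
    v = residuals.values
    c00 = np.einsum("nit,njt->tij", v[:, :, :-1], v[:, :, :-1])
    c10 = np.einsum("nit,njt->tij", v[:, :, 1:], v[:, :, :-1])
    csum00 = np.concatenate([np.zeros((1, 2, 2)), np.cumsum(c00, axis=0)])
    csum10 = np.concatenate([np.zeros((1, 2, 2)), np.cumsum(c10, axis=0)])

    W = center_idx.size
    A = np.full((W, 2, 2), np.nan)
    moduli = np.full((W, 2), np.nan)
    vectors = np.full((W, 2, 2), np.nan)
    n_pairs = np.zeros(W, dtype=int)
    cflag = np.zeros(W, dtype=bool)
    pairs_per_window = (k - 1) * residuals.n_trials
    for wi, ci in enumerate(center_idx):
        lo, hi = ci - half_samples, ci + half_samples  # pair indices [lo, hi)
        s00 = csum00[hi] - csum00[lo]
        s10 = csum10[hi] - csum10[lo]
        n_pairs[wi] = pairs_per_window
        if pairs_per_window < min_pairs:
            logger.info("window at %.0f ms skipped: %d pairs < %d",
                        times[ci], pairs_per_window, min_pairs)
            continue
        det = s00[0, 0] * s00[1, 1] - s00[0, 1] * s00[1, 0]
        scale = max(s00[0, 0], s00[1, 1], 1e-300)
        if not np.isfinite(det) or abs(det) < 1e-12 * scale**2:
            logger.info("window at %.0f ms skipped: singular moment matrix", times[ci])
            continue
        A[wi] = np.linalg.solve(s00.T, s10.T).T
        moduli[wi], vectors[wi], cflag[wi] = eig_order(A[wi])
    return DynamicsTimecourse(
        window_centers_ms=times[center_idx],
        A_hat=A,
        eig_moduli=moduli,
        eig_vectors=vectors,
        n_pairs=n_pairs,
        complex_flag=cflag,
        lock=residuals.lock,
        recording=residuals.recording,
    )
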