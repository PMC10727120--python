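"""Two-component PCA sensor-space reduction and per-subject z-scoring.

The component space is fit once, on the grand-average condition ERPs
(stimulus- and response-locked, time-concatenated), and then reused
unchanged for every recording: it is a signal-processing device to find a
low-dimensional space of task-evoked activity, not a per-subject model.
Single trials are projected into that space and standardized with one mean
and one SD per component per recording, pooled over all trials and time
points — a per-timepoint z-score would flatten exactly the fluctuation
dynamics the downstream AR(1) model measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .prep import CONDITIONS, EpochedDataset, RecordingMeta

N_COMPONENTS = 2


@dataclass
class ComponentSpace:
    """Sensor loadings of the two retained principal components."""

    loadings: np.ndarray  # (n_sensors, 2), orthonormal columns
    explained_fraction: np.ndarray  # (2,), non-increasing, each <= 1
    fit_provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.explained_fraction = np.asarray(self.explained_fraction, dtype=float)
        if self.loadings.ndim != 2 or self.loadings.shape[1] != N_COMPONENTS:
            raise ValueError("loadings must be (n_sensors, 2)")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(N_COMPONENTS), atol=1e-8):
            raise ValueError("loading columns must be orthonormal")
        ef = self.explained_fraction
        if ef.shape != (N_COMPONENTS,) or np.any(ef > 1 + 1e-12) or ef[0] < ef[1] - 1e-12:
            raise ValueError("explained_fraction must be 2 non-increasing values <= 1")


@dataclass
class LatentTrials:
    """Trials x 2 components x time, in z-units after standardization."""

    values: np.ndarray  # (n_trials, 2, n_times)
    fs: float
    lock: str
    start_ms: float
    conditions: np.ndarray  # (n_trials,) condition labels
    recording: RecordingMeta
    zscore_mean: np.ndarray | None = None  # (2,) per-component mean used
    zscore_sd: np.ndarray | None = None  # (2,) per-component SD used
    trials: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != N_COMPONENTS:
            raise ValueError("values must be (n_trials, 2, n_times)")
        self.conditions = np.asarray(self.conditions)
        if self.conditions.shape[0] != self.values.shape[0]:
            raise ValueError("conditions length mismatch")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return self.start_ms + np.arange(self.values.shape[2]) * 1000.0 / self.fs


def condition_means(epochs: EpochedDataset) -> dict[str, np.ndarray]:
    """Per-condition mean over trials, (n_sensors, n_times) each."""
    conds = epochs.trials["condition"].to_numpy()
    out = {}
    for cond in CONDITIONS:
        mask = conds == cond
        if mask.any():
            out[cond] = epochs.data[mask].mean(axis=0)
    return out


def grand_average_erps(
    datasets: Iterable[EpochedDataset],
) -> dict[str, np.ndarray]:
    """Grand-average condition ERPs pooled over all trials of all recordings."""
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for ds in datasets:
        conds = ds.trials["condition"].to_numpy()
        for cond in CONDITIONS:
            mask = conds == cond
            if not mask.any():
                continue
            s = ds.data[mask].sum(axis=0)
            if cond in sums:
                sums[cond] += s
                counts[cond] += int(mask.sum())
            else:
                sums[cond] = s.astype(float)
                counts[cond] = int(mask.sum())
    return {c: sums[c] / counts[c] for c in sums}


def fit_component_space(
    grand_averages: Sequence[np.ndarray] | Mapping[str, np.ndarray],
    provenance: dict | None = None,
) -> ComponentSpace:
    """Eigendecompose the sensor covariance of time-concatenated mean ERPs.

    Each array is (n_sensors, n_times); arrays are concatenated along time,
    the concatenated time axis is mean-centered per sensor, and the top two
    eigenvectors of the resulting sensors x sensors covariance are retained.
    The sign of each component is fixed so its largest-|loading| sensor is
    positive, making downstream eigenvector orderings deterministic.
    """
    if isinstance(grand_averages, Mapping):
        arrays = [np.asarray(grand_averages[k], dtype=float) for k in sorted(grand_averages)]
    else:
        arrays = [np.asarray(a, dtype=float) for a in grand_averages]
    if not arrays:
        raise ValueError("no grand averages provided")
    n_sensors = arrays[0].shape[0]
    if any(a.ndim != 2 or a.shape[0] != n_sensors for a in arrays):
        raise ValueError("grand averages must share the sensor dimension")
    concat = np.concatenate(arrays, axis=1)
    if concat.shape[1] < 2:
        raise ValueError("need at least 2 time points in total")
    concat = concat - concat.mean(axis=1, keepdims=True)
    cov = concat @ concat.T / concat.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= 0 or evals[1] <= 1e-12 * max(evals[0], 1.0):
        raise ValueError("grand-average covariance has rank < 2")
    loadings = evecs[:, :N_COMPONENTS]
    for k in range(N_COMPONENTS):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
    return ComponentSpace(
        loadings=loadings,
        explained_fraction=evals[:N_COMPONENTS] / total,
        fit_provenance=provenance or {},
    )


def project(epochs: EpochedDataset, space: ComponentSpace) -> np.ndarray:
    """Project sensor data into component space: (n_trials, 2, n_times)."""
    if epochs.n_sensors != space.loadings.shape[0]:
        raise ValueError("sensor count does not match component loadings")
    return np.einsum("sk,nst->nkt", space.loadings, epochs.data.astype(float))


def pooled_zscore_params(
    latent_segments: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """One mean and SD per component, pooled over all trials and time points
    of all provided segments (e.g. a recording's three lock segmentations)."""
    flat = [seg.transpose(1, 0, 2).reshape(N_COMPONENTS, -1) for seg in latent_segments]
    allv = np.concatenate(flat, axis=1)
    mean = allv.mean(axis=1)
    sd = allv.std(axis=1)
    # "flat" includes numerically-zero spread relative to the data scale
    tol = 1e-12 * max(float(np.max(np.abs(allv), initial=0.0)), 1e-30)
    for k in range(N_COMPONENTS):
        if not np.isfinite(sd[k]) or sd[k] <= tol:
            raise ValueError(f"component {k + 1} is flat: pooled SD is zero")
    return mean, sd


def zscore_latent_session(
    latents_by_lock: Mapping[str, LatentTrials],
) -> dict[str, LatentTrials]:
    """Standardize already-latent trials with one session-pooled mean/SD per
    component shared across the session's lock segmentations."""
    mean, sd = pooled_zscore_params([lt.values for lt in latents_by_lock.values()])
    out = {}
    for lock, lt in latents_by_lock.items():
        out[lock] = LatentTrials(
            values=(lt.values - mean[None, :, None]) / sd[None, :, None],
            fs=lt.fs,
            lock=lt.lock,
            start_ms=lt.start_ms,
            conditions=lt.conditions,
            recording=lt.recording,
            zscore_mean=mean,
            zscore_sd=sd,
            trials=lt.trials,
        )
    return out


def project_and_zscore(
    epochs_by_lock: Mapping[str, EpochedDataset] | EpochedDataset,
    space: ComponentSpace,
) -> dict[str, LatentTrials]:
    """Project a recording's segmentations and z-score with session-pooled
    per-component mean/SD (shared across all locks of the recording)."""
    if isinstance(epochs_by_lock, EpochedDataset):
        epochs_by_lock = {epochs_by_lock.lock: epochs_by_lock}
    latents = {lock: project(ds, space) for lock, ds in epochs_by_lock.items()}
    mean, sd = pooled_zscore_params(list(latents.values()))
    out = {}
    for lock, ds in epochs_by_lock.items():
        z = (latents[lock] - mean[None, :, None]) / sd[None, :, None]
        out[lock] = LatentTrials(
            values=z,
            fs=ds.fs,
            lock=lock,
            start_ms=ds.start_ms,
            conditions=ds.trials["condition"].to_numpy(),
            recording=ds.recording,
            zscore_mean=mean,
            zscore_sd=sd,
            trials=ds.trials,
        )
    return out
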