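"""Signal conditioning for epoched EEG: lowpass filtering, resampling,
event-locked re-segmentation, and recording inclusion rules.

The dynamics analysis operates on evoked activity below ~15 Hz, so epochs
are zero-phase lowpass filtered and decimated to a common 30 Hz analysis
grid before any model fitting.  Segmentation re-locks each trial to one of
the three task events (fixation cue, flanker stimulus, button response)
using fixed per-lock windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

#: the three task events trials can be locked to
LOCKS = ("cue", "stimulus", "response")

#: four trial conditions: congruency x correctness
CONDITIONS = (
    "congruent_correct",
    "congruent_error",
    "incongruent_correct",
    "incongruent_error",
)


@dataclass(frozen=True)
class LockWindows:
    """Analysis windows (start_ms, end_ms) relative to each task event."""

    cue: tuple[float, float] = (-600.0, 500.0)
    stimulus: tuple[float, float] = (-400.0, 600.0)
    response: tuple[float, float] = (-500.0, 500.0)

    def __post_init__(self) -> None:
        for lock in LOCKS:
            start, end = getattr(self, lock)
            if not start < end:
                raise ValueError(f"window for {lock!r} must have start < end")

    def window(self, lock: str) -> tuple[float, float]:
        if lock not in LOCKS:
            raise ValueError(f"unknown lock {lock!r}; expected one of {LOCKS}")
        return getattr(self, lock)


@dataclass(frozen=True)
class RecordingMeta:
    """Identity of one EEG session: who, when, and demographic covariates."""

    recording_id: str
    participant: str
    age: float  # years, real-valued at time of recording
    sex: str  # "F" or "M"
    wave: int  # target age of the longitudinal wave (12, 15, 18)


@dataclass
class EpochedDataset:
    """Trials x sensors x time array with per-trial and per-recording metadata.

    ``lock`` is one of :data:`LOCKS`, or ``"trial"`` for generator output
    that spans a whole trial anchored at the cue (t=0 at cue onset) and still
    carries per-trial event latencies for later re-segmentation.

    ``trials`` columns: ``condition``, ``rt_ms``, ``responded``, and the
    event latencies ``cue_ms``, ``stimulus_ms``, ``response_ms`` (ms relative
    to the epoch time axis origin; NaN where the event is absent).
    """

    data: np.ndarray  # (n_trials, n_sensors, n_times)
    fs: float
    lock: str
    start_ms: float  # time of the first sample relative to the lock event
    trials: pd.DataFrame
    recording: RecordingMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_sensors, n_times)")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("trials metadata length mismatch")
        if "condition" in self.trials:
            bad = set(self.trials["condition"]) - set(CONDITIONS)
            if bad:
                raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if "responded" in self.trials and "rt_ms" in self.trials:
            resp = self.trials["responded"].to_numpy(dtype=bool)
            rts = self.trials["rt_ms"].to_numpy(dtype=float)
            if np.any(resp & ~(rts > 0)):
                raise ValueError("rt_ms must be > 0 for responded trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.start_ms + np.arange(self.n_times) * 1000.0 / self.fs


def window_n_samples(start_ms: float, end_ms: float, fs: float) -> int:
    """Sample count of a window inclusive of both endpoints."""
    return int(round((end_ms - start_ms) / 1000.0 * fs)) + 1


def lowpass_and_downsample(
    epochs: EpochedDataset,
    cutoff: float | None = 15.0,
    target_fs: float = 30.0,
    order: int = 4,
) -> EpochedDataset:
    """Zero-phase lowpass filter then polyphase-resample to ``target_fs``.

    The filter is a Butterworth lowpass of the given order applied
    forward-backward (``sosfiltfilt``), so the passband is flat, the
    effective attenuation is doubled, and no phase distortion is introduced
    (phase lags would bias the autoregressive fits downstream).
    ``cutoff=None`` skips filtering; ``target_fs`` equal to the input rate
    skips resampling.  Metadata is carried through unchanged.
    """
    fs = epochs.fs
    data = epochs.data.astype(np.float64, copy=True)
    if cutoff is not None:
        if cutoff >= fs / 2.0:
            raise ValueError(
                f"cutoff {cutoff} Hz must be below the Nyquist frequency {fs / 2.0} Hz"
            )
        sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
        padlen = 3 * (2 * order + 1)
        if epochs.n_times <= padlen:
            logger.warning(
                "epoch of %d samples is short for the filter edge padding; "
                "using reduced reflect padding",
                epochs.n_times,
            )
            padlen = max(epochs.n_times - 2, 0)
        data = signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen)
    if target_fs != fs:
        frac = Fraction(target_fs / fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    return replace(
        epochs,
        data=np.ascontiguousarray(data),
        fs=float(target_fs),
        trials=epochs.trials.copy(),
    )


def segment(
    epochs: EpochedDataset,
    lock: str,
    windows: LockWindows = LockWindows(),
) -> EpochedDataset:
    """Re-segment trial epochs around one task event.

    Only trials with a response are retained (correct and commission-error
    trials in both congruency conditions).  Trials whose lock window falls
    outside the recorded epoch are dropped with a logged count.  The output
    window is inclusive of both endpoints, giving
    ``round((end-start)/1000*fs)+1`` samples.
    """
    if lock not in LOCKS:
        raise ValueError(f"unknown lock {lock!r}")
    start_ms, end_ms = windows.window(lock)
    n_out = window_n_samples(start_ms, end_ms, epochs.fs)
    lat_col = f"{lock}_ms"
    if lat_col not in epochs.trials:
        raise ValueError(f"trials metadata lacks event latencies {lat_col!r}")

    responded = epochs.trials["responded"].to_numpy(dtype=bool)
    latencies = epochs.trials[lat_col].to_numpy(dtype=float)
    usable = responded & np.isfinite(latencies)
    if not usable.any():
        raise ValueError(f"no trial carries a usable {lock!r} event")

    keep_rows: list[int] = []
    starts: list[int] = []
    n_dropped = 0
    for i in np.flatnonzero(usable):
        i0 = int(round((latencies[i] + start_ms - epochs.start_ms) * epochs.fs / 1000.0))
        if i0 < 0 or i0 + n_out > epochs.n_times:
            n_dropped += 1
            continue
        keep_rows.append(i)
        starts.append(i0)
    if n_dropped:
        logger.info(
            "recording %s: dropped %d/%d trials whose %s window exceeded the epoch",
            epochs.recording.recording_id,
            n_dropped,
            int(usable.sum()),
            lock,
        )
    if not keep_rows:
        raise ValueError(f"all {lock!r}-locked windows fall outside the recorded epochs")

    idx = np.asarray(starts)[:, None] + np.arange(n_out)[None, :]
    data = epochs.data[np.asarray(keep_rows)[:, None, None],
                       np.arange(epochs.n_sensors)[None, :, None],
                       idx[:, None, :]]
    trials = epochs.trials.iloc[keep_rows].reset_index(drop=True)
    return EpochedDataset(
        data=np.ascontiguousarray(data),
        fs=epochs.fs,
        lock=lock,
        start_ms=start_ms,
        trials=trials,
        recording=epochs.recording,
    )


def apply_inclusion_rule(
    datasets: Mapping[str, Iterable[EpochedDataset]],
    min_trials: int = 50,
) -> dict[str, list[EpochedDataset]]:
    """Drop recordings with fewer than ``min_trials`` trials, per lock.

    Exclusion is lock-specific: a recording short of cue-locked trials can
    still contribute to the stimulus- or response-locked analyses.
    """
    out: dict[str, list[EpochedDataset]] = {}
    for lock, group in datasets.items():
        group = list(group)
        kept = [ds for ds in group if ds.n_trials >= min_trials]
        n_excl = len(group) - len(kept)
        if n_excl:
            logger.info("%s lock: excluded %d recordings below %d trials",
                        lock, n_excl, min_trials)
        out[lock] = kept
    return out
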