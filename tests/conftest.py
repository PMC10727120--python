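import numpy as np
import pandas as pd
import pytest

from eegdyn.prep import EpochedDataset, RecordingMeta


@pytest.fixture
def meta():
    return RecordingMeta(recording_id="sub000_w15", participant="sub000",
                         age=15.2, sex="F", wave=15)


def make_trials(n, conditions=None, rts=None, responded=None, delay=450.0):
    conditions = (np.asarray(conditions) if conditions is not None
                  else np.array(["congruent_correct"] * n))
    rts = np.asarray(rts, dtype=float) if rts is not None else np.full(n, 380.0)
    responded = (np.asarray(responded, dtype=bool) if responded is not None
                 else np.ones(n, dtype=bool))
    rts = rts.copy()
    rts[~responded] = np.nan
    return pd.DataFrame({
        "condition": conditions,
        "rt_ms": rts,
        "responded": responded,
        "cue_ms": 0.0,
        "stimulus_ms": delay,
        "response_ms": delay + rts,
    })


def make_epochs(data, fs=30.0, start_ms=-700.0, lock="trial", meta_obj=None,
                **trial_kwargs):
    data = np.asarray(data, dtype=float)
    meta_obj = meta_obj or RecordingMeta("r0", "p0", 15.0, "F", 15)
    trials = make_trials(data.shape[0], **trial_kwargs)
    return EpochedDataset(data=data, fs=fs, lock=lock, start_ms=start_ms,
                          trials=trials, recording=meta_obj)


@pytest.fixture
def epochs_factory():
    return make_epochs
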