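import logging

import numpy as np
import pytest

import arousalkit as ak

# the EMG low-pass clip at 128 Hz is expected and would flood test logs
logging.getLogger("arousalkit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_config():
    return ak.RunConfig()


@pytest.fixture(scope="session")
def clean_night():
    """30-minute synthetic night with no injected events."""
    plan = ak.make_stage_plan(1800)
    spec = ak.SynthSpec(duration_s=1800, stages=plan, seed=101)
    return ak.generate(spec)


@pytest.fixture(scope="session")
def event_night():
    """30-minute synthetic night with 10 injected arousal bursts."""
    plan = ak.make_stage_plan(1800)
    hyp = ak.Hypnogram(stages=plan)
    events = ak.plan_events(hyp, 10, seed=7)
    spec = ak.SynthSpec(duration_s=1800, stages=plan, events=events, seed=7)
    rec, hyp, ledger = ak.generate(spec)
    return rec, hyp, ledger


def noise_recording(n_eeg=3, duration_s=120, fs=128, rms=20.0, seed=0, with_emg=False):
    """Plain white-noise Recording for unit tests."""
    rng = np.random.default_rng(seed)
    labels = [f"E{i}" for i in range(n_eeg)]
    roles = ["EEG"] * n_eeg
    data = [rng.standard_normal(duration_s * fs) * rms for _ in range(n_eeg)]
    if with_emg:
        labels += ["EMG1", "EMG2"]
        roles += ["EMG", "EMG"]
        data += [rng.standard_normal(duration_s * fs) * 5.0 for _ in range(2)]
    return ak.Recording(data=np.vstack(data), fs=float(fs), labels=labels, roles=roles)
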