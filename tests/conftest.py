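import numpy as np
import pytest

from pupilcouple import preproc, spectral, synth


@pytest.fixture(scope="session")
def full_subject():
    """One small full-preset synthetic subject, shared across tests."""
    return synth.make_subject("full", duration_s=120.0, n_channels=4, seed=7)


@pytest.fixture(scope="session")
def full_analysis(full_subject):
    """Preprocessed pupil + envelope stack for the shared subject."""
    trace = preproc.preprocess_pupil(
        full_subject.pupil.pupil_raw, full_subject.pupil.fs,
        saccade_times=full_subject.pupil.saccade_times,
        target_fs=full_subject.neural.fs)
    n = min(len(trace.diameter), full_subject.neural.data.shape[1])
    stack = spectral.wavelet_envelopes(
        full_subject.neural.data[:, :n], full_subject.neural.fs)
    return trace, stack, n


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
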