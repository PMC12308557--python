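import numpy as np
import pytest

import preshock as ps


@pytest.fixture(scope="session")
def clean_waveform():
    """One low-noise synthetic record with its ground truth."""
    params = ps.WaveformParams(target_hr=110, qrs_amplitude=1.5, noise_power=0.001, seed=11)
    return ps.synth_waveform(params)


@pytest.fixture(scope="session")
def preprocessed_waveform(clean_waveform):
    record, truth = clean_waveform
    return ps.preprocess(record), truth


@pytest.fixture(scope="session")
def small_cohort():
    """Ten records per class through the full waveform path."""
    return ps.synth_cohort(n_per_class=10, seed=21)


@pytest.fixture(scope="session")
def feature_sample():
    """A moderately sized feature table drawn from the class summaries."""
    X, y = ps.sample_feature_table(n_per_class=150, seed=31)
    return X, y


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_train_config():
    """Singleton grids keep classifier tests quick."""
    return ps.TrainConfig(c_grid=(10.0,), gamma_grid=(0.1,), seed=0)
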