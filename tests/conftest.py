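import numpy as np
import pytest

from emonarx.features import FEATURE_NAMES, FeatureSet
from emonarx.protocol import ProtocolConfig, generate_protocol
from emonarx.simulate import SubjectProfile, generate_recording


@pytest.fixture(scope="session")
def protocol_config():
    return ProtocolConfig()


@pytest.fixture(scope="session")
def timeline(protocol_config):
    return generate_protocol(protocol_config, seed=7)


@pytest.fixture(scope="session")
def default_profile():
    return SubjectProfile()


@pytest.fixture(scope="session")
def raw_trial(timeline, default_profile, protocol_config):
    """One synthetic analysed trial at the acquisition rate."""
    return generate_recording(timeline.analysed[0], default_profile,
                              protocol_config.fs_raw, seed=42)


@pytest.fixture(scope="session")
def preprocessed_trial(raw_trial):
    from emonarx.preprocess import preprocess_recording
    return preprocess_recording(raw_trial)


@pytest.fixture(scope="session")
def feature_set(preprocessed_trial):
    from emonarx.features import assemble_features
    return assemble_features(preprocessed_trial)


def make_feature_set(series: dict, intensity: np.ndarray, fs: float = 2.56,
                     subject: str = "S01", trial: int = 0,
                     quality: str = "Q1") -> FeatureSet:
    """FeatureSet from a handful of named series; everything else is a
    masked zero series."""
    n = intensity.shape[0]
    feats = {name: np.zeros(n) for name in FEATURE_NAMES}
    feats.update({k: np.asarray(v, dtype=float) for k, v in series.items()})
    avail = {name: (name in series) for name in FEATURE_NAMES}
    return FeatureSet(subject=subject, trial=trial, quality=quality, fs=fs,
                      features=feats, intensity=np.asarray(intensity, float),
                      available=avail)


@pytest.fixture
def linear_narx_trials():
    """7 trials from a noiseless linear NARX process on one feature."""
    from emonarx.narx import LagSpec
    from emonarx.simulate import (TrueNarxProcess,
                                  generate_intensity_from_narx,
                                  synthesize_feature_series)
    spec = LagSpec(1, ("gsr_filtered",), (1,), (2,))
    proc = TrueNarxProcess(spec, a=(0.6,), b=((0.3, 0.15),),
                           q=((0.0, 0.0),), noise_sd=0.0)
    trials = []
    for k in range(7):
        u = synthesize_feature_series(1, 260, seed=500 + k,
                                      names=["gsr_filtered"])
        y, _ = generate_intensity_from_narx(u, proc, seed=k)
        y = (y + 5.0) / 10.0  # fixed affine into [0, 1], same for all
        assert y.min() >= 0 and y.max() <= 1
        trials.append(make_feature_set({"gsr_filtered": u["gsr_filtered"]},
                                       y, trial=k))
    return spec, proc, trials
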