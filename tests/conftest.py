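import numpy as np
import pytest

from fixnov import encoding as E, synth


@pytest.fixture(scope="session")
def small_session():
    """One short synthetic session shared across tests (seeded)."""
    cfg = synth.SynthConfig(seed=11, duration_s=60.0, n_channels=3,
                            n_modulated=1)
    rec, truth = synth.generate_gaze(cfg)
    feats = synth.generate_feature_table(cfg, truth)
    return cfg, rec, truth, feats


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def basic_specs(with_novelty: bool = True):
    specs = [
        E.RegressorSpec("saccade_onset", "saccade_onset", "impulse"),
        E.RegressorSpec("fixation_onset", "fixation_onset", "impulse"),
        E.RegressorSpec("amplitude", "saccade_onset", "linear"),
        E.RegressorSpec("luminance", "fixation_onset", "linear"),
    ]
    if with_novelty:
        specs.append(E.RegressorSpec("novelty", "fixation_onset", "linear"))
    return specs
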