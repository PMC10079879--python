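import numpy as np
import pytest

from eegformer import (AttentionConfig, ConvConfig, DatasetSpec, ModelConfig,
                       RecordingSet, SimulationConfig, generate_ssvep_set,
                       segment_trials)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_cfg():
    """Smallest geometry that still exercises every stage: 3 channels,
    30-sample windows, 8 conv filters, D=8 with 2 heads, M=4."""
    return ModelConfig(S=3, L=30, n_classes=2,
                       conv=ConvConfig(n_filters=8),
                       attention=AttentionConfig(D=8, A=2, K=1, mlp_ratio=2),
                       M=4, decoder_N=4, init_seed=0)


@pytest.fixture
def toy_recordings(rng):
    """12 trials, 3 channels, 2 subjects, 2 classes, 90 samples at 100 Hz."""
    trials = [rng.standard_normal((3, 90)) for _ in range(12)]
    labels = np.arange(12) % 2
    subjects = np.repeat([0, 1], 6)
    return RecordingSet(trials, labels, subjects, ("O1", "Oz", "O2"), 100.0)


@pytest.fixture
def toy_segments(toy_recordings):
    return segment_trials(toy_recordings, ratio=0.3)  # 30-sample windows


@pytest.fixture
def overfit_ssvep():
    """64 single-window 4-class SSVEP trials at high SNR (the learning
    sanity-check conditions): 8 posterior channels, 0.4 s trials, 250 Hz."""
    spec = DatasetSpec(4, 1, 16, 8, 250.0, 0.4)
    cfg = SimulationConfig(spec=spec, stimulus_freqs=(8.0, 10.0, 12.0, 15.0),
                           noise_sd=0.1, seed=7)
    return segment_trials(generate_ssvep_set(cfg), ratio=0.4)
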