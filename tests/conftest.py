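import numpy as np
import pytest

from adenseunet import ModelConfig, PhantomConfig, make_sample


def reduced_model_config(seed: int = 0) -> ModelConfig:
    """Desk-scale network: 96px input, growth rate 8, [2,2,2,2] blocks,
    slim decoder.  Small enough to train on a CPU in seconds per step."""
    return ModelConfig(
        input_side=96,
        growth_rate_k=8,
        block_layers=[2, 2, 2, 2],
        stem_filters=32,
        decoder_channel_cap=32,
        head_width=16,
        seed=seed,
    )


def tiny_model_config(seed: int = 0) -> ModelConfig:
    """Smallest valid config (32px, k=2) for fast structural tests."""
    return ModelConfig(
        input_side=32,
        growth_rate_k=2,
        block_layers=[1, 1, 1, 1],
        stem_filters=4,
        stem_kernel=3,
        decoder_channel_cap=8,
        head_width=4,
        seed=seed,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantoms_96():
    cfg = PhantomConfig(side=96, seed=0)
    return [make_sample(cfg, i) for i in range(8)]
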