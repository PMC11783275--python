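import numpy as np
import pytest

from embddg import MockEmbedder, ModelConfig, ModelParams, ProteinSequence


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cfg():
    return ModelConfig(m=8, w=3, h=2, s=6)


@pytest.fixture
def tiny_params(tiny_cfg, rng):
    return ModelParams.init(tiny_cfg, d=5, rng=rng)


@pytest.fixture
def mock_embedder():
    return MockEmbedder(d=6, k=7, seed=42)


@pytest.fixture
def short_protein():
    return ProteinSequence("P1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")


def random_cfg_and_instance(rng, L_max=6, m_max=8):
    """A random small architecture + input for oracle comparisons."""
    h = int(rng.choice([1, 2]))
    m = int(h * rng.integers(1, m_max // h + 1))
    cfg = ModelConfig(
        m=m,
        w=int(rng.choice([1, 3, 5])),
        h=h,
        s=int(rng.integers(2, 7)),
    )
    L = int(rng.integers(1, L_max + 1))
    d = int(rng.integers(1, 6))
    params = ModelParams.init(cfg, d=d, rng=rng)
    # random biases so the all-positive/all-negative branches are exercised
    params.bc[:] = rng.standard_normal(cfg.m) * 0.5
    params.b1[:] = rng.standard_normal(cfg.s) * 0.5
    params.b2[:] = rng.standard_normal(cfg.m) * 0.5
    params.bO[...] = rng.standard_normal()
    D = rng.standard_normal((L, d))
    return cfg, params, D
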