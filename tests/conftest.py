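import numpy as np
import pytest

from clinpred.pipeline import PipelineConfig
from clinpred.synthetic import SyntheticConfig, generate, make_reference_fixture


@pytest.fixture(scope="session")
def reference_table():
    return make_reference_fixture()


@pytest.fixture(scope="session")
def noiseless_table():
    return make_reference_fixture(noiseless=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def fast_config(**overrides) -> PipelineConfig:
    """Cheap pipeline hyperparameters for tests; override as needed."""
    base = dict(
        k=5,
        n_runs=3,
        pretrain_epochs=15,
        finetune_epochs=400,
        nmf_restarts=2,
        nmf_max_iter=150,
        seed=0,
    )
    base.update(overrides)
    return PipelineConfig(**base)


def small_table(seed: int = 0, **overrides):
    """A quick-to-generate labeled table for plumbing tests."""
    base = dict(n=80, m=12, k_true=3, positive_rate=0.2,
                feature_blocks=(4, 4, 4), n_noise_features=2, seed=seed)
    base.update(overrides)
    return generate(SyntheticConfig(**base))
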