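import numpy as np
import pytest

from molfewshot import (
    EncoderConfig,
    FewShotGraphModel,
    MetaConfig,
    SyntheticSpec,
    generate_family,
    reference_loss_config,
)


@pytest.fixture(scope="session")
def small_family():
    """A small but non-trivial task family shared across fast tests."""
    spec = SyntheticSpec(n_tasks=6, n_molecules_per_task=50,
                         positive_fraction=0.2, motif_size=3, seed=42)
    return generate_family(spec)


@pytest.fixture(scope="session")
def tiny_trained(small_family):
    """A briefly meta-trained model for tests that need non-random weights."""
    fam = small_family
    model = FewShotGraphModel(
        fam.table, fam.split, k_shot=3,
        encoder_config=EncoderConfig(hidden_dim=16),
        loss_config=reference_loss_config(),
        meta_config=MetaConfig(meta_train_iterations=40, runs=2,
                               finetune_steps_at_test=30),
    )
    return model, model.fit(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
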