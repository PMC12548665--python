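import numpy as np
import pytest

from tggan.brainnet import NetworkSpec
from tggan.gan import TrainConfig, train
from tggan.prediction import rank_interleaved_split, split_dataset
from tggan.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """20 subjects, 12 nodes: enough structure for contract tests."""
    cfg = SyntheticConfig(n_subjects=20, n_nodes=12, n_signal_edges=8, seed=42)
    dataset, truth = generate_dataset(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """A briefly trained task-guided model for interface-level tests."""
    dataset, _ = tiny_dataset
    tr, va = split_dataset(dataset, rank_interleaved_split(dataset))
    cfg = TrainConfig(
        batch_size=4,
        max_epochs=8,
        critic_steps_per_gen=1,
        warmup_epochs=8,
        patience=4,
        task_alpha=0.5,
        seed=7,
    )
    return train(tr, va, NetworkSpec.small(12), cfg)
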