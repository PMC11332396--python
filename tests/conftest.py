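import numpy as np
import pytest

from milfusion.mil import MILConfig, train_mil
from milfusion.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """A desk-scale cohort config: small bags, low feature dim, strong signal."""
    return SyntheticConfig(n_cases=60, recurrence_fraction=0.3, feature_dim=16,
                           bag_size_range=(20, 40), signal_fraction_recurrence=0.25,
                           seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_mil_config() -> MILConfig:
    return MILConfig(feature_dim=16, hidden_dim=32, attention_dim=16,
                     max_epochs=15, patience=5, seed=11)


@pytest.fixture(scope="session")
def trained_tiny(tiny_cohort, tiny_mil_config):
    """A MIL model trained once on the tiny cohort, shared across tests."""
    tr = tiny_cohort.subset("train")
    bags, labels = tr.bags(), tr.labels()
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(bags))
    val, trn = idx[:10], idx[10:]
    model, history = train_mil([bags[i] for i in trn], labels[trn],
                               [bags[i] for i in val], labels[val],
                               tiny_mil_config)
    return model, history
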