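import numpy as np
import pytest

from cd4imm import synthetic
from cd4imm.nnalign import Hyperparams, cross_validate


@pytest.fixture(scope="session")
def planted_small():
    """Small planted-motif dataset: 120+120 15-mers, 9-mer core, strength 0.9."""
    return synthetic.generate_labeled_dataset(120, 120, seed=11)


@pytest.fixture(scope="session")
def fast_hp():
    """Reduced training budget for unit tests."""
    return Hyperparams(max_epochs=120, patience=25)


@pytest.fixture(scope="session")
def cv_small(planted_small, fast_hp):
    """Cross-validation of a reduced ensemble on the small planted set."""
    return cross_validate(planted_small, L=9, n_seeds=2, hyperparams=fast_hp, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
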