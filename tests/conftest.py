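import numpy as np
import pytest

from amidyn import synth
from amidyn.mfa import DiffusionTensor


@pytest.fixture(scope="session")
def planted_tensor() -> DiffusionTensor:
    return DiffusionTensor(1.2e7, 1.4e7, 1.9e7, 35.0)


@pytest.fixture(scope="session")
def small_truth(planted_tensor):
    """A 30-residue synthetic dimer used by the cheaper fitting tests."""
    return synth.default_ground_truth(n_residues=30, tensor=planted_tensor, seed=42)


@pytest.fixture(scope="session")
def clean_records(small_truth):
    return synth.simulate_observables(small_truth, noise_frac=0.0)


@pytest.fixture(scope="session")
def toy_dimer():
    return synth.make_toy_dimer(12)


@pytest.fixture()
def rng():
    return np.random.default_rng(20221116)
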