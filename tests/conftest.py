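import numpy as np
import pytest

from kmersig.dataset_io import make_plan
from kmersig.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_dataset():
    """A tiny dense synthetic dataset (20 drugs x 6 targets, 120 pairs)."""
    spec = SyntheticSpec(
        n_drugs=20, n_targets=6, density=1.0,
        mol_len_mean=40, mol_len_range=(20, 80),
        prot_len_mean=240, prot_len_range=(215, 400),
        seed=7,
    )
    table, truth = generate(spec)
    return table, truth, spec


@pytest.fixture(scope="session")
def small_plan(small_dataset):
    table, _, _ = small_dataset
    return make_plan(table, seed=7)
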