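import numpy as np
import pytest

from cscpair.synthetic import generate_lr_db, generate_planted_dataset


@pytest.fixture(scope="session")
def recovery_fixture():
    """Moderate-noise planted dataset: 2 pairs, 50 cells/subgroup,
    10 genes/block, signal/baseline = 4, NB dispersion 5."""
    return generate_planted_dataset(
        K=2, cells_per_subgroup=50, genes_per_block=10,
        signal=8.0, baseline=2.0, dispersion=5.0, seed=7,
    )


@pytest.fixture(scope="session")
def noisy_fixture():
    """Hard regime where single runs recover structure only partially;
    used for the stability and coupling-perturbation experiments."""
    return generate_planted_dataset(
        K=2, cells_per_subgroup=30, genes_per_block=6,
        signal=3.0, baseline=1.0, dispersion=3.0, seed=42,
    )


@pytest.fixture(scope="session")
def noiseless_fixture():
    """Zero-noise limit with disjoint blocks (small-instance oracle)."""
    return generate_planted_dataset(
        K=2, cells_per_subgroup=3, genes_per_block=2,
        signal=6.0, baseline=0.0, noiseless=True, seed=0,
    )


@pytest.fixture(scope="session")
def sparse_fixture():
    """Sparse-baseline fixture for the masked-sampling experiment: a
    20%-masked subgroup falls below the 20% detection-fraction rule at
    cell-type level."""
    return generate_planted_dataset(
        K=2, cells_per_subgroup=50, genes_per_block=10,
        signal=5.0, baseline=0.02, dispersion=10.0, seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_lr_db():
    return generate_lr_db(12, seed=42)
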