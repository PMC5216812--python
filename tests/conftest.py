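import numpy as np
import pytest

from vmquant.expression import CountMatrix
from vmquant.synthetic_data import (
    SyntheticCohortSpec,
    SyntheticImageSpec,
    generate_expression_cohort,
    generate_vm_image,
)


@pytest.fixture(scope="session")
def default_image():
    return generate_vm_image(SyntheticImageSpec(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    spec = SyntheticCohortSpec(
        n_samples=120,
        n_genes=300,
        n_contaminated=10,
        library_size_mean=200_000,
        seed=11,
    )
    return spec, generate_expression_cohort(spec)


@pytest.fixture()
def tiny_counts():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(8)]
    samples = [f"s{i}" for i in range(5)]
    return CountMatrix(genes, samples, rng.integers(0, 100, (8, 5)).astype(float))
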