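import numpy as np
import pytest

from orthoflux.fba import BiomassAugmentation
from orthoflux.synthetic import (
    ProteomeSimConfig,
    ToyModelConfig,
    generate_toy_model,
    simulate_proteomes,
)


@pytest.fixture(scope="session")
def chain_model():
    """Single branch, capacity 10, yield 0.5: WT growth 5.0, unique fluxes."""
    model, growth = generate_toy_model(
        ToyModelConfig(n_branches=1, capacities=(10.0,), yields_=(0.5,))
    )
    return model, growth


@pytest.fixture(scope="session")
def two_branch_model():
    """Two substrate routes, capacities 10 and 4, yield 1: WT growth 14.0."""
    model, growth = generate_toy_model(ToyModelConfig())
    return model, growth


@pytest.fixture(scope="session")
def cofactor_model():
    """Two branches + cofactor branch behind a two-gene AND complex."""
    model, growth = generate_toy_model(
        ToyModelConfig(include_cofactor_branch=True)
    )
    return model, growth


@pytest.fixture(scope="session")
def ribose_model():
    """Carbon branches + essential 'isomerase' ribose branch."""
    model, growth = generate_toy_model(
        ToyModelConfig(
            include_ribose_branch=True,
            include_cofactor_branch=True,
            ribose_capacity=5.0,
            ribose_coefficient=0.1,
        )
    )
    return model, growth


@pytest.fixture(scope="session")
def cofactor_augmentation():
    return BiomassAugmentation(requirements={"COF": 0.0005})


@pytest.fixture(scope="session")
def planted_proteomes():
    """Five planted pairs, no decoys, sites preserved."""
    return simulate_proteomes(
        ProteomeSimConfig(seed=7, n_pairs=5, n_paralogs=0)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
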