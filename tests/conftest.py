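import numpy as np
import pytest

from ddapre.fixtures import (
    FixtureSpec,
    make_planted_dataset,
    make_toy_mesh,
    make_toy_smiles,
)


@pytest.fixture(scope="session")
def toy_drugs():
    return make_toy_smiles(20, seed=11)


@pytest.fixture(scope="session")
def toy_diseases():
    return make_toy_mesh(30, depth=3, branching=3, seed=11)


@pytest.fixture(scope="session")
def planted():
    """Default-scale planted dataset: 27 x 60 pairs, 11.4% positive,
    five informative dimensions at effect size 3."""
    return make_planted_dataset(FixtureSpec(seed=101))


@pytest.fixture(scope="session")
def planted_null():
    """Same shape with zero effect size: no recoverable signal."""
    return make_planted_dataset(FixtureSpec(effect_size=0.0, seed=101))
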