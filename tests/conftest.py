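import numpy as np
import pytest

from exp2sl.labels import SLLabelSet, assemble_dataset, label_pairs
from exp2sl.synthetic import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def small_spec():
    # reduced landmark dimension keeps unit tests fast; structure is unchanged
    return FixtureSpec(n_genes=30, n_plates=3, n_landmark=60, seed=11)


@pytest.fixture(scope="session")
def small_fixture(small_spec):
    return generate_fixture(small_spec)


@pytest.fixture(scope="session")
def small_labels(small_fixture):
    pos, neg = label_pairs(small_fixture["scores"])
    universe = set(small_fixture["signatures"].index)
    return assemble_dataset(SLLabelSet(pos, neg, universe), small_fixture["signatures"])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
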