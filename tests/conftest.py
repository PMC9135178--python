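import pytest

from metnc.chem import default_ruleset
from metnc.evaluation import PairDataset
from metnc.fixtures import FixtureSpec, builtin_toy_pairs, make_randomized_dataset


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture(scope="session")
def toy_pairs():
    return builtin_toy_pairs()


@pytest.fixture(scope="session")
def planted_ester_dataset(ruleset):
    """50 pairs, all planted through ester-category rules (seed 7)."""
    spec = FixtureSpec(seed=7, n_pairs=50, category_mix={"esters": 1.0})
    return make_randomized_dataset(spec, ruleset)


@pytest.fixture(scope="session")
def five_pair_dataset(toy_pairs):
    """A small mixed-category slice for exhaustive equivalence checks."""
    return PairDataset(pairs=toy_pairs.pairs[:5])
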