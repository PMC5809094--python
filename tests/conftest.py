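import numpy as np
import pytest

from phylocomp.interactions import InteractionTimeline
from phylocomp.synth import make_fixture_bank, sim_tree
from phylocomp.tree import read_tree


@pytest.fixture(scope="session")
def tree3():
    """((A:1,B:1):1,C:2); -- the smallest nontrivial ultrametric tree."""
    return read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def tree6():
    return read_tree(
        "(((A:1,B:1):1,(C:1.5,D:1.5):0.5):1,(E:2,F:2):1);"
    )


@pytest.fixture(scope="session")
def tree50():
    """Random 50-tip pure-birth tree, crown age 25 My."""
    return sim_tree(0.3, 0.0, 50, seed=101)


@pytest.fixture(scope="session")
def tree50_symp(tree50):
    return InteractionTimeline.full_sympatry(tree50)


@pytest.fixture(scope="session")
def study_tiny():
    return make_fixture_bank("tiny", seed=1)


@pytest.fixture(scope="session")
def study_standard():
    return make_fixture_bank("standard", seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
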