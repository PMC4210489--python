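import dendropy
import pytest

from divshift.episodic import EpisodicBDModel
from divshift.simulate import SimulationRecipe, make_study_fixture
from divshift.trees import Chronogram


def chronogram_from_newick(newick: str, **kwargs) -> Chronogram:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return Chronogram(tree, **kwargs)


@pytest.fixture
def three_tip() -> Chronogram:
    """((A:1,B:1):1,C:2); — crown age 2, branching times (2, 1)."""
    return chronogram_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip() -> Chronogram:
    return chronogram_from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture(scope="session")
def constant_rate_recipe() -> SimulationRecipe:
    """Constant-rate birth-death truth: lam=0.10, mu=0.05, crown 60, rho=1."""
    return SimulationRecipe(
        model=EpisodicBDModel(lam=(0.10,), mu=(0.05,)), crown_age=60.0, rho=1.0, seed=77
    )


@pytest.fixture(scope="session")
def study_fixture():
    """50-replicate study-scale fixture (crown 180, shift at 103 Ma, rho=0.0187)."""
    return make_study_fixture(seed=2014, n_trees=50)
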