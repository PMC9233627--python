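import numpy as np
import pytest

from cpgjump.experiments import generate_fixture_tree
from cpgjump.phylo_io import Phylogeny
from cpgjump.substitution_model import CpGModelParams

PHI = (0.3, 0.2, 0.2, 0.3)


@pytest.fixture(scope="session")
def phi():
    return PHI


@pytest.fixture(scope="session")
def tiny_tree():
    return Phylogeny.from_newick("((A:0.1,B:0.15):0.2,C:0.3);")


@pytest.fixture(scope="session")
def small_tree():
    """6-tip Yule fixture, total length 1.5."""
    return generate_fixture_tree(6, 1.5, np.random.default_rng(4321))


@pytest.fixture(scope="session")
def ten_tip_tree():
    return generate_fixture_tree(10, 2.0, np.random.default_rng(7))


def make_params(**kw):
    base = dict(phi=PHI, kappa=4.0, lam=1.0, omega=0.5)
    base.update(kw)
    return CpGModelParams(**base)


@pytest.fixture
def params_factory():
    return make_params
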