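import numpy as np
import pandas as pd
import pytest

from canidmacro import ModelSpec, as_phylo_data
from canidmacro.simulate import SimulationConfig, simulate_tree, simulate_trait


@pytest.fixture(scope="session")
def bd_tree60():
    """60-tip birth-death tree with extinct tips (non-ultrametric)."""
    tree, history = simulate_tree(SimulationConfig(seed=5, n_tips=60))
    return tree, history


@pytest.fixture(scope="session")
def bd_tree100():
    tree, _ = simulate_tree(SimulationConfig(seed=11, n_tips=100))
    return tree


@pytest.fixture(scope="session")
def yule_tree128():
    """128-tip pure-birth tree (all tips extant, ultrametric)."""
    tree, _ = simulate_tree(SimulationConfig(seed=7, n_tips=128, death_rate=0.0))
    return tree


@pytest.fixture(scope="session")
def tree6():
    """Small fixed 6-tip non-ultrametric tree for dense-algebra oracles."""
    return as_phylo_data("(((A:1.5,B:2.5):2,(C:1,D:4):1.5):1,(E:2,F:6.5):2.5);")


@pytest.fixture
def bm_trait60(bd_tree60):
    tree, _ = bd_tree60
    return simulate_trait(tree, ModelSpec("BM", {"z0": 0.0, "sigma2": 0.05}), seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
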