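import numpy as np
import pandas as pd
import pytest

from cflung.geometry import build_tree, load_default_tree
from cflung.model import SimParams, simulate


def make_toy_tree(n_generations: int, d0: float = 8.0, L0: float = 16.0,
                  shrink: float = 0.7):
    """Small geometric test tree: dimensions shrink by a constant factor."""
    gens = np.arange(n_generations)
    return build_tree(pd.DataFrame({
        "generation": gens,
        "diameter_mm": d0 * shrink ** gens,
        "length_mm": L0 * shrink ** gens,
    }))


@pytest.fixture(scope="session")
def default_tree():
    return load_default_tree()


@pytest.fixture(scope="session")
def toy_tree4():
    return make_toy_tree(4)


@pytest.fixture(scope="session")
def table1_params():
    """The fitted model constants, package defaults, fixed test seed."""
    return SimParams(seed=20210, horizon=600)


@pytest.fixture(scope="session")
def table1_trajectories(default_tree, table1_params):
    """20 replicates of the full disease course at the fitted parameters.

    Shared across the acceptance and registry tests; the dominant cost of
    the suite, computed once.
    """
    return simulate(table1_params, default_tree, n_replicates=20)
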