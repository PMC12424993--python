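import numpy as np
import pytest

import treeharmonize as th


def random_tree(rng: np.random.Generator, n_leaves: int) -> th.Phylogeny:
    """Random binary tree over labels L0..L{n-1} via random joins."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return th.Phylogeny.from_newick(nodes[0] + ";")


@pytest.fixture(scope="session")
def balanced4() -> th.Phylogeny:
    return th.Phylogeny.from_newick("((A,B),(C,D));")


@pytest.fixture(scope="session")
def caterpillar3() -> th.Phylogeny:
    return th.Phylogeny.from_newick("((A,B),C);")


@pytest.fixture(scope="session")
def bundle() -> th.SimBundle:
    """Default-condition synthetic bundle shared across tests."""
    return th.simulate(th.SimConfig(seed=11, n_snvs=800, n_svs=60))


@pytest.fixture(scope="session")
def worked_example() -> th.SimBundle:
    return th.make_worked_example()
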