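import numpy as np
import pandas as pd
import pytest

from paleopcs.simulate import Scenario, generate_fixture_bundle
from paleopcs.tree import Tree, read_tree


@pytest.fixture
def toy_tree() -> Tree:
    """((A:1,B:1):2,C:3); — ultrametric, depth 3."""
    return read_tree("((A:1,B:1):2,C:3);")


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Small filtering-scenario bundle shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    sc = Scenario(seed=11)
    objs = generate_fixture_bundle(sc, out)
    objs["dir"] = out
    objs["scenario"] = sc
    return objs


def random_dated_tree(n_tips: int, rng: np.random.Generator) -> Tree:
    """Random coalescent-style dated tree built by successive joins."""
    from paleopcs.tree import Node

    nodes = [Node(label=f"x{i}", age=0.0) for i in range(n_tips)]
    age = 0.0
    while len(nodes) > 1:
        age += rng.exponential(1.0)
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(age=age)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return Tree(nodes[0])


def brute_force_patristic(tree: Tree) -> pd.DataFrame:
    """Path-sum oracle: distances via explicit root paths, independent of the
    package's cophenetic implementation."""
    leaves = tree.leaves()

    def path_to_root(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    labels = [l.label for l in leaves]
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        pi = path_to_root(leaves[i])
        set_i = {id(x) for x in pi}
        for j in range(i + 1, n):
            pj = path_to_root(leaves[j])
            mrca = next(x for x in pj if id(x) in set_i)
            d = (mrca.age - leaves[i].age) + (mrca.age - leaves[j].age)
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)
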