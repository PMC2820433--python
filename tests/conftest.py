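import random

import pytest

from treescope import PhyloNode, parse_newick, populate_random
from treescope.newick import FLEXIBLE


def random_tree(seed, n_leaves=None, min_leaves=4, max_leaves=50,
                randomize_dists=True, randomize_supports=False):
    """Seeded random binary tree with optional random branch lengths."""
    rng = random.Random(seed)
    if n_leaves is None:
        n_leaves = rng.randint(min_leaves, max_leaves)
    tree = populate_random(n_leaves, seed=rng.randrange(2 ** 31))
    if randomize_dists:
        for node in tree.traverse("preorder"):
            node.dist = rng.uniform(0.05, 3.0)
    if randomize_supports:
        for node in tree.traverse("preorder"):
            node.support = round(rng.uniform(0.0, 1.0), 6)
    return tree


def caterpillar(n_leaves, name_prefix="L"):
    """Fully unbalanced tree built iteratively (2*n_leaves - 1 nodes)."""
    from treescope import TreeNode
    root = TreeNode()
    cur = root
    for i in range(n_leaves - 1):
        leaf = TreeNode(name=f"{name_prefix}{i}")
        nxt = TreeNode()
        cur.children = [leaf, nxt]
        leaf.up = cur
        nxt.up = cur
        cur = nxt
    cur.name = f"{name_prefix}{n_leaves - 1}"
    return root


@pytest.fixture
def quartet():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);", FLEXIBLE)


@pytest.fixture
def gene_tree_3():
    """The normative 3-leaf gene tree with one hidden loss."""
    t = parse_newick("(HSA_a:1,(HSA_b:1,MMU_b:1):1);", FLEXIBLE,
                     node_class=PhyloNode)
    from treescope import assign_species
    assign_species(t)
    return t


@pytest.fixture
def species_tree_2():
    return parse_newick("(HSA:1,MMU:1);", FLEXIBLE)
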