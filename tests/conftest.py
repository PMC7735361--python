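"""Shared fixtures: toy trees, random simulated trees, GLMM datasets."""

from __future__ import annotations

import numpy as np
import pytest

from dinodiv import pathstats, synthetic, trees


@pytest.fixture
def toy_tree():
    """((A:1,B:1):1,C:2); — all root-to-tip distances 2.0."""
    return trees.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def random_trees():
    """100 random birth-death trees of assorted sizes (dated, with ages)."""
    out = []
    for s in range(200):
        cfg = synthetic.BDSimConfig(
            lambda0=0.12, mu=0.03, k=0.0, duration=30.0, seed=s
        )
        t = synthetic.simulate_bd_tree(cfg)
        if t is not None and trees.n_tips(t) >= 4:
            out.append(t)
        if len(out) == 100:
            break
    assert len(out) == 100
    return out


@pytest.fixture(scope="session")
def recovery_dataset():
    """A ~100-tip dated tree with its path-stat table and VCV."""
    tree = synthetic.simulate_bd_tree_retrying(
        synthetic.BDSimConfig(lambda0=0.11, mu=0.02, duration=50.0, seed=11),
        min_tips=90,
        max_tips=130,
    )
    table = pathstats.extract_table(tree)
    A = pathstats.phylo_vcv(tree).matrix
    return tree, table, A


# ---------------------------------------------------------------------------
# independent oracles (deliberately written over raw child pointers /
# pairwise scans, not via the package's own path routines)


def oracle_node_count(tree, taxon: str) -> int:
    """Count internal nodes on the root-to-tip path via recursive descent."""

    def descend(node, depth):
        if node.is_leaf():
            lab = node.taxon.label if node.taxon is not None else node.label
            return depth if lab == taxon else None
        for c in node.child_nodes():
            hit = descend(c, depth + 1)
            if hit is not None:
                return hit
        return None

    got = descend(tree.seed_node, 0)
    assert got is not None, f"tip {taxon!r} not found"
    return got


def oracle_vcv(tree):
    """Pairwise shared-path computation: for each tip pair, sum the branch
    lengths of the edges both root-to-tip paths traverse."""

    def path_edges(leaf):
        out = []
        nd = leaf
        while nd.parent_node is not None:
            out.append((id(nd), nd.edge.length))
            nd = nd.parent_node
        return dict(out)

    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label if lf.taxon else lf.label for lf in leaves]
    paths = [path_edges(lf) for lf in leaves]
    n = len(leaves)
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            shared = set(paths[i]) & set(paths[j])
            A[i, j] = A[j, i] = sum(paths[i][e] for e in shared)
    return labels, A
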