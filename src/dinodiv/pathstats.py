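"""Per-tip path statistics and the phylogenetic covariance structure.

The diversification-rate test regresses, for every tip of a dated tree,
the number of splitting events between the root and that tip (the "node
count", a proxy for cumulative speciation along the lineage) on the
root-to-tip distance in Myr (the "time elapsed").  Because closely
related tips share most of their root-to-tip path, their node counts are
correlated; the shared path lengths form the phylogenetic
variance-covariance matrix A used as the random-effect structure in the
GLMM:

    A[i, j] = path length (Myr) from the root to the MRCA of tips i, j
    A[i, i] = root-to-tip distance of tip i

Node-count convention: the root is counted and the tip is not, so a tip
hanging directly off the root has node count 1 (the tree's root node is
itself one splitting event).  ``include_tip=True`` gives the alternative
both-endpoints convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import trees as _trees
from .trees import PhyloTree

__all__ = [
    "TipPathStats",
    "PhyloCovariance",
    "node_count",
    "time_elapsed",
    "phylo_vcv",
    "extract_stats",
    "extract_table",
    "taxon_order",
]


@dataclass(frozen=True)
class TipPathStats:
    """Node count and time elapsed for one tip — the GLMM response/covariate pair."""

    taxon: str
    node_count: int
    time_elapsed: float


@dataclass
class PhyloCovariance:
    """Phylogenetic VCV with its taxon ordering.

    ``matrix`` is symmetric positive semi-definite with
    ``A_ii >= A_ij >= 0``.  When built with ``scale=True`` the matrix is
    divided by the maximum root-to-tip depth so the deepest tip has unit
    variance.
    """

    taxa: list[str]
    matrix: np.ndarray
    scaled: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)


def taxon_order(tree: PhyloTree) -> list[str]:
    """The tip ordering shared by :func:`extract_table` and :func:`phylo_vcv`."""
    return _trees.tip_labels(tree)


def _find_tip(tree: PhyloTree, taxon: str):
    for leaf in tree.leaf_node_iter():
        if _trees._leaf_label(leaf) == taxon:
            return leaf
    raise KeyError(f"unknown tip label: {taxon!r}")


def node_count(tree: PhyloTree, taxon: str, include_tip: bool = False) -> int:
    """Number of internal nodes on the root-to-tip path (root included).

    Equivalently the number of cladogenetic events a lineage has passed
    through; multifurcating nodes count once, like bifurcations.  The
    minimum is 1 (a tip that is a direct child of the root).
    """
    leaf = _find_tip(tree, taxon)
    n = 0
    nd = leaf.parent_node
    while nd is not None:
        n += 1
        nd = nd.parent_node
    return n + 1 if include_tip else n


def time_elapsed(tree: PhyloTree, taxon: str) -> float:
    """Root-to-tip distance in Myr (sum of branch lengths on the path)."""
    leaf = _find_tip(tree, taxon)
    total = 0.0
    nd = leaf
    while nd.parent_node is not None:
        if nd.edge.length is None:
            raise ValueError(
                f"unset branch length on the path to {taxon!r}; tree must be dated"
            )
        total += nd.edge.length
        nd = nd.parent_node
    return total


def phylo_vcv(tree: PhyloTree, scale: bool = False) -> PhyloCovariance:
    """Phylogenetic variance-covariance matrix of the tree's tips.

    Computed in one postorder pass: each internal node at depth d (root
    distance in Myr) contributes d as the covariance of every tip pair
    whose MRCA it is.
    """
    taxa = taxon_order(tree)
    index = {lab: i for i, lab in enumerate(taxa)}
    n = len(taxa)
    A = np.zeros((n, n))

    depth: dict[int, float] = {}
    below: dict[int, list[int]] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[id(nd)] = 0.0
        else:
            bl = nd.edge.length
            if bl is None:
                raise ValueError("tree must have branch lengths set on every edge")
            depth[id(nd)] = depth[id(nd.parent_node)] + bl
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            i = index[_trees._leaf_label(nd)]
            A[i, i] = depth[id(nd)]
            below[id(nd)] = [i]
        else:
            groups = [below[id(c)] for c in nd.child_nodes()]
            d = depth[id(nd)]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i in groups[gi]:
                        A[i, groups[gj]] = d
                        A[np.asarray(groups[gj]), i] = d
            below[id(nd)] = [i for g in groups for i in g]
    if scale:
        mx = A.diagonal().max()
        if mx <= 0:
            raise ValueError("cannot scale a zero-depth tree")
        A = A / mx
    return PhyloCovariance(taxa=taxa, matrix=A, scaled=scale)


def extract_stats(tree: PhyloTree, include_tip: bool = False) -> list[TipPathStats]:
    """Per-tip (node count, time elapsed) rows in :func:`taxon_order` order."""
    rows = []
    for leaf in tree.leaf_node_iter():
        lab = _trees._leaf_label(leaf)
        # walk once instead of re-searching per taxon
        n, t = 0, 0.0
        nd = leaf
        while nd.parent_node is not None:
            if nd.edge.length is None:
                raise ValueError(f"unset branch length on the path to {lab!r}")
            t += nd.edge.length
            n += 1
            nd = nd.parent_node
        rows.append(
            TipPathStats(taxon=lab, node_count=n + 1 if include_tip else n, time_elapsed=t)
        )
    return rows


def extract_table(tree: PhyloTree, include_tip: bool = False) -> pd.DataFrame:
    """DataFrame with columns ``taxon, node_count, time_elapsed``.

    Row order matches the taxon ordering of :func:`phylo_vcv`, so the
    table and the VCV can be passed straight to the GLMM.
    """
    rows = extract_stats(tree, include_tip=include_tip)
    return pd.DataFrame(
        {
            "taxon": [r.taxon for r in rows],
            "node_count": [r.node_count for r in rows],
            "time_elapsed": [r.time_elapsed for r in rows],
        }
    )
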