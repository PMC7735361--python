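"""Tree containers and Newick I/O shared by every pipeline stage.

Trees are rooted :class:`dendropy.Tree` objects with branch lengths in
Myr.  Dated trees additionally carry a node age in Ma (before present,
older = larger) on every node as ``node.age``, with the convention

    branch length = parent age - child age.

This module owns the parsing / serialisation conventions: labels are
taken literally (underscores are never converted to spaces, so taxon
names match age tables byte-for-byte), internal node labels are retained
but unused, multifurcations are preserved, and child order carries no
meaning — tree equality is defined up to child permutation.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Optional

import dendropy

__all__ = [
    "PhyloTree",
    "TaxonAgeRange",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "read_newick",
    "tips",
    "tip_labels",
    "n_tips",
    "n_internal",
    "isomorphic",
    "validate_tree",
    "has_node_ages",
]

#: The tree type used throughout the package.
PhyloTree = dendropy.Tree


class NewickParseError(ValueError):
    """Malformed Newick input (position reported when known)."""


class TreeValidationError(ValueError):
    """A parsed tree violates a structural invariant."""


@dataclass(frozen=True)
class TaxonAgeRange:
    """Stratigraphic age bounds for one taxon.

    ``max_age`` is the older bound and ``min_age`` the younger bound,
    both in Ma before present (so max_age >= min_age >= 0).  These
    emulate first/last appearance data: the taxon's true age lies
    somewhere in the interval.
    """

    taxon: str
    max_age: float
    min_age: float

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValueError("taxon label must be non-empty")
        if not (self.max_age >= self.min_age >= 0.0):
            raise ValueError(
                f"invalid age range for {self.taxon!r}: "
                f"need max_age >= min_age >= 0, got "
                f"[{self.min_age}, {self.max_age}]"
            )


# ---------------------------------------------------------------------------
# parsing / writing


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted tree from a Newick string.

    Branch lengths are preserved exactly as written; multifurcations and
    internal node labels are kept.  Raises :class:`NewickParseError` on
    malformed input and :class:`TreeValidationError` on duplicate or
    empty tip labels or negative branch lengths.
    """
    if not isinstance(text, str):
        raise TypeError("expected a Newick string")
    if ";" not in text:
        raise NewickParseError(
            f"missing ';' terminator (input ends at position {len(text)})"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise TreeValidationError(f"duplicate tip label: {exc}") from exc
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    validate_tree(tree)
    return tree


def read_newick(path) -> list[PhyloTree]:
    """Read one or more trees (one per line / per tree statement) from a file."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    trees = []
    buf = ""
    for chunk in text.split(";"):
        buf += chunk
        if buf.strip():
            trees.append(parse_newick(buf + ";"))
        buf = ""
    return trees


def write_newick(tree: PhyloTree) -> str:
    """Serialise a tree to Newick with lossless branch lengths.

    Branch lengths are rendered with 17 significant digits so that a
    parse/write round trip is exact at double precision.
    """
    s = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    )
    return s.strip() + "\n"


# ---------------------------------------------------------------------------
# structure helpers


def tips(tree: PhyloTree) -> list:
    """Leaf nodes in a stable traversal order (the order used for tables/VCV)."""
    return list(tree.leaf_node_iter())


def tip_labels(tree: PhyloTree) -> list[str]:
    return [_leaf_label(leaf) for leaf in tree.leaf_node_iter()]


def _leaf_label(leaf) -> str:
    if leaf.taxon is not None and leaf.taxon.label:
        return leaf.taxon.label
    return leaf.label or ""


def n_tips(tree: PhyloTree) -> int:
    return sum(1 for _ in tree.leaf_node_iter())


def n_internal(tree: PhyloTree) -> int:
    return sum(1 for nd in tree.preorder_node_iter() if not nd.is_leaf())


def has_node_ages(tree: PhyloTree) -> bool:
    return all(getattr(nd, "age", None) is not None for nd in tree.preorder_node_iter())


def validate_tree(tree: PhyloTree) -> None:
    """Check structural invariants; raise :class:`TreeValidationError` if violated.

    - tip labels unique and non-empty,
    - branch lengths (when set) finite and >= 0,
    - node ages (when set everywhere) consistent with branch lengths.
    """
    labels = tip_labels(tree)
    if any(not lab for lab in labels):
        raise TreeValidationError("empty tip label")
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise TreeValidationError(f"duplicate tip label: {lab!r}")
        seen.add(lab)
    for nd in tree.preorder_node_iter():
        bl = nd.edge.length
        if bl is not None and (not math.isfinite(bl) or bl < 0):
            raise TreeValidationError(
                f"invalid branch length {bl!r} above node {_node_repr(nd)}"
            )
    if has_node_ages(tree):
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            dur = nd.parent_node.age - nd.age
            if dur < -1e-9:
                raise TreeValidationError(
                    f"child older than parent at {_node_repr(nd)}"
                )
            if nd.edge.length is not None and abs(nd.edge.length - dur) > 1e-6:
                raise TreeValidationError(
                    f"branch length inconsistent with ages at {_node_repr(nd)}"
                )


def _node_repr(nd) -> str:
    if nd.is_leaf():
        return _leaf_label(nd)
    return nd.label or f"<internal, {sum(1 for _ in nd.leaf_iter())} tips>"


# ---------------------------------------------------------------------------
# isomorphism (clade-based, rooted, tolerant on branch lengths)


def _clade_map(tree: PhyloTree) -> dict[frozenset, Optional[float]]:
    """Map each node's descendant-tip set to its parent branch length."""
    out: dict[frozenset, Optional[float]] = {}
    below: dict[int, frozenset] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            cl = frozenset([_leaf_label(nd)])
        else:
            cl = frozenset().union(*(below[id(c)] for c in nd.child_nodes()))
        below[id(nd)] = cl
        if cl in out:
            raise TreeValidationError("repeated clade (unifurcation?)")
        out[cl] = nd.edge.length if nd.parent_node is not None else None
    return out


def isomorphic(a: PhyloTree, b: PhyloTree, tol: float = 1e-9) -> bool:
    """True if the rooted trees share topology and branch lengths to ``tol``.

    Child order is ignored; a clade is identified by its descendant tip
    set.  Unset branch lengths only match unset branch lengths.
    """
    ca, cb = _clade_map(a), _clade_map(b)
    if set(ca) != set(cb):
        return False
    for clade, la in ca.items():
        lb = cb[clade]
        if (la is None) != (lb is None):
            return False
        if la is not None and abs(la - lb) > tol:
            return False
    return True
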