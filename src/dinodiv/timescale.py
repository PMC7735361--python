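"""Stochastic time-scaling of undated cladograms from taxon age ranges.

A fossil cladogram has topology but no branch durations.  The dating
protocol implemented here:

1. draw each taxon's age uniformly between its stratigraphic bounds
   (:func:`sample_taxon_ages`);
2. place each tip at its sampled age and each internal node at the age
   of its oldest descendant tip (:func:`date_tree_basic`) — this yields
   zero-length branches wherever a node's age coincides with a child's;
3. lengthen sub-minimum branches by pushing ancestral nodes older, never
   moving tips, until every branch lasts at least ``mbl`` Myr
   (:func:`enforce_mbl`, default minimum 1 Myr).

Because step 1 is random, :func:`date_ensemble` repeats the procedure
(default 100 replicates, seeds ``base + r``) to propagate age
uncertainty into every downstream statistic.  Pushing nodes older can
inflate the root age past the oldest possible taxon age;
:func:`root_age_diagnostic` quantifies that inflation.

Ages are in Ma before present (older = larger); branch length = parent
age - child age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import trees as _trees
from .trees import PhyloTree, TaxonAgeRange

__all__ = [
    "DatingConfig",
    "RootAgeDiagnostic",
    "sample_taxon_ages",
    "date_tree_basic",
    "enforce_mbl",
    "date_ensemble",
    "root_age_diagnostic",
    "read_age_ranges",
    "write_age_ranges",
]


@dataclass(frozen=True)
class DatingConfig:
    """Dating protocol knobs: minimum branch duration, replicates, seeding."""

    mbl: float = 1.0
    replicates: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.mbl <= 0:
            raise ValueError("mbl must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class RootAgeDiagnostic:
    """Root-age inflation report: how far dating pushed the root past the
    oldest possible taxon age."""

    root_age: float
    oldest_max_age: float
    difference: float
    threshold: float
    flagged: bool


def sample_taxon_ages(
    ranges: Sequence[TaxonAgeRange], seed: Optional[int] = None
) -> dict[str, float]:
    """Draw one age per taxon, Uniform(min_age, max_age)."""
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for r in ranges:
        out[r.taxon] = float(rng.uniform(r.min_age, r.max_age)) if r.max_age > r.min_age else r.min_age
    return out


def date_tree_basic(tree: PhyloTree, tip_ages: Mapping[str, float]) -> PhyloTree:
    """Date a cladogram: tips at their sampled ages, nodes at their oldest
    descendant tip's age, branch lengths from age differences.

    Zero-length branches are expected wherever a node and its oldest
    child coincide; run :func:`enforce_mbl` afterwards.
    """
    dated = tree.clone(depth=1)
    for nd in dated.postorder_node_iter():
        if nd.is_leaf():
            lab = _trees._leaf_label(nd)
            if lab not in tip_ages:
                raise KeyError(f"no sampled age for taxon {lab!r}")
            nd.age = float(tip_ages[lab])
        else:
            nd.age = max(c.age for c in nd.child_nodes())
    _set_lengths_from_ages(dated)
    return dated


def enforce_mbl(tree: PhyloTree, mbl: float = 1.0) -> PhyloTree:
    """Raise ancestral node ages until every branch lasts at least ``mbl``.

    One postorder pass: each internal node's age becomes
    ``max(current age, max(child age + mbl))``.  Tips never move, node
    ages never decrease, topology is untouched, and the pass is
    idempotent on trees that already satisfy the minimum.
    """
    if mbl <= 0:
        raise ValueError("mbl must be > 0")
    out = tree.clone(depth=1)
    for nd in out.postorder_node_iter():
        if nd.is_leaf():
            if getattr(nd, "age", None) is None:
                raise ValueError("enforce_mbl needs a dated tree (node ages set)")
            continue
        nd.age = max(
            getattr(nd, "age", -np.inf),
            max(c.age for c in nd.child_nodes()) + mbl,
        )
    _set_lengths_from_ages(out)
    return out


def _set_lengths_from_ages(tree: PhyloTree) -> None:
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = nd.parent_node.age - nd.age
        else:
            nd.edge.length = None


def date_ensemble(
    tree: PhyloTree,
    ranges: Sequence[TaxonAgeRange],
    config: DatingConfig | None = None,
) -> list[PhyloTree]:
    """Full dating protocol repeated ``config.replicates`` times.

    Replicate r draws its taxon ages with seed ``base_seed + r``, so the
    ensemble is reproducible and replicates are independent.
    """
    config = config or DatingConfig()
    out = []
    for r in range(config.replicates):
        ages = sample_taxon_ages(ranges, seed=config.base_seed + r)
        out.append(enforce_mbl(date_tree_basic(tree, ages), config.mbl))
    return out


def root_age_diagnostic(
    dated: PhyloTree,
    ranges: Sequence[TaxonAgeRange],
    threshold: float = 10.0,
) -> RootAgeDiagnostic:
    """Root age minus the oldest possible taxon age (positive = inflated).

    Minimum-branch-duration enforcement can only push nodes older, so a
    large positive difference signals that the protocol is biasing the
    root age upward; ``flagged`` is set when the difference exceeds
    ``threshold`` Myr.
    """
    root_age = dated.seed_node.age
    if root_age is None:
        raise ValueError("tree is not dated")
    oldest = max(r.max_age for r in ranges)
    diff = root_age - oldest
    return RootAgeDiagnostic(
        root_age=float(root_age),
        oldest_max_age=float(oldest),
        difference=float(diff),
        threshold=threshold,
        flagged=diff > threshold,
    )


# ---------------------------------------------------------------------------
# CSV I/O for age tables (taxon,max_age,min_age with header)


def read_age_ranges(path) -> list[TaxonAgeRange]:
    df = pd.read_csv(path)
    required = {"taxon", "max_age", "min_age"}
    if not required.issubset(df.columns):
        raise ValueError(f"age table must have columns {sorted(required)}")
    return [
        TaxonAgeRange(taxon=str(row.taxon), max_age=float(row.max_age), min_age=float(row.min_age))
        for row in df.itertuples(index=False)
    ]


def write_age_ranges(ranges: Iterable[TaxonAgeRange], path) -> None:
    pd.DataFrame(
        [{"taxon": r.taxon, "max_age": r.max_age, "min_age": r.min_age} for r in ranges]
    ).to_csv(path, index=False)
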