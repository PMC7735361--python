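"""DIC model selection, outcome categories and the ensemble pipeline.

For each dated tree the three speciation models are fitted and compared
by DIC with a 4-unit rule: the best model is the one with the smallest
DIC, and models within 4 units of it are considered indistinguishable.
Outcomes fall into five categories:

- ``unambiguous_null`` / ``unambiguous_asymptote`` / ``unambiguous_downturn``
  — a single model beats both others by more than the threshold;
- ``downturn_or_asymptote`` — the two slowdown models are tied with each
  other but both beat the null;
- ``no_model_favoured`` — the null is within the threshold of the best
  model (even if not itself best): if the simplest model is
  statistically indistinguishable from the best, nothing is favoured.

The last rule is configurable (``null_blocks=False`` reports the tied
set instead).  Exact DIC ties resolve toward the simpler model
(null < asymptote < downturn in complexity).

:func:`run_pipeline` drives dating, fitting and classification over an
ensemble of topologies, caching each fit as a JSON sidecar so re-runs
only execute missing fits.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import glmm as _glmm
from . import pathstats as _pathstats
from . import timescale as _timescale
from .glmm import MCMCSettings, ModelSpec, PriorSpec, derive_seed
from .trees import PhyloTree, TaxonAgeRange

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "SelectionOutcome",
    "EnsembleSummary",
    "FitPlan",
    "classify",
    "plan_fits",
    "run_pipeline",
    "summarize",
]

CATEGORIES = (
    "unambiguous_null",
    "unambiguous_asymptote",
    "unambiguous_downturn",
    "downturn_or_asymptote",
    "no_model_favoured",
)

#: minimum mean ESS before a fit-quality warning is logged
ESS_WARN_THRESHOLD = 200.0


@dataclass(frozen=True)
class SelectionOutcome:
    """Per-tree model-selection result under the DIC rule."""

    tree_id: str
    intercept_mode: str
    dic_null: float
    dic_asymptote: float
    dic_downturn: float
    category: str
    source_tree: str = ""

    @property
    def dics(self) -> dict[str, float]:
        return {
            "null": self.dic_null,
            "asymptote": self.dic_asymptote,
            "downturn": self.dic_downturn,
        }


@dataclass
class EnsembleSummary:
    """Category counts and percentages over an ensemble of trees."""

    table: pd.DataFrame  # columns: group cols, category, count, percent

    def counts(self) -> pd.DataFrame:
        return self.table


@dataclass(frozen=True)
class FitPlan:
    """Bookkeeping for a pipeline run: how many trees and fits it implies."""

    n_dated_trees: int
    n_models: int
    n_intercept_modes: int

    @property
    def n_fits(self) -> int:
        return self.n_dated_trees * self.n_models * self.n_intercept_modes

    @property
    def n_selection_exercises(self) -> int:
        return self.n_dated_trees * self.n_intercept_modes


def classify(
    dics: Mapping[str, float],
    threshold: float = 4.0,
    null_blocks: bool = True,
) -> str:
    """Apply the DIC decision rule to one tree's three model fits.

    The candidate set C holds every model within ``threshold`` of the
    smallest DIC.  |C| = 1 gives an unambiguous winner;
    C = {downturn, asymptote} the combined slowdown category; and any C
    containing the null (with ``null_blocks``) means no model is
    favoured.
    """
    missing = set(_glmm.MODEL_FORMS) - set(dics)
    if missing:
        raise ValueError(f"missing DIC values for: {sorted(missing)}")
    vals = {m: float(dics[m]) for m in _glmm.MODEL_FORMS}
    if not all(np.isfinite(v) for v in vals.values()):
        raise ValueError(f"non-finite DIC: {vals}")
    best_val = min(vals.values())
    candidates = {m for m, v in vals.items() if v <= best_val + threshold}
    if len(candidates) == 1:
        return f"unambiguous_{candidates.pop()}"
    if "null" in candidates:
        if null_blocks:
            return "no_model_favoured"
        # report the tied set's simplest member instead
        simplest = min(candidates, key=lambda m: _glmm.FORM_COMPLEXITY[m])
        return f"unambiguous_{simplest}"
    return "downturn_or_asymptote"


def best_model(dics: Mapping[str, float]) -> str:
    """Smallest-DIC model; exact ties resolve toward the simpler model."""
    return min(
        _glmm.MODEL_FORMS,
        key=lambda m: (float(dics[m]), _glmm.FORM_COMPLEXITY[m]),
    )


def plan_fits(
    n_topologies: int,
    replicates_per_topology: int,
    n_predated: int = 0,
    n_models: int = 3,
    n_intercept_modes: int = 1,
) -> FitPlan:
    """Enumerate the fits a run will perform before doing any work."""
    n_trees = n_topologies * replicates_per_topology + n_predated
    return FitPlan(
        n_dated_trees=n_trees,
        n_models=n_models,
        n_intercept_modes=n_intercept_modes,
    )


# ---------------------------------------------------------------------------
# pipeline


def _fit_one(
    table: pd.DataFrame,
    A: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    priors: PriorSpec,
    settings: MCMCSettings,
) -> _glmm.ModelFit:
    X, offset = _glmm.build_design(table, spec)
    return _glmm.fit_mcmc(y, X, offset, A, priors=priors, settings=settings, spec=spec)


def run_pipeline(
    topologies: Mapping[str, PhyloTree],
    ranges: Mapping[str, Sequence[TaxonAgeRange]],
    out_dir,
    dating: _timescale.DatingConfig | None = None,
    mcmc: MCMCSettings | None = None,
    priors: PriorSpec | None = None,
    intercept_modes: Sequence[str] = ("estimated",),
    threshold: float = 4.0,
    base_seed: int = 0,
    predated: Optional[Mapping[str, PhyloTree]] = None,
) -> tuple[pd.DataFrame, EnsembleSummary, list[dict]]:
    """Date every topology, fit all three models per dated tree and
    intercept mode, classify, and summarize.

    ``predated`` trees (already carrying branch lengths in Myr) skip the
    dating stage and are fitted as-is, one outcome each.

    Each fit writes a JSON sidecar under ``out_dir/fits``; re-runs skip
    fits whose sidecar already exists (delete a sidecar to recompute
    exactly that fit).  Per-fit seeds are derived by hashing the tree
    identifier, model form and intercept mode with ``base_seed``, so
    partial re-runs reproduce the original chains.

    Returns (outcomes frame, ensemble summary, list of failures).
    """
    dating = dating or _timescale.DatingConfig()
    mcmc = mcmc or MCMCSettings()
    priors = priors or PriorSpec()
    out_dir = Path(out_dir)
    fits_dir = out_dir / "fits"
    fits_dir.mkdir(parents=True, exist_ok=True)

    jobs: list[tuple[str, str, PhyloTree]] = []
    for topo_id, topo in topologies.items():
        ens_cfg = _timescale.DatingConfig(
            mbl=dating.mbl,
            replicates=dating.replicates,
            base_seed=derive_seed(base_seed, topo_id, "dating"),
        )
        dated = _timescale.date_ensemble(topo, ranges[topo_id], ens_cfg)
        jobs += [(f"{topo_id}_rep{rep}", topo_id, tree) for rep, tree in enumerate(dated)]
    for pre_id, tree in (predated or {}).items():
        jobs.append((pre_id, pre_id, tree))

    rows: list[dict] = []
    failures: list[dict] = []
    for tree_id, topo_id, tree in jobs:
        table = _pathstats.extract_table(tree)
        A = _pathstats.phylo_vcv(tree).matrix
        y = np.asarray(table["node_count"], float)
        for mode in intercept_modes:
            dics: dict[str, float] = {}
            ok = True
            for form in _glmm.MODEL_FORMS:
                sidecar = fits_dir / f"{tree_id}__{mode}__{form}.json"
                if sidecar.exists():
                    with open(sidecar) as fh:
                        info = json.load(fh)
                    dics[form] = info["dic"]
                    continue
                spec = ModelSpec(form=form, intercept_mode=mode)
                seed = derive_seed(base_seed, tree_id, form, mode)
                settings = MCMCSettings(
                    n_iter=mcmc.n_iter, thin=mcmc.thin, burn_in=mcmc.burn_in, seed=seed
                )
                t0 = time.perf_counter()
                try:
                    fit = _fit_one(table, A, y, spec, priors, settings)
                except Exception as exc:
                    logger.error("fit failed for %s/%s/%s: %s", tree_id, mode, form, exc)
                    failures.append(
                        {"tree_id": tree_id, "intercept_mode": mode, "form": form,
                         "error": str(exc)}
                    )
                    ok = False
                    break
                elapsed = time.perf_counter() - t0
                if fit.mean_ess < ESS_WARN_THRESHOLD:
                    logger.warning(
                        "low mean ESS %.1f (< %.0f) for %s/%s/%s",
                        fit.mean_ess, ESS_WARN_THRESHOLD, tree_id, mode, form,
                    )
                logger.info(
                    "fit %s/%s/%s: DIC=%.2f pD=%.2f meanESS=%.0f (%.1fs)",
                    tree_id, mode, form, fit.dic, fit.pd_, fit.mean_ess, elapsed,
                )
                info = fit.summary_dict()
                info["elapsed_s"] = elapsed
                with open(sidecar, "w") as fh:
                    json.dump(info, fh, indent=1)
                dics[form] = fit.dic
            if not ok:
                continue
            rows.append(
                {
                    "tree_id": tree_id,
                    "source_tree": topo_id,
                    "intercept_mode": mode,
                    "dic_null": dics["null"],
                    "dic_asymptote": dics["asymptote"],
                    "dic_downturn": dics["downturn"],
                    "category": classify(dics, threshold=threshold),
                }
            )
    outcomes = pd.DataFrame(rows)
    outcomes.to_csv(out_dir / "outcomes.csv", index=False)
    summary = summarize(outcomes) if len(outcomes) else EnsembleSummary(pd.DataFrame())
    if len(outcomes):
        summary.table.to_csv(out_dir / "summary.csv", index=False)
    if failures:
        pd.DataFrame(failures).to_csv(out_dir / "failures.csv", index=False)
    return outcomes, summary, failures


def summarize(
    outcomes,
    grouping: Sequence[str] = ("source_tree", "intercept_mode"),
) -> EnsembleSummary:
    """Category counts and percentages per group (supplementary-table style)."""
    if isinstance(outcomes, (list, tuple)):
        outcomes = pd.DataFrame(
            [
                {
                    "tree_id": o.tree_id,
                    "source_tree": o.source_tree,
                    "intercept_mode": o.intercept_mode,
                    "category": o.category,
                }
                for o in outcomes
            ]
        )
    if len(outcomes) == 0:
        raise ValueError("no outcomes to summarize")
    grouping = [g for g in grouping if g in outcomes.columns]
    rows = []
    groups = outcomes.groupby(list(grouping)) if grouping else [((), outcomes)]
    for key, grp in groups:
        if not isinstance(key, tuple):
            key = (key,)
        total = len(grp)
        counts = grp["category"].value_counts()
        for cat in CATEGORIES:
            c = int(counts.get(cat, 0))
            row = dict(zip(grouping, key))
            row.update(category=cat, count=c, percent=100.0 * c / total, group_size=total)
            rows.append(row)
    return EnsembleSummary(pd.DataFrame(rows))
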