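"""Three-stage cross-cohort refinement of a metabolite-anchored gene module.

The initial module is derived in a single anchor cohort and is therefore
contaminated by anchor-specific noise.  Refinement pools evidence from
every cohort in the collection:

* **Stage 1** scores each initial gene's contribution (MGCS) to the
  module's integrity in every dataset; genes absent from a dataset's
  platform receive that dataset's *missing-gene constant*, 0.5 x the
  dataset's module CMS.
* **Stage 2** correlates every gene in the union universe against the
  module-average expression profile per dataset, substituting the
  missing-gene constant for absences.
* **Stage 3** takes the k candidates with the highest average correlation
  (initial genes excluded), computes their per-dataset MGCS against the
  initial module, stacks them with the initial genes into a 2k-row
  combined table, and keeps the k genes with the highest average MGCS as
  the refined module.

A single refinement pass is performed, matching the published procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .anchor import derive_initial_module
from .data_model import (
    DatasetCollection,
    ExpressionDataset,
    GeneModule,
    MetaboliteTable,
    gene_universe,
    samples_in_class,
)
from .module_score import CmsResult, cms_for_module

__all__ = [
    "RefinementResult",
    "RefineOutput",
    "stage1",
    "stage2",
    "stage3",
    "combine_and_rank",
    "refine",
    "replacement_fraction",
]


@dataclass
class RefinementResult:
    """Outcome of stage 3: the refined module plus its 2k-gene ranking."""

    refined: GeneModule
    combined_ranking: pd.DataFrame  # index gene; columns avg_mgcs, origin
    replaced_count: int
    provenance: dict[str, str]  # refined gene -> {"initial", "candidate"}


@dataclass
class RefineOutput:
    """Full orchestration output: initial module, refinement and CMS report."""

    initial: GeneModule
    result: RefinementResult
    report: pd.DataFrame  # per dataset: cms before/after on cancer and normal
    cms_initial: dict[str, "CmsResult | None"]  # keyed "<dataset>:<class>"
    cms_refined: dict[str, "CmsResult | None"]


def _row_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``a`` and every row of ``b``.

    Rows with zero variance yield NaN.
    """
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    a_n = np.sqrt((a_c**2).sum(axis=1))
    b_n = np.sqrt((b_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a_c @ b_c.T) / np.outer(a_n, b_n)
    return r


def _rank_top_k(values: pd.Series, k: int) -> list[str]:
    """Top-k index labels by descending value, ties lexicographic."""
    if len(values) < k:
        raise ValueError(f"only {len(values)} rows available, need k={k}")
    order = sorted(values.items(), key=lambda item: (-item[1], item[0]))
    return [g for g, _ in order[:k]]


def stage1(collection: DatasetCollection, initial: GeneModule,
           class_filter: str | Iterable[str] | None = "cancer",
           ) -> tuple[pd.DataFrame, dict[str, float], dict[str, CmsResult]]:
    """Per-dataset MGCS of every initial gene, plus missing-gene constants.

    Returns the initial MGCS table (genes x datasets, constants substituted
    for absences), the per-dataset constant (0.5 x dataset CMS) and the
    underlying CmsResult per dataset.  Datasets where the module is not
    evaluable are excluded with a warning.
    """
    columns: dict[str, np.ndarray] = {}
    constants: dict[str, float] = {}
    results: dict[str, CmsResult] = {}
    for ds in collection:
        samples = samples_in_class(ds, class_filter)
        if len(samples) < 3:
            warnings.warn(f"{ds.dataset_id}: < 3 samples, excluded from stage 1",
                          stacklevel=2)
            continue
        res = cms_for_module(ds, initial, samples=samples)
        if not res.evaluable:
            warnings.warn(f"{ds.dataset_id}: module not evaluable, excluded",
                          stacklevel=2)
            continue
        constant = 0.5 * res.cms
        col = np.full(len(initial.members), constant)
        for i, g in enumerate(initial.members):
            if g in res.mgcs.index:
                col[i] = res.mgcs.loc[g]
        columns[ds.dataset_id] = col
        constants[ds.dataset_id] = constant
        results[ds.dataset_id] = res
    if not columns:
        raise ValueError("module not evaluable in any dataset")
    table = pd.DataFrame(columns, index=pd.Index(initial.members, name="gene"))
    return table, constants, results


def stage2(collection: DatasetCollection, initial: GeneModule,
           constants: dict[str, float],
           class_filter: str | Iterable[str] | None = "cancer") -> pd.DataFrame:
    """Correlation of every union-universe gene to the module-average profile.

    The module-average profile in a dataset is the elementwise mean over the
    expression profiles of the initial genes present there.  Genes absent
    from a dataset — and zero-variance genes, whose correlation is
    undefined — receive the dataset's missing-gene constant.  Initial genes
    are retained in the table at this stage and excluded in stage 3.
    """
    universe = gene_universe(collection, mode="union")
    table = pd.DataFrame(index=pd.Index(universe, name="gene"),
                         columns=list(constants), dtype=float)
    for ds in collection:
        did = ds.dataset_id
        if did not in constants:
            continue
        samples = samples_in_class(ds, class_filter)
        present_initial = [g for g in initial.members if g in set(ds.genes)]
        x = ds.values[samples].to_numpy()
        avg = ds.values.loc[present_initial, samples].to_numpy().mean(axis=0)
        r = _row_corr(x, avg[None, :])[:, 0]
        n_zero_var = int(np.isnan(r).sum())
        if n_zero_var:
            warnings.warn(
                f"{did}: {n_zero_var} zero-variance candidate(s) set to the "
                f"missing-gene constant", stacklevel=2)
        col = pd.Series(r, index=ds.values.index).reindex(universe)
        table[did] = col.fillna(constants[did]).to_numpy()
    return table


def stage3(mgcs_table: pd.DataFrame, candidate_table: pd.DataFrame,
           initial: GeneModule, collection: DatasetCollection,
           constants: dict[str, float], k: int | None = None,
           class_filter: str | Iterable[str] | None = "cancer") -> RefinementResult:
    """Combine top-k candidates with the initial genes and re-rank by MGCS.

    (a) the k candidates with the highest average stage-2 correlation across
    datasets are selected (initial genes excluded); (b) each receives a
    per-dataset MGCS — its average correlation to the initial genes present
    in that dataset, constants substituted for absences; (c) the 2k-row
    combined table of candidate plus initial MGCS is averaged across
    datasets; (d) the k genes with the highest average MGCS form the refined
    module.  All ties break lexicographically by gene id.
    """
    if k is None:
        k = len(initial.members)
    if k > len(initial.members):
        raise ValueError("k must not exceed the initial module size")
    candidates = candidate_table.drop(index=[g for g in initial.members
                                             if g in candidate_table.index])
    avg_corr = candidates.mean(axis=1)
    top_candidates = _rank_top_k(avg_corr, k)

    cand_mgcs = pd.DataFrame(index=pd.Index(top_candidates, name="gene"),
                             columns=list(constants), dtype=float)
    for ds in collection:
        did = ds.dataset_id
        if did not in constants:
            continue
        samples = samples_in_class(ds, class_filter)
        gene_set = set(ds.genes)
        present_initial = [g for g in initial.members if g in gene_set]
        present_cand = [g for g in top_candidates if g in gene_set]
        col = pd.Series(constants[did], index=top_candidates, dtype=float)
        if present_cand and present_initial:
            a = ds.values.loc[present_cand, samples].to_numpy()
            b = ds.values.loc[present_initial, samples].to_numpy()
            r = _row_corr(a, b)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                means = np.nanmean(r, axis=1)
            for g, v in zip(present_cand, means):
                if np.isfinite(v):
                    col.loc[g] = v
        cand_mgcs[did] = col.to_numpy()

    return combine_and_rank(mgcs_table.loc[initial.members], cand_mgcs,
                            initial, k)


def combine_and_rank(initial_mgcs: pd.DataFrame, candidate_mgcs: pd.DataFrame,
                     initial: GeneModule, k: int) -> RefinementResult:
    """Stack initial and candidate MGCS tables and keep the top k by average.

    The combined table has ``|initial| + |candidates|`` rows (2k in the
    standard procedure); the refined module is the k genes with the highest
    unweighted average MGCS across datasets, ties lexicographic.
    """
    overlap = set(initial_mgcs.index) & set(candidate_mgcs.index)
    if overlap:
        raise ValueError(f"candidates overlap the initial module: {sorted(overlap)[:5]}")
    combined = pd.concat([initial_mgcs, candidate_mgcs])
    avg_mgcs = combined.mean(axis=1)
    refined_genes = _rank_top_k(avg_mgcs, k)
    initial_set = set(initial.members)
    provenance = {g: ("initial" if g in initial_set else "candidate")
                  for g in refined_genes}
    scores = [float(avg_mgcs.loc[g]) for g in refined_genes]
    refined = GeneModule("refined", refined_genes, scores=scores)
    order = sorted(avg_mgcs.items(), key=lambda item: (-item[1], item[0]))
    ranking = pd.DataFrame(
        {"avg_mgcs": [v for _, v in order],
         "origin": ["initial" if g in initial_set else "candidate"
                    for g, _ in order]},
        index=pd.Index([g for g, _ in order], name="gene"),
    )
    replaced = sum(1 for g in refined_genes if g not in initial_set)
    return RefinementResult(refined=refined, combined_ranking=ranking,
                            replaced_count=replaced, provenance=provenance)


def refine(collection: DatasetCollection, metabolite_table: MetaboliteTable,
           metabolites: Sequence[str] = ("citrate", "spermine"),
           k: int = 150, class_filter: str | Iterable[str] | None = "cancer",
           include_anchor: bool = True) -> RefineOutput:
    """Full orchestration: anchor profile -> initial module -> stages 1-3.

    Stages run over every dataset in the collection including the anchor
    (``include_anchor=False`` restricts nomination to the non-anchor
    cohorts), always on the ``class_filter`` samples.  The report evaluates
    the initial and refined modules on both cancer- and normal-class
    samples of every dataset.
    """
    anchor_ds = collection.anchor
    initial, profile, _ = derive_initial_module(
        anchor_ds, metabolite_table, metabolites=metabolites,
        class_filter=class_filter, k=k)
    stage_collection = collection
    if not include_anchor:
        others = [d for d in collection if d.dataset_id != collection.anchor_id]
        stage_collection = DatasetCollection(others, anchor_id=others[0].dataset_id)
    mgcs_table, constants, _ = stage1(stage_collection, initial, class_filter)
    cand_table = stage2(stage_collection, initial, constants, class_filter)
    result = stage3(mgcs_table, cand_table, initial, stage_collection,
                    constants, k=k, class_filter=class_filter)

    cms_initial: dict[str, CmsResult | None] = {}
    cms_refined: dict[str, CmsResult | None] = {}
    rows = []
    for ds in collection:
        row: dict[str, float | int | str] = {"dataset_id": ds.dataset_id}
        for label, module, store in (("initial", initial, cms_initial),
                                     ("refined", result.refined, cms_refined)):
            for cls in ("cancer", "normal"):
                samples = samples_in_class(ds, cls)
                key = f"cms_{label}_{cls}"
                if len(samples) >= 3:
                    res = cms_for_module(ds, module, samples=samples)
                    row[key] = res.cms
                else:
                    res = None
                    row[key] = float("nan")
                store[f"{ds.dataset_id}:{cls}"] = res
            gene_set = set(ds.genes)
            row[f"n_missing_{label}"] = sum(1 for g in module.members
                                            if g not in gene_set)
        rows.append(row)
    report = pd.DataFrame(rows).set_index("dataset_id")
    return RefineOutput(initial=initial, result=result, report=report,
                       cms_initial=cms_initial, cms_refined=cms_refined)


def replacement_fraction(initial: GeneModule, refined: GeneModule,
                         ) -> tuple[int, float, np.ndarray]:
    """How many refined genes are new, and the cumulative per-rank curve.

    Returns ``(count, fraction, curve)`` where ``curve[i]`` is the fraction
    of new genes among the refined module's top ``i + 1`` ranks.
    """
    if not initial.members or not refined.members:
        raise ValueError("both modules must be non-empty")
    initial_set = set(initial.members)
    new = np.array([g not in initial_set for g in refined.members], dtype=float)
    count = int(new.sum())
    curve = np.cumsum(new) / (np.arange(len(new)) + 1)
    return count, count / len(refined.members), curve
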