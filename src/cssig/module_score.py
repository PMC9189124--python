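"""Module-integrity statistics: CMS, MGCS, shuffle null and lognormal tail.

The Correlation Module Score (CMS) of a gene module in a dataset is the
mean of all off-diagonal pairwise Pearson correlations between the module
genes' expression profiles; a high CMS means the module behaves as a
coherent co-expression unit in that cohort.  The Module Gene Contribution
Score (MGCS) decomposes the CMS per gene: it is one gene's mean
correlation to all other module genes, so mean(MGCS) == CMS exactly.

Significance of an observed CMS is assessed against a permutation null in
which the anchor metabolite profile is shuffled across samples and a fresh
top-k module is selected per permutation; a lognormal distribution is
fitted to the null CMS values and the upper-tail probability of the
observed CMS is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .anchor import AnchorProfile, correlate_genes_to_profile, select_top_k
from .data_model import (
    DatasetCollection,
    ExpressionDataset,
    GeneModule,
    samples_in_class,
)

__all__ = [
    "IntraCorrelationTable",
    "CmsResult",
    "NullDistribution",
    "intra_correlation_table",
    "cms",
    "mgcs",
    "mgcs_all",
    "cms_for_module",
    "evaluate_across_collection",
    "permutation_null",
    "random_module_null",
    "lognormal_p",
]


@dataclass
class IntraCorrelationTable:
    """Square table of pairwise Pearson correlations over module genes.

    ``r`` is a full m x m DataFrame (diagonal = 1) over the module genes
    present in the dataset after excluding zero-variance genes (listed in
    ``dropped``).
    """

    r: pd.DataFrame
    samples_used: int
    dropped: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.r.index)

    @property
    def n_cells(self) -> int:
        m = len(self.r)
        return m * m


@dataclass
class CmsResult:
    """Per-dataset module-integrity summary.

    ``cms`` is NaN when the module could not be evaluated in the dataset
    (fewer than two present genes with variance, or too few samples).
    """

    dataset_id: str
    cms: float
    mgcs: pd.Series
    present: list[str]
    missing: list[str]
    samples_used: int

    @property
    def evaluable(self) -> bool:
        return np.isfinite(self.cms)


@dataclass
class NullDistribution:
    """Shuffle-null CMS values with a lognormal fit and upper-tail p."""

    null_cms: np.ndarray
    mu_hat: float
    sigma_hat: float
    p: float
    seed: int | None
    observed_cms: float
    observed_module: GeneModule | None = None


def intra_correlation_table(dataset: ExpressionDataset, module: GeneModule,
                            samples: Sequence[str] | None = None) -> IntraCorrelationTable:
    """Full pairwise Pearson table over the module genes present in ``dataset``.

    Zero-variance genes are excluded with a warning and recorded; at least
    two present genes (after exclusion) and three samples are required.
    A 150-gene module yields the full 150 x 150 = 22,500-cell table.
    """
    gene_set = set(dataset.genes)
    present = [g for g in module.members if g in gene_set]
    if samples is None:
        samples = dataset.samples
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError(f"need >= 3 samples, got {len(samples)}")
    x = dataset.values.loc[present, samples].to_numpy()
    sd = x.std(axis=1)
    dropped = [g for g, s in zip(present, sd) if s == 0.0]
    if dropped:
        warnings.warn(
            f"{dataset.dataset_id}: excluding zero-variance module gene(s) {dropped}",
            stacklevel=2,
        )
        keep = sd > 0.0
        present = [g for g, k in zip(present, keep) if k]
        x = x[keep]
    if len(present) < 2:
        raise ValueError(
            f"{dataset.dataset_id}: module has {len(present)} usable genes, need >= 2"
        )
    r = np.corrcoef(x)
    return IntraCorrelationTable(
        r=pd.DataFrame(r, index=present, columns=present),
        samples_used=len(samples),
        dropped=dropped,
    )


def cms(table: IntraCorrelationTable) -> float:
    """Mean of all off-diagonal cells of the intra-correlation table."""
    m = len(table.r)
    if m < 2:
        raise ValueError("CMS needs a table over >= 2 genes")
    arr = table.r.to_numpy()
    return float((arr.sum() - np.trace(arr)) / (m * (m - 1)))


def mgcs(table: IntraCorrelationTable, gene: str) -> float:
    """Mean correlation of ``gene`` to every other gene in the table."""
    if gene not in table.r.index:
        raise KeyError(f"gene {gene!r} not in table")
    m = len(table.r)
    if m < 2:
        raise ValueError("MGCS needs a table over >= 2 genes")
    row = table.r.loc[gene].to_numpy()
    return float((row.sum() - table.r.loc[gene, gene]) / (m - 1))


def mgcs_all(table: IntraCorrelationTable) -> pd.Series:
    """MGCS for every table gene; mean(MGCS) equals the CMS exactly."""
    m = len(table.r)
    if m < 2:
        raise ValueError("MGCS needs a table over >= 2 genes")
    arr = table.r.to_numpy()
    vals = (arr.sum(axis=1) - np.diag(arr)) / (m - 1)
    return pd.Series(vals, index=table.r.index, name="mgcs")


def cms_for_module(dataset: ExpressionDataset, module: GeneModule,
                   samples: Sequence[str] | None = None) -> CmsResult:
    """CMS/MGCS of a module in one dataset, with missing-gene bookkeeping."""
    gene_set = set(dataset.genes)
    missing = [g for g in module.members if g not in gene_set]
    try:
        table = intra_correlation_table(dataset, module, samples=samples)
    except ValueError:
        present = [g for g in module.members if g in gene_set]
        return CmsResult(dataset.dataset_id, float("nan"), pd.Series(dtype=float),
                         present, missing, 0)
    per_gene = mgcs_all(table)
    return CmsResult(
        dataset_id=dataset.dataset_id,
        cms=float(per_gene.mean()),
        mgcs=per_gene,
        present=table.genes,
        missing=missing,
        samples_used=table.samples_used,
    )


def evaluate_across_collection(collection: DatasetCollection, module: GeneModule,
                               class_filter: str | Iterable[str] | None = None,
                               ) -> dict[str, CmsResult]:
    """One CmsResult per dataset, restricted to the filtered samples.

    Datasets where the module has fewer than two usable genes are reported
    as non-evaluable (CMS = NaN) rather than raising.
    """
    results: dict[str, CmsResult] = {}
    for ds in collection:
        samples = samples_in_class(ds, class_filter)
        if len(samples) < 3:
            gene_set = set(ds.genes)
            missing = [g for g in module.members if g not in gene_set]
            present = [g for g in module.members if g in gene_set]
            warnings.warn(
                f"{ds.dataset_id}: < 3 samples in class filter, not evaluable",
                stacklevel=2,
            )
            results[ds.dataset_id] = CmsResult(ds.dataset_id, float("nan"),
                                               pd.Series(dtype=float), present,
                                               missing, len(samples))
            continue
        res = cms_for_module(ds, module, samples=samples)
        if not res.evaluable:
            warnings.warn(
                f"{ds.dataset_id}: module not evaluable (< 2 usable genes)",
                stacklevel=2,
            )
        results[ds.dataset_id] = res
    return results


def lognormal_p(null_values: Sequence[float] | np.ndarray,
                observed: float) -> tuple[float, float, float]:
    """Lognormal MLE fit to positive null values and upper-tail p of ``observed``.

    The fit is maximum likelihood on the logs: mu_hat = mean(log values),
    sigma_hat = population standard deviation of the logs (location fixed
    at zero).  p = 1 - F_lognormal(observed).
    """
    vals = np.asarray(null_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need >= 2 null values")
    if not np.isfinite(vals).all() or (vals <= 0).any():
        raise ValueError("all null values must be finite and > 0")
    if observed <= 0 or not np.isfinite(observed):
        raise ValueError("observed value must be finite and > 0")
    logs = np.log(vals)
    mu_hat = float(logs.mean())
    sigma_hat = float(logs.std(ddof=0))
    if sigma_hat == 0.0:
        raise ValueError("null values are all identical; lognormal fit degenerate")
    p = float(stats.lognorm.sf(observed, s=sigma_hat, scale=np.exp(mu_hat)))
    return mu_hat, sigma_hat, p


def _lexicographic_gene_order(dataset: ExpressionDataset) -> np.ndarray:
    return np.argsort(np.asarray(dataset.genes, dtype=object), kind="stable")


def permutation_null(anchor: ExpressionDataset, profile: AnchorProfile,
                     samples: Sequence[str] | None = None, k: int = 150,
                     n_perm: int = 100, seed: int | None = None) -> NullDistribution:
    """Shuffle-null for the metabolite-anchored module's CMS.

    For each of ``n_perm`` permutations the anchor profile's values are
    randomly permuted across the samples, a fresh top-k module is selected
    from the gene-profile correlations, and its CMS on the same samples is
    recorded.  The observed CMS (unshuffled profile) is compared with a
    lognormal fit to the null values.  Seeded and reproducible.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    shared = [s for s in anchor.samples if s in set(profile.samples)]
    if samples is not None:
        wanted = set(samples)
        shared = [s for s in shared if s in wanted]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    # genes in lexicographic order so a stable descending sort breaks ties by id
    order = _lexicographic_gene_order(anchor)
    genes = np.asarray(anchor.genes, dtype=object)[order]
    x = anchor.values[shared].to_numpy()[order]
    x_c = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((x_c**2).sum(axis=1))
    usable = norms > 0.0
    if int(usable.sum()) < k:
        raise ValueError(f"only {int(usable.sum())} genes with variance, need k={k}")
    xn = np.zeros_like(x_c)
    xn[usable] = x_c[usable] / norms[usable, None]

    p0 = profile.values.loc[shared].to_numpy(dtype=float)

    def _topk_cms(p_vec: np.ndarray) -> tuple[float, np.ndarray]:
        p_c = p_vec - p_vec.mean()
        p_n = float(np.sqrt((p_c**2).sum()))
        if p_n == 0.0:
            raise ValueError("profile has zero variance")
        r = xn @ (p_c / p_n)
        key = -r
        key[~usable] = np.inf  # ineligible for selection: sort last
        idx = np.argsort(key, kind="stable")[:k]
        sub = xn[idx]
        corr_sum = float((sub @ sub.T).sum())
        return (corr_sum - k) / (k * (k - 1)), idx

    observed_cms, obs_idx = _topk_cms(p0)
    rng = np.random.default_rng(seed)
    null_cms = np.empty(n_perm)
    for i in range(n_perm):
        null_cms[i], _ = _topk_cms(rng.permutation(p0))
    mu_hat, sigma_hat, p = lognormal_p(null_cms, observed_cms)
    obs_r = xn[obs_idx] @ ((p0 - p0.mean()) / np.sqrt(((p0 - p0.mean()) ** 2).sum()))
    obs_order = sorted(zip(genes[obs_idx], obs_r), key=lambda t: (-t[1], t[0]))
    module = GeneModule("observed_topk", [g for g, _ in obs_order],
                        scores=[float(v) for _, v in obs_order])
    return NullDistribution(null_cms=null_cms, mu_hat=mu_hat, sigma_hat=sigma_hat,
                            p=p, seed=seed, observed_cms=float(observed_cms),
                            observed_module=module)


def random_module_null(dataset: ExpressionDataset, size: int, n_modules: int,
                       seed: int | None = None,
                       samples: Sequence[str] | None = None) -> np.ndarray:
    """CMS values of random same-size gene modules (the alternative null).

    The default significance test shuffles the metabolite profile; this
    helper instead samples random gene sets of the module's size, which is
    the other reading of a "random module" null.
    """
    if samples is None:
        samples = dataset.samples
    samples = list(samples)
    x = dataset.values[samples].to_numpy()
    x_c = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((x_c**2).sum(axis=1))
    usable = np.flatnonzero(norms > 0.0)
    if usable.size < size:
        raise ValueError("not enough genes with variance")
    xn = x_c[usable] / norms[usable, None]
    rng = np.random.default_rng(seed)
    out = np.empty(n_modules)
    for i in range(n_modules):
        idx = rng.choice(usable.size, size=size, replace=False)
        sub = xn[idx]
        out[i] = ((sub @ sub.T).sum() - size) / (size * (size - 1))
    return out
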