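"""Single-sample GSEA: rank running-sum enrichment of a module per sample.

For one sample, genes are sorted by expression in descending order (ties
broken lexicographically by gene id) and the score is the sum over all
rank positions of the difference between the weighted in-set empirical
CDF and the out-of-set empirical CDF.  In-set steps at position ``i``
(1-based from the top) are weighted by ``(N - i + 1) ** alpha`` — the
expression rank weight — so ``alpha = 0`` gives plain equal steps and is
exactly hand-enumerable.  The statistic is rank-based: any strictly
increasing transform of a sample's expression leaves its score unchanged.

Scores are computed on raw (producer-normalized) expression by default;
the ``centered`` mode z-scores each gene across samples before ranking
(used for sparse per-pixel data).  Cross-dataset comparisons use the
adapted procedure: both datasets are scored on their shared gene universe
with the module restricted to it, optionally followed by min-max 0-1
rescaling of one dataset's scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionDataset, GeneModule

__all__ = [
    "EnrichmentScores",
    "DEFAULT_ALPHA",
    "ssgsea_sample",
    "ssgsea_dataset",
    "adapted_pair_scores",
    "minmax01",
    "correlate_signature_scores",
]

#: Rank-weight exponent used unless a caller overrides it.  alpha = 0 gives
#: unweighted steps and hand-checkable scores.
DEFAULT_ALPHA = 0.25


@dataclass
class EnrichmentScores:
    """Per-sample enrichment values for one module with provenance."""

    dataset_id: str
    module_name: str
    scores: pd.Series  # indexed by sample id
    universe: list[str]
    mode: str = "raw"
    alpha: float = DEFAULT_ALPHA
    normalized: str = "none"
    dropped_members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("enrichment scores must be finite")


def _score_ranked(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum score given expression and membership in universe order.

    ``values``/``in_set`` must already be aligned to lexicographically
    sorted gene ids so the stable descending sort breaks ties by id.
    """
    n = values.size
    order = np.argsort(-values, kind="stable")
    mask = in_set[order]
    m = int(mask.sum())
    weights = (np.arange(n, 0, -1, dtype=float)) ** alpha  # N .. 1
    win = np.where(mask, weights, 0.0)
    p_in = np.cumsum(win) / win.sum()
    p_out = np.cumsum(~mask) / float(n - m)
    return float((p_in - p_out).sum())


def ssgsea_sample(expression: pd.Series, gene_set: GeneModule | Iterable[str],
                  alpha: float = DEFAULT_ALPHA) -> float:
    """Enrichment score of a gene set in one sample's expression vector.

    The universe is the expression vector's index.  The effective set (set
    intersected with the universe) must be non-empty and a strict subset of
    the universe.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    members = list(gene_set.members) if isinstance(gene_set, GeneModule) else list(gene_set)
    genes = expression.index.to_numpy(dtype=object)
    if genes.size < 2:
        raise ValueError("universe must hold >= 2 genes")
    values = expression.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression values must be finite")
    member_set = set(members)
    in_set = np.array([g in member_set for g in genes])
    m = int(in_set.sum())
    if m == 0:
        raise ValueError("gene set does not intersect the universe")
    if m == genes.size:
        raise ValueError("gene set equals the whole universe")
    lex = np.argsort(genes, kind="stable")
    return _score_ranked(values[lex], in_set[lex], alpha)


def ssgsea_dataset(dataset: ExpressionDataset, module: GeneModule,
                   mode: str = "raw", alpha: float = DEFAULT_ALPHA,
                   samples: Sequence[str] | None = None) -> EnrichmentScores:
    """Per-sample enrichment of ``module`` across a dataset.

    ``raw`` (the default) ranks each sample's expression as-is, making each
    sample's score independent of the others; ``centered`` z-scores every
    gene across samples first (zero-variance genes become 0).
    """
    if mode not in ("raw", "centered"):
        raise ValueError(f"unknown mode {mode!r}")
    if samples is None:
        samples = dataset.samples
    samples = list(samples)
    genes = np.asarray(dataset.genes, dtype=object)
    x = dataset.values[samples].to_numpy()
    if mode == "centered":
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(sd > 0, (x - mu) / sd, 0.0)
    member_set = set(module.members)
    in_set = np.array([g in member_set for g in genes])
    m = int(in_set.sum())
    if m == 0:
        raise ValueError("module does not intersect the dataset's genes")
    if m == genes.size:
        raise ValueError("module equals the whole universe")
    dropped = [g for g in module.members if g not in set(genes)]
    lex = np.argsort(genes, kind="stable")
    in_lex = in_set[lex]
    x_lex = x[lex]
    vals = [
        _score_ranked(x_lex[:, j], in_lex, alpha) for j in range(len(samples))
    ]
    return EnrichmentScores(
        dataset_id=dataset.dataset_id,
        module_name=module.name,
        scores=pd.Series(vals, index=samples, name="ssgsea"),
        universe=list(genes),
        mode=mode,
        alpha=alpha,
        dropped_members=dropped,
    )


def adapted_pair_scores(dataset_a: ExpressionDataset, dataset_b: ExpressionDataset,
                        module: GeneModule, alpha: float = DEFAULT_ALPHA,
                        mode: str = "raw",
                        ) -> tuple[EnrichmentScores, EnrichmentScores]:
    """Score two datasets on their shared gene universe.

    Both the universe and the module are restricted to the genes shared by
    the two datasets, so the number and identity of genes and the set size
    are identical for both scorings.  Module genes outside the shared
    universe are dropped and reported in each result's metadata.  When the
    universes already coincide the result is bit-identical to plain
    per-dataset scoring.
    """
    shared = [g for g in dataset_a.genes if g in set(dataset_b.genes)]
    if len(shared) < 2:
        raise ValueError("shared gene universe holds < 2 genes")
    restricted = [g for g in module.members if g in set(shared)]
    if not restricted:
        raise ValueError("module does not intersect the shared universe")
    sub_module = GeneModule(module.name, restricted)
    out = []
    for ds in (dataset_a, dataset_b):
        sub = ExpressionDataset(ds.dataset_id, ds.values.loc[shared],
                                ds.annotations)
        scores = ssgsea_dataset(sub, sub_module, mode=mode, alpha=alpha)
        scores.dropped_members = [g for g in module.members
                                  if g not in set(restricted)]
        out.append(scores)
    return out[0], out[1]


def minmax01(scores: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Rescale to the 0-1 range: (x - min) / (max - min).

    Invariant under positive affine maps of the input; a constant vector is
    an error.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 values")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise ValueError("cannot min-max scale a constant vector")
    rescaled = (arr - lo) / (hi - lo)
    if isinstance(scores, pd.Series):
        return pd.Series(rescaled, index=scores.index, name=scores.name)
    return rescaled


def correlate_signature_scores(scores_a: EnrichmentScores,
                               scores_b: EnrichmentScores) -> float:
    """Pearson r between two per-sample score vectors, joined by sample id."""
    shared = [s for s in scores_a.scores.index if s in set(scores_b.scores.index)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    r, _ = stats.pearsonr(scores_a.scores.loc[shared].to_numpy(),
                          scores_b.scores.loc[shared].to_numpy())
    return float(r)
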