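"""Anchor metabolite profile and the initial metabolite-correlated gene module.

The anchor cohort is the single dataset with paired metabolite and
expression measurements.  The workflow mirrors how a secretion-linked
signature is seeded: the concentration profiles of the anchoring
metabolites (here citrate and spermine, which are almost perfectly
mutually correlated across prostate tissue) are each normalized to unit
sum and averaged into a single per-sample activity proxy; every gene's
expression profile is then Pearson-correlated with that proxy, and the
top-k positively correlated genes form the initial module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ExpressionDataset,
    GeneModule,
    MetaboliteTable,
    samples_in_class,
)

__all__ = [
    "AnchorProfile",
    "unit_sum_average",
    "correlate_genes_to_profile",
    "select_top_k",
    "derive_initial_module",
    "DEFAULT_MODULE_SIZE",
]

#: Signature size used throughout: the 150 genes most positively correlated
#: with the anchor metabolite profile.
DEFAULT_MODULE_SIZE = 150


@dataclass
class AnchorProfile:
    """Unit-sum averaged metabolite concentration profile.

    ``values`` is indexed by sample id, sums to 1 and is non-negative;
    ``constituents`` names the averaged metabolites.
    """

    values: pd.Series
    constituents: list[str]

    def __post_init__(self) -> None:
        vals = self.values.astype(float)
        if (vals < 0).any():
            raise ValueError("anchor profile values must be non-negative")
        total = float(vals.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"anchor profile must sum to 1, got {total}")
        self.values = vals

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)


def unit_sum_average(table: MetaboliteTable, metabolites: Sequence[str],
                     samples: Sequence[str] | None = None) -> AnchorProfile:
    """Average metabolite profiles after normalizing each to unit sum.

    Each named metabolite's concentration vector (over the chosen samples)
    is divided by its sum, the normalized vectors are averaged elementwise,
    and the result again sums to one.  Scale-invariant per metabolite:
    multiplying any constituent profile by c > 0 leaves the output unchanged.
    """
    metabolites = list(metabolites)
    if not metabolites:
        raise ValueError("need at least one metabolite name")
    unknown = [m for m in metabolites if m not in table.values.index]
    if unknown:
        raise KeyError(f"unknown metabolite name(s): {unknown}")
    sub = table.values.loc[metabolites]
    if samples is not None:
        missing = [s for s in samples if s not in sub.columns]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing[:5]}")
        sub = sub[list(samples)]
    sums = sub.sum(axis=1)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"zero-sum metabolite profile(s): {bad}")
    normalized = sub.div(sums, axis=0)
    avg = normalized.mean(axis=0)
    return AnchorProfile(values=avg, constituents=metabolites)


def correlate_genes_to_profile(dataset: ExpressionDataset, profile: AnchorProfile,
                               samples: Sequence[str] | None = None) -> pd.Series:
    """Pearson r between the anchor profile and every gene's expression.

    Computed over the samples shared by the dataset and the profile
    (optionally further restricted).  Genes with zero expression variance
    get NaN ("undefined") and are ineligible for selection.
    """
    shared = [s for s in dataset.samples if s in set(profile.samples)]
    if samples is not None:
        wanted = set(samples)
        shared = [s for s in shared if s in wanted]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared samples between dataset and profile, got {len(shared)}"
        )
    x = dataset.values[shared].to_numpy()
    p = profile.values.loc[shared].to_numpy(dtype=float)
    p_c = p - p.mean()
    p_norm = float(np.sqrt((p_c**2).sum()))
    if p_norm == 0.0:
        raise ValueError("anchor profile has zero variance over the chosen samples")
    x_c = x - x.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((x_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x_c @ p_c) / (x_norm * p_norm)
    r[x_norm == 0.0] = np.nan
    return pd.Series(r, index=dataset.values.index, name="pearson_r")


def select_top_k(correlations: Mapping[str, float] | pd.Series, k: int,
                 name: str = "initial") -> GeneModule:
    """The k genes with the highest correlation, as a ranked module.

    NaN (undefined) correlations are excluded.  Ties at any rank are broken
    lexicographically by gene id, so the output is invariant to the input
    ordering of the correlation map.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    series = pd.Series(correlations, dtype=float).dropna()
    if len(series) < k:
        raise ValueError(
            f"only {len(series)} defined correlations available, need k={k}"
        )
    order = sorted(series.items(), key=lambda item: (-item[1], item[0]))[:k]
    members = [g for g, _ in order]
    scores = [float(r) for _, r in order]
    return GeneModule(name=name, members=members, scores=scores)


def derive_initial_module(dataset: ExpressionDataset, table: MetaboliteTable,
                          metabolites: Sequence[str] = ("citrate", "spermine"),
                          class_filter: str | Iterable[str] | None = "cancer",
                          k: int = DEFAULT_MODULE_SIZE,
                          name: str = "initial") -> tuple[GeneModule, AnchorProfile, pd.Series]:
    """Anchor profile -> gene correlations -> top-k initial module.

    The unit-sum average uses every sample shared between the expression
    matrix and the metabolite table; the gene correlations are restricted to
    the ``class_filter`` samples (cancer samples by default — the derivation
    on normal samples is available by passing ``class_filter='normal'``).
    Returns the module, the profile and the full per-gene correlation map.
    """
    shared = [s for s in dataset.samples if s in set(table.samples)]
    if len(shared) < 3:
        raise ValueError("anchor dataset and metabolite table share < 3 samples")
    profile = unit_sum_average(table, metabolites, samples=shared)
    corr_samples = samples_in_class(dataset, class_filter)
    corr_samples = [s for s in corr_samples if s in set(shared)]
    correlations = correlate_genes_to_profile(dataset, profile, samples=corr_samples)
    module = select_top_k(correlations, k=k, name=name)
    return module, profile, correlations
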