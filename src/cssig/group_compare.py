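"""Plain statistics for comparing enrichment scores between sample groups.

These are deliberately ordinary tools — a Welch two-sample t-test for
two-group comparisons, Spearman rank correlation for ordered disease-stage
trends, per-dataset centering for cross-cohort displays, and a Pearson
check against tumor-fraction annotations.  They stand in for moderated
differential-score models; no multiple-testing correction is applied and
raw p-values are reported per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionDataset
from .ssgsea import EnrichmentScores

__all__ = [
    "GroupComparison",
    "compare_groups",
    "ordinal_trend",
    "center_per_dataset",
    "tumor_fraction_correlation",
]


@dataclass
class GroupComparison:
    """Welch two-sample comparison of scores between two groups."""

    groups: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    difference: float
    statistic: float
    p: float


def _as_series(scores: EnrichmentScores | pd.Series) -> pd.Series:
    if isinstance(scores, EnrichmentScores):
        return scores.scores
    return scores


def compare_groups(scores: EnrichmentScores | pd.Series,
                   groups: Mapping[str, str] | pd.Series) -> GroupComparison:
    """Welch t-test of scores between exactly two group labels.

    Both groups need >= 2 scored samples.  Degenerate zero-variance inputs
    are handled explicitly: identical group values give statistic 0 and
    p = 1; zero variance with different means gives p = 0.
    """
    values = _as_series(scores)
    labels = pd.Series(groups)
    shared = [s for s in values.index if s in set(labels.index)]
    values = values.loc[shared]
    labels = labels.loc[shared]
    names = sorted(set(labels))
    if len(names) != 2:
        raise ValueError(f"need exactly two group labels, got {names}")
    a = values[labels == names[0]].to_numpy(dtype=float)
    b = values[labels == names[1]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        statistic, p = (0.0, 1.0) if diff == 0.0 else (float("inf"), 0.0)
    else:
        statistic, p = stats.ttest_ind(a, b, equal_var=False)
        statistic, p = float(statistic), float(p)
    return GroupComparison(
        groups=(names[0], names[1]),
        n=(len(a), len(b)),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        difference=diff,
        statistic=statistic,
        p=p,
    )


def ordinal_trend(scores: EnrichmentScores | pd.Series,
                  classes: Mapping[str, str] | pd.Series,
                  ordered_classes: Sequence[str]) -> tuple[float, float]:
    """Spearman rho between scores and the rank of an ordered class list.

    Samples whose class is not in ``ordered_classes`` are ignored.  A
    negative rho means scores decline along the ordering (e.g. normal
    epithelium -> low grade -> high grade -> metastasis).  Invariant to
    strictly increasing transforms of the class ranks.
    """
    values = _as_series(scores)
    labels = pd.Series(classes)
    rank_of = {c: i for i, c in enumerate(ordered_classes)}
    shared = [s for s in values.index
              if s in set(labels.index) and labels.loc[s] in rank_of]
    if len(shared) < 3:
        raise ValueError("need >= 3 samples within the ordered classes")
    present_classes = {labels.loc[s] for s in shared}
    if len(present_classes) < 2:
        raise ValueError("need >= 2 distinct classes present")
    x = np.array([rank_of[labels.loc[s]] for s in shared], dtype=float)
    y = values.loc[shared].to_numpy(dtype=float)
    rho, p = stats.spearmanr(y, x)
    return float(rho), float(p)


def center_per_dataset(scores_by_dataset: Mapping[str, pd.Series | EnrichmentScores],
                       ) -> dict[str, pd.Series]:
    """Subtract each dataset's mean score; output means are exactly zero.

    Idempotent: centering twice equals centering once.
    """
    out: dict[str, pd.Series] = {}
    for dataset_id, scores in scores_by_dataset.items():
        values = _as_series(scores).astype(float)
        if values.empty:
            raise ValueError(f"no scores for dataset {dataset_id!r}")
        out[dataset_id] = values - values.mean()
    return out


def tumor_fraction_correlation(scores: EnrichmentScores | pd.Series,
                               dataset: ExpressionDataset) -> float:
    """Pearson r between per-sample scores and tumor-fraction annotations."""
    if dataset.annotations is None or "tumor_fraction" not in dataset.annotations:
        raise ValueError("dataset carries no tumor_fraction annotation")
    values = _as_series(scores)
    tf = dataset.annotations["tumor_fraction"].dropna()
    shared = [s for s in values.index if s in set(tf.index)]
    if len(shared) < 3:
        raise ValueError("need >= 3 annotated samples")
    r, _ = stats.pearsonr(values.loc[shared], tf.loc[shared])
    return float(r)
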