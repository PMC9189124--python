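"""Per-dataset correlation networks over module genes and hub ranking.

In each cohort the module genes become nodes and every node keeps directed
edges to the k genes with the largest absolute Pearson correlation to it
(k = 20 by default), so central genes accumulate many incoming links.
A gene's degree in a dataset is its number of distinct neighbours in the
union of in- and out-links (a reciprocal pair counts once); hub genes are
those with the highest mean degree across the collection's datasets, with
genes absent from a dataset contributing degree zero there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import (
    DatasetCollection,
    ExpressionDataset,
    GeneModule,
    samples_in_class,
)

__all__ = [
    "ModuleNetwork",
    "HubRanking",
    "DEFAULT_LINKS",
    "DEFAULT_N_HUBS",
    "build_topk_network",
    "node_degrees",
    "hub_ranking",
]

#: Outgoing links kept per node.
DEFAULT_LINKS = 20
#: Number of hub genes reported.
DEFAULT_N_HUBS = 10


@dataclass
class ModuleNetwork:
    """Directed top-k absolute-correlation network over present module genes."""

    dataset_id: str
    graph: nx.DiGraph
    k: int

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


@dataclass
class HubRanking:
    """Mean node degree across datasets and the resulting hub list."""

    mean_degree: pd.Series
    hubs: list[str]
    n_hubs: int


def build_topk_network(dataset: ExpressionDataset, module: GeneModule,
                       k: int = DEFAULT_LINKS,
                       samples: Sequence[str] | None = None) -> ModuleNetwork:
    """Keep each node's k strongest outgoing |Pearson r| links.

    Every node gets out-degree min(k, n - 1); ties in |r| break
    lexicographically by target gene id.  Degree is invariant to sign flips
    of expression profiles because absolute correlation is used.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    gene_set = set(dataset.genes)
    present = [g for g in module.members if g in gene_set]
    if samples is None:
        samples = dataset.samples
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError(f"need >= 3 samples, got {len(samples)}")
    x = dataset.values.loc[present, samples].to_numpy()
    sd = x.std(axis=1)
    present = [g for g, s in zip(present, sd) if s > 0]
    if len(present) < 2:
        raise ValueError("need >= 2 present module genes with variance")
    x = dataset.values.loc[present, samples].to_numpy()
    r = np.abs(np.corrcoef(x))
    graph = nx.DiGraph()
    graph.add_nodes_from(present)
    n = len(present)
    budget = min(k, n - 1)
    for i, source in enumerate(present):
        targets = sorted(
            ((-r[i, j], present[j]) for j in range(n) if j != i))[:budget]
        for neg_w, target in targets:
            graph.add_edge(source, target, weight=float(-neg_w))
    return ModuleNetwork(dataset_id=dataset.dataset_id, graph=graph, k=k)


def node_degrees(network: ModuleNetwork, mode: str = "distinct") -> pd.Series:
    """Node degree per gene.

    ``distinct`` counts distinct adjacent nodes in the union graph (a
    reciprocal pair counts once); ``in_out`` counts in-degree + out-degree
    (reciprocal pairs count twice).
    """
    if mode == "distinct":
        und = network.graph.to_undirected()
        deg = dict(und.degree())
    elif mode == "in_out":
        deg = {n: d for n, d in network.graph.degree()}
    else:
        raise ValueError(f"unknown degree mode {mode!r}")
    return pd.Series({n: float(deg.get(n, 0)) for n in network.nodes},
                     name="degree")


def hub_ranking(collection: DatasetCollection, module: GeneModule,
                k: int = DEFAULT_LINKS, n_hubs: int = DEFAULT_N_HUBS,
                class_filter: str | Iterable[str] | None = "cancer",
                degree_mode: str = "distinct",
                absent: str = "zero") -> HubRanking:
    """Hub genes by mean degree across the collection's networks.

    ``absent='zero'`` (default) lets genes missing from a dataset contribute
    degree 0 to the mean so hubs must be broadly present;
    ``absent='present_only'`` averages only over datasets where the gene
    occurs.  Networks are built on cancer-class samples by default.
    """
    if absent not in ("zero", "present_only"):
        raise ValueError(f"unknown absent policy {absent!r}")
    per_dataset: list[pd.Series] = []
    for ds in collection:
        samples = samples_in_class(ds, class_filter)
        try:
            network = build_topk_network(ds, module, k=k, samples=samples)
        except ValueError:
            continue
        per_dataset.append(node_degrees(network, mode=degree_mode))
    if not per_dataset:
        raise ValueError("module network not constructible in any dataset")
    table = pd.DataFrame(
        {i: s for i, s in enumerate(per_dataset)}).reindex(module.members)
    if absent == "zero":
        table = table.fillna(0.0)
    mean_degree = table.mean(axis=1, skipna=True).fillna(0.0)
    order = sorted(mean_degree.items(), key=lambda item: (-item[1], item[0]))
    hubs = [g for g, _ in order[:n_hubs]]
    return HubRanking(mean_degree=mean_degree, hubs=hubs, n_hubs=n_hubs)
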