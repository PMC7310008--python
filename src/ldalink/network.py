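"""Microbe co-abundance networks, module detection and topic labeling.

Microbes whose profiles — raw relative abundances across patients, or
topic-weight columns of the microbe topic model — are strongly Pearson
correlated are joined by an edge.  The conventional cutoffs differ by
source: 0.8 for topic-based profiles (short, de-noised vectors) and 0.3
for raw abundances.  Modules (densely connected groups, interpretable as
shared metabolic niches) are found by edge-betweenness division, label
propagation, or fast-greedy modularity; nodes are labeled with every
topic for which they rank among the topic's top contributors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nxcomm

from .lda import LDAModel
from .tables import AbundanceTable

__all__ = [
    "MicrobeNetwork",
    "build_network",
    "detect_modules",
    "label_modules_with_topics",
    "RAW_CUTOFF",
    "TOPIC_CUTOFF",
]

#: default edge cutoffs by profile source
RAW_CUTOFF = 0.3
TOPIC_CUTOFF = 0.8


@dataclass
class MicrobeNetwork:
    graph: nx.Graph
    cutoff: float
    source: str  # "raw" | "topic"
    modules: dict[str, int] = field(default_factory=dict)
    topic_labels: dict[str, list[int]] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_list(self) -> pd.DataFrame:
        rows = [(i, j, d["r"]) for i, j, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["microbe_i", "microbe_j", "r"])

    def module_table(self) -> pd.DataFrame:
        rows = [
            (n, self.modules.get(n, -1),
             ",".join(str(t) for t in self.topic_labels.get(n, [])))
            for n in self.graph.nodes
        ]
        return pd.DataFrame(rows, columns=["microbe", "module", "topic_labels"])


def _profiles(X) -> pd.DataFrame:
    """Microbe profile columns from an abundance table or a phi matrix."""
    if isinstance(X, AbundanceTable):
        return X.data
    if isinstance(X, LDAModel):
        return X.phi
    return X  # DataFrame with microbes as columns


def build_network(X, cutoff: float, source: str = "raw", signed: bool = False) -> MicrobeNetwork:
    """Threshold the pairwise Pearson correlation of microbe profiles.

    An edge joins microbes i and j when r >= ``cutoff`` (positive
    co-abundance); ``signed=True`` switches to |r| >= cutoff.  Isolated
    microbes stay in the graph as nodes.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    frame = _profiles(X)
    if frame.shape[1] < 3:
        raise ValueError("need at least 3 microbes to build a network")
    values = frame.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    graph = nx.Graph()
    microbes = list(frame.columns)
    graph.add_nodes_from(microbes)
    n = len(microbes)
    for i in range(n):
        for j in range(i + 1, n):
            r = corr[i, j]
            if np.isnan(r):
                continue
            keep = abs(r) >= cutoff if signed else r >= cutoff
            if keep:
                graph.add_edge(microbes[i], microbes[j], r=float(r))
    return MicrobeNetwork(graph=graph, cutoff=cutoff, source=source)


def _best_modularity_partition(graph: nx.Graph):
    """Girvan-Newman divisive clustering cut at maximum modularity."""
    components = list(nx.connected_components(graph))
    if graph.number_of_edges() == 0:
        return components
    best, best_q = components, nx.community.modularity(graph, components)
    for partition in nxcomm.girvan_newman(graph):
        parts = [set(p) for p in partition]
        q = nx.community.modularity(graph, parts)
        if q > best_q:
            best, best_q = parts, q
    return best


def detect_modules(net: MicrobeNetwork, method: str = "edge_betweenness",
                   seed: int = 0) -> dict[str, int]:
    """Partition the network into modules; assignment also stored on ``net``.

    ``edge_betweenness`` removes highest-betweenness edges divisively and
    cuts the dendrogram at maximum modularity; ``label_propagation`` is
    the seeded asynchronous variant; ``fast_greedy`` is agglomerative
    modularity optimization.  Every node lands in exactly one module.
    """
    graph = net.graph
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    if method == "edge_betweenness":
        parts = _best_modularity_partition(graph)
    elif method == "label_propagation":
        parts = list(nxcomm.asyn_lpa_communities(graph, seed=seed))
    elif method == "fast_greedy":
        if graph.number_of_edges() == 0:
            parts = [{n} for n in graph.nodes]
        else:
            parts = list(nxcomm.greedy_modularity_communities(graph))
    else:
        raise ValueError(f"unknown module detection method {method!r}")
    modules: dict[str, int] = {}
    for mid, part in enumerate(sorted(parts, key=lambda p: (-len(p), sorted(p)[0]))):
        for node in part:
            modules[node] = mid
    net.modules = modules
    return modules


def label_modules_with_topics(net: MicrobeNetwork, phiM: LDAModel,
                              top_n: int = 10) -> dict[str, list[int]]:
    """Label each microbe with the topics it contributes most to.

    Microbe m gets label k when it is among the ``top_n`` largest entries
    of topic k's word distribution; ties at the boundary are all
    included, and a microbe may carry several labels.
    """
    missing = set(net.nodes) - set(phiM.phi.columns)
    if missing:
        raise KeyError(f"network microbes missing from the topic model: {sorted(missing)[:3]}")
    labels: dict[str, list[int]] = {n: [] for n in net.nodes}
    for k in range(phiM.n_topics):
        row = phiM.phi.iloc[k]
        if top_n >= len(row):
            cut = -np.inf
        else:
            cut = np.sort(row.to_numpy())[::-1][top_n - 1]
        top = set(row.index[row.to_numpy() >= cut])
        for node in net.nodes:
            if node in top:
                labels[node].append(k)
    net.topic_labels = labels
    return labels
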