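"""Community detection and merging on the co-expression graph.

Short random walks tend to get trapped in dense subgraphs, so walktrap
communities approximate co-expression modules. Because a module driven by
several latent factors can be over-split (each sub-community tracking one
factor), detected communities are re-examined with a merge statistic: the
observed between-community edge density divided by the density expected if
the pair were a single community,

    delta_ij = [k_ij / (m_i m_j)] / [(k_i + k_j) / (m_i^2 + m_j^2)],

where m_i is the size and k_i the within-edge count of community i and
k_ij the number of edges between the pair. Outlying delta values — above
the median plus four times the (75th percentile - median) spread of all
pairwise deltas — flag pairs that should be one community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import numpy as np

from .network import CoexpressionGraph

logger = logging.getLogger("nmlsa")

MAX_MERGE_ROUNDS = 20


@dataclass
class ModulePartition:
    """Disjoint communities of feature indices with edge bookkeeping."""

    communities: list[set[int]]
    within_edges: np.ndarray = field(default=None)      # k_i per community
    between_edges: np.ndarray = field(default=None)     # k_ij matrix

    def __post_init__(self) -> None:
        all_members = [i for c in self.communities for i in c]
        if len(all_members) != len(set(all_members)):
            raise ValueError("communities must be disjoint")

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.communities], dtype=int)

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def labels(self, n_features: int) -> np.ndarray:
        """Per-feature community label; -1 for unassigned features."""
        lab = np.full(n_features, -1, dtype=int)
        for c, members in enumerate(self.communities):
            lab[list(members)] = c
        return lab


@dataclass
class MergeStatistics:
    """Pairwise merge statistic delta and the pooled outlier cutoff."""

    delta: np.ndarray
    cutoff: float


def _count_edges(communities: list[set[int]], edges: np.ndarray,
                 n_features: int) -> tuple[np.ndarray, np.ndarray]:
    """Within-community edge counts k_i and between counts k_ij."""
    c = len(communities)
    label = np.full(n_features, -1, dtype=int)
    for idx, members in enumerate(communities):
        label[list(members)] = idx
    k_within = np.zeros(c, dtype=int)
    k_between = np.zeros((c, c), dtype=int)
    if len(edges):
        li = label[edges[:, 0]]
        lj = label[edges[:, 1]]
        keep = (li >= 0) & (lj >= 0)
        li, lj = li[keep], lj[keep]
        same = li == lj
        np.add.at(k_within, li[same], 1)
        a = np.minimum(li[~same], lj[~same])
        b = np.maximum(li[~same], lj[~same])
        np.add.at(k_between, (a, b), 1)
        k_between = k_between + k_between.T
    return k_within, k_between


def partition_from_graph(graph: CoexpressionGraph,
                         communities: list[set[int]]) -> ModulePartition:
    k_i, k_ij = _count_edges(communities, graph.edges, graph.n_features)
    return ModulePartition(communities=communities, within_edges=k_i,
                           between_edges=k_ij)


def detect_communities(graph: CoexpressionGraph,
                       steps: int = 4) -> ModulePartition:
    """Walktrap communities of the non-isolated vertices, cut at maximum
    modularity. An empty edge set yields an empty partition."""
    if len(graph.edges) == 0:
        return ModulePartition(communities=[],
                               within_edges=np.zeros(0, dtype=int),
                               between_edges=np.zeros((0, 0), dtype=int))
    vertices = np.unique(graph.edges)
    index_of = {int(v): i for i, v in enumerate(vertices)}
    g = ig.Graph(n=len(vertices),
                 edges=[(index_of[int(i)], index_of[int(j)])
                        for i, j in graph.edges])
    clustering = g.community_walktrap(steps=steps).as_clustering()
    communities = [{int(vertices[i]) for i in cl} for cl in clustering]
    return partition_from_graph(graph, communities)


def merge_statistic(partition: ModulePartition) -> MergeStatistics:
    """delta_ij for every community pair, plus the pooled outlier cutoff.

    A pair with no within-community edges on either side (k_i + k_j = 0)
    carries no evidence and gets delta = 0.
    """
    if partition.n_communities < 2:
        raise ValueError("need at least 2 communities")
    m = partition.sizes.astype(float)
    k_i = partition.within_edges.astype(float)
    k_ij = partition.between_edges.astype(float)
    c = len(m)
    obs = k_ij / np.outer(m, m)
    expect = (k_i[:, None] + k_i[None, :]) / (m[:, None] ** 2 + m[None, :] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(expect > 0, obs / expect, 0.0)
    delta = np.where(k_ij == 0, 0.0, delta)
    np.fill_diagonal(delta, 0.0)
    iu = np.triu_indices(c, k=1)
    pooled = delta[iu]
    cutoff = float(np.median(pooled)
                   + 4.0 * (np.quantile(pooled, 0.75) - np.median(pooled)))
    return MergeStatistics(delta=delta, cutoff=cutoff)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def merge_outliers(partition: ModulePartition, graph: CoexpressionGraph,
                   stats: MergeStatistics | None = None) -> ModulePartition:
    """Merge community pairs whose delta exceeds the pooled outlier cutoff.

    Flagged pairs merge transitively (union-find); delta and the cutoff are
    recomputed and the rule re-applied until a fixed point (capped rounds).
    With fewer than 3 community pairs the pooled distribution is
    meaningless and no merging is attempted.
    """
    current = partition
    for round_no in range(MAX_MERGE_ROUNDS):
        c = current.n_communities
        if c * (c - 1) // 2 < 3:
            return current
        st = stats if (stats is not None and round_no == 0) \
            else merge_statistic(current)
        iu = np.triu_indices(c, k=1)
        pooled = st.delta[iu]
        flagged = pooled > st.cutoff
        if np.quantile(pooled, 0.75) == np.median(pooled):
            # Degenerate spread (typical when most pairs share no edges):
            # the outlier cutoff collapses to the median and any stray edge
            # would count as an outlier. Demand the absolute signature of a
            # split community as well: between-density above the density
            # expected were the pair one community (delta > 1).
            flagged &= pooled > 1.0
        if not flagged.any():
            return current
        uf = _UnionFind(c)
        for a, b in zip(iu[0][flagged], iu[1][flagged]):
            logger.info("merge round %d: communities %d + %d (delta=%.3f > "
                        "cutoff=%.3f)", round_no, a, b,
                        st.delta[a, b], st.cutoff)
            uf.union(int(a), int(b))
        groups: dict[int, set[int]] = {}
        for idx, members in enumerate(current.communities):
            groups.setdefault(uf.find(idx), set()).update(members)
        current = partition_from_graph(graph, list(groups.values()))
    return current


def filter_small(partition: ModulePartition, min_size: int,
                 graph: CoexpressionGraph | None = None) -> ModulePartition:
    """Drop communities with fewer than ``min_size`` features."""
    kept = [c for c in partition.communities if len(c) >= min_size]
    n_dropped = partition.n_communities - len(kept)
    if n_dropped:
        logger.warning("dropped %d communities below min size %d",
                       n_dropped, min_size)
    if graph is not None:
        return partition_from_graph(graph, kept)
    keep_idx = [i for i, c in enumerate(partition.communities)
                if len(c) >= min_size]
    return ModulePartition(
        communities=kept,
        within_edges=(partition.within_edges[keep_idx]
                      if partition.within_edges is not None else None),
        between_edges=(partition.between_edges[np.ix_(keep_idx, keep_idx)]
                       if partition.between_edges is not None else None))
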