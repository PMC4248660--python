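import numpy as np
import pytest

from conftest import clique_edges, graph_from_edges
from nmlsa.modules import (ModulePartition, detect_communities, filter_small,
                           merge_outliers, merge_statistic,
                           partition_from_graph)


def brute_force_delta(communities, edges):
    """Independent recomputation of delta for every community pair."""
    edges = {frozenset(e) for e in map(tuple, edges)}
    c = len(communities)
    delta = np.zeros((c, c))
    for i in range(c):
        for j in range(i + 1, c):
            mi, mj = len(communities[i]), len(communities[j])
            ki = sum(1 for e in edges if e <= communities[i])
            kj = sum(1 for e in edges if e <= communities[j])
            kij = sum(1 for e in edges
                      if len(e & communities[i]) == 1
                      and len(e & communities[j]) == 1)
            if kij == 0 or ki + kj == 0:
                continue
            delta[i, j] = delta[j, i] = ((kij / (mi * mj))
                                         / ((ki + kj) / (mi ** 2 + mj ** 2)))
    return delta


def test_two_cliques_one_bridge():
    edges = (clique_edges(range(20)) + clique_edges(range(20, 40))
             + [(0, 20)])
    g = graph_from_edges(40, edges)
    part = detect_communities(g, steps=4)
    assert sorted(map(len, part.communities)) == [20, 20]
    assert {frozenset(c) for c in part.communities} == {
        frozenset(range(20)), frozenset(range(20, 40))}


def test_single_clique():
    g = graph_from_edges(30, clique_edges(range(30)))
    part = detect_communities(g, steps=4)
    assert part.n_communities == 1
    assert part.communities[0] == set(range(30))


def test_empty_graph_yields_empty_partition():
    g = graph_from_edges(10, [])
    part = detect_communities(g, steps=4)
    assert part.n_communities == 0


def test_sparse_random_graph_has_no_giant_community():
    """Erdos-Renyi G(200, 0.01) should not produce large communities."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(200, k=1)
        mask = rng.random(len(iu[0])) < 0.01
        g = graph_from_edges(200, list(zip(iu[0][mask], iu[1][mask])))
        part = detect_communities(g, steps=4)
        if part.n_communities and max(map(len, part.communities)) >= 50:
            hits += 1
    assert hits <= 1  # >= 95% of seeds stay below 50


def test_merge_statistic_split_cliques():
    """Two 10-cliques fully interconnected: delta = (100/100)/(90/200)."""
    a, b = set(range(10)), set(range(10, 20))
    edges = (clique_edges(a) + clique_edges(b)
             + [(i, j) for i in a for j in b])
    g = graph_from_edges(20, edges)
    part = partition_from_graph(g, [a, b])
    with pytest.raises(ValueError):
        merge_statistic(partition_from_graph(g, [a | b]))
    # need a third community for the pooled distribution; delta check only
    assert part.within_edges.tolist() == [45, 45]
    assert part.between_edges[0, 1] == 100
    st_val = ((100 / (10 * 10)) / ((45 + 45) / (10 ** 2 + 10 ** 2)))
    np.testing.assert_allclose(st_val, 2.2222222222, rtol=1e-9)
    stats = merge_statistic(part)
    np.testing.assert_allclose(stats.delta[0, 1], st_val, rtol=1e-12)


def test_merge_statistic_no_between_edges():
    g = graph_from_edges(20, clique_edges(range(10))
                         + clique_edges(range(10, 20)))
    stats = merge_statistic(partition_from_graph(
        g, [set(range(10)), set(range(10, 20))]))
    assert stats.delta[0, 1] == 0.0


def test_merge_statistic_matches_brute_force(rng):
    """delta on a random graph partition agrees with direct recomputation."""
    iu = np.triu_indices(30, k=1)
    mask = rng.random(len(iu[0])) < 0.3
    edges = list(zip(iu[0][mask], iu[1][mask]))
    comms = [set(range(10)), set(range(10, 18)), set(range(18, 30))]
    g = graph_from_edges(30, edges)
    stats = merge_statistic(partition_from_graph(g, comms))
    expected = brute_force_delta(comms, edges)
    np.testing.assert_allclose(stats.delta, expected, atol=1e-12)
    assert np.allclose(stats.delta, stats.delta.T)


def test_split_community_delta(rng):
    """A G(20, 0.5) community split in half has delta near 2 m^2/(m^2+m^2)
    * (pair count ratio) = 20/9: between-density equals within-density, and
    the denominator's m_i^2 + m_j^2 is about half the merged pair count.

    In particular delta for a split homogeneous community sits well above
    1, the absolute merge signature."""
    deltas = []
    for seed in range(30):
        r = np.random.default_rng(seed)
        iu = np.triu_indices(20, k=1)
        mask = r.random(len(iu[0])) < 0.5
        edges = list(zip(iu[0][mask], iu[1][mask]))
        d = brute_force_delta([set(range(10)), set(range(10, 20))], edges)
        deltas.append(d[0, 1])
    assert abs(np.mean(deltas) - 20.0 / 9.0) < 0.3
    assert all(d > 1.0 for d in deltas)


def test_merge_outliers_planted_split():
    """Ten communities, one split clique among unconnected background:
    only the split pair merges."""
    comms = []
    edges = []
    start = 0
    for k in range(10):
        members = set(range(start, start + 12))
        comms.append(members)
        edges += clique_edges(members)
        start += 12
    # communities 0 and 1 are one split clique: complete bipartite between
    edges += [(i, j) for i in comms[0] for j in comms[1]]
    # faint background connectivity so the pooled spread is positive
    rng = np.random.default_rng(1)
    for k in range(2, 9):
        edges.append((min(comms[k]), min(comms[k + 1])))
    g = graph_from_edges(120, edges)
    part = partition_from_graph(g, comms)
    merged = merge_outliers(part, g)
    assert merged.n_communities == 9
    assert comms[0] | comms[1] in merged.communities
    # total assigned features conserved
    assert sum(map(len, merged.communities)) == 120


def test_merge_outliers_all_equal_deltas_unchanged():
    """Equal deltas give a cutoff equal to the common value; nothing
    strictly exceeds it, so the partition is unchanged."""
    comms = [set(range(i * 10, (i + 1) * 10)) for i in range(4)]
    edges = []
    for c in comms:
        edges += clique_edges(c)
    # identical single bridge between every pair -> identical deltas
    for a in range(4):
        for b in range(a + 1, 4):
            edges.append((min(comms[a]), min(comms[b])))
    g = graph_from_edges(40, edges)
    part = partition_from_graph(g, comms)
    merged = merge_outliers(part, g)
    assert merged.n_communities == 4


def test_merge_outliers_single_community_short_circuit():
    g = graph_from_edges(10, clique_edges(range(10)))
    part = partition_from_graph(g, [set(range(10))])
    assert merge_outliers(part, g).n_communities == 1


def test_merge_never_increases_count(planted_module):
    from nmlsa.config import RunConfig
    from nmlsa.io import ExpressionMatrix
    from nmlsa.network import build_network
    values, _ = planted_module
    expr = ExpressionMatrix(values, [f"g{i}" for i in range(len(values))],
                            [f"s{j}" for j in range(values.shape[1])])
    g = build_network(expr, RunConfig(seed=0))
    part = detect_communities(g, 4)
    merged = merge_outliers(part, g)
    assert merged.n_communities <= part.n_communities
    assert (sum(map(len, merged.communities))
            == sum(map(len, part.communities)))


@pytest.mark.parametrize("sizes,min_size,expected", [
    ([3, 50, 120], 10, [50, 120]),
    ([3, 5], 10, []),
    ([3, 50, 120], 1, [3, 50, 120]),
])
def test_filter_small(sizes, min_size, expected):
    start = 0
    comms = []
    for s in sizes:
        comms.append(set(range(start, start + s)))
        start += s
    part = ModulePartition(communities=comms)
    out = filter_small(part, min_size)
    assert sorted(map(len, out.communities)) == sorted(expected)
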