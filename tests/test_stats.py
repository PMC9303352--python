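"""Macro statistics against closed forms and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from semnet.build import SemanticNetwork
from semnet.stats import (
    MacroStats,
    degree_distribution_similarity,
    detect_communities,
    group_summary,
    macro_stats,
)

from .conftest import make_net

# Printed per-participant full-network rows (age, |V|, <k>, C, L) of the
# study this pipeline reproduces; used as input data for group summaries.
TABLE2_FULL = [
    ("young", 24, 5780, 3.03, 0.091, 8.15),
    ("young", 27, 4836, 3.47, 0.115, 7.13),
    ("young", 27, 4920, 3.31, 0.119, 7.36),
    ("young", 28, 4995, 3.44, 0.136, 7.14),
    ("old", 68, 5275, 3.35, 0.059, 6.54),
    ("old", 68, 6461, 2.63, 0.045, 9.33),
    ("old", 69, 6157, 2.78, 0.053, 8.37),
    ("old", 70, 5792, 2.39, 0.055, 11.3),
]


def brute_force_stats(g: nx.Graph) -> tuple[float, float]:
    """Independent C and L: triangle enumeration + Floyd-Warshall."""
    cs = []
    for v in g.nodes:
        nbrs = list(g[v])
        if len(nbrs) < 2:
            cs.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
        cs.append(links / (len(nbrs) * (len(nbrs) - 1) / 2))
    comp = max(nx.connected_components(g), key=len)
    nodes = sorted(comp)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((len(nodes), len(nodes)))
    for u, v in g.subgraph(comp).edges:
        m[idx[u], idx[v]] = m[idx[v], idx[u]] = 1
    d = floyd_warshall(m, directed=False, unweighted=True)
    iu = np.triu_indices(len(nodes), k=1)
    L = float(d[iu].mean()) if len(nodes) > 1 else float("nan")
    return float(np.mean(cs)), L


def test_triangle_closed_form(triangle):
    ms = macro_stats(triangle)
    assert ms == MacroStats(n_nodes=3, mean_degree=2.0, clustering=1.0, path_length=1.0)


def test_path_closed_form(path3):
    ms = macro_stats(path3)
    assert ms.n_nodes == 3
    assert ms.mean_degree == pytest.approx(4 / 3)
    assert ms.clustering == 0.0
    assert ms.path_length == pytest.approx(4 / 3)


def test_macro_stats_matches_brute_force_on_random_graphs():
    """C and L agree with the enumeration/Floyd-Warshall oracle, and
    <k>*|V| = 2E exactly, on 50 random graphs of up to 12 nodes."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        n = int(rng.integers(3, 13))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.15, 0.8)), seed=int(rng.integers(2**31)))
        nx.set_edge_attributes(g, 1, "weight")
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
        net = SemanticNetwork(graph=g, owner="rand")
        ms = macro_stats(net)
        c_ref, l_ref = brute_force_stats(g)
        assert ms.clustering == pytest.approx(c_ref, abs=1e-12)
        if not np.isnan(l_ref):
            assert ms.path_length == pytest.approx(l_ref, abs=1e-9)
        assert ms.mean_degree * ms.n_nodes == pytest.approx(2 * g.number_of_edges())


def test_group_summary_reproduces_printed_group_means():
    stats = [
        (MacroStats(n_nodes=v, mean_degree=k, clustering=c, path_length=l), grp)
        for grp, _age, v, k, c, l in TABLE2_FULL
    ]
    by_group = {s.group: s for s in group_summary(stats)}
    assert round(by_group["old"].n_nodes) == 5921
    assert round(by_group["young"].n_nodes) == 5133
    assert round(by_group["old"].clustering, 3) == 0.053
    assert round(by_group["young"].clustering, 3) == 0.115
    assert max(v for _, _, v, *_ in TABLE2_FULL) == 6461


def test_group_summary_single_network_is_identity(triangle):
    ms = macro_stats(triangle)
    (gs,) = group_summary([(ms, "young")], groups=("young",))
    assert (gs.n_nodes, gs.mean_degree, gs.clustering, gs.path_length) == (
        ms.n_nodes,
        ms.mean_degree,
        ms.clustering,
        ms.path_length,
    )


def test_group_summary_unknown_label_rejected(triangle):
    with pytest.raises(ValueError, match="unknown group"):
        group_summary([(macro_stats(triangle), "middle")])


def test_degree_similarity_self_is_one(triangle):
    assert degree_distribution_similarity(triangle, triangle) == pytest.approx(1.0)


def test_degree_similarity_reversed_ranks():
    a = make_net([("x", "y"), ("x", "z"), ("x", "w")])  # deg x=3, others 1
    b = make_net([("y", "x"), ("y", "z"), ("y", "w"), ("z", "x"), ("z", "w")])
    r = degree_distribution_similarity(a, b)
    assert -1.0 <= r < 0.5  # x is hub in a but not in b


def test_degree_similarity_independent_graphs_near_permutation_null():
    """|r| for unrelated graphs is within the permutation-null spread."""
    rng = np.random.default_rng(11)
    nodes = [f"n{i}" for i in range(200)]

    def random_net(seed):
        g = nx.gnp_random_graph(200, 0.05, seed=seed)
        g = nx.relabel_nodes(g, dict(enumerate(nodes)))
        nx.set_edge_attributes(g, 1, "weight")
        return SemanticNetwork(graph=g, owner=str(seed))

    a, b = random_net(1), random_net(2)
    r = degree_distribution_similarity(a, b)
    da = np.array([a.graph.degree(v) for v in nodes], float)
    db = np.array([b.graph.degree(v) for v in nodes], float)
    null = []
    for _ in range(500):
        perm = rng.permutation(200)
        null.append(np.corrcoef(da, db[perm])[0, 1])
    assert abs(r) < np.quantile(np.abs(null), 0.999)


def test_degree_similarity_needs_two_shared_nodes():
    with pytest.raises(ValueError):
        degree_distribution_similarity(
            make_net([("a", "b")]), make_net([("b", "c")])
        )


def test_louvain_two_triangles_bridged():
    net = make_net(
        [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z"), ("c", "x")]
    )
    parts = detect_communities(net, seed=0)
    assert len(parts) == 2
    assert {frozenset(p) for p in parts} == {
        frozenset({"a", "b", "c"}),
        frozenset({"x", "y", "z"}),
    }


def test_louvain_complete_graph_single_community():
    g = nx.complete_graph(6)
    g = nx.relabel_nodes(g, {i: f"k{i}" for i in range(6)})
    nx.set_edge_attributes(g, 1, "weight")
    parts = detect_communities(SemanticNetwork(graph=g, owner="k"), seed=0)
    assert len(parts) == 1


def test_louvain_recovers_planted_partition():
    g = nx.planted_partition_graph(2, 60, 0.35, 0.01, seed=4)
    labels = {v: g.nodes[v]["block"] for v in g.nodes}
    g = nx.Graph(g)
    nx.set_edge_attributes(g, 1, "weight")
    parts = detect_communities(SemanticNetwork(graph=g, owner="pp"), seed=1)
    # map each community to its majority planted block and count agreement
    agree = sum(
        max(sum(labels[v] == b for v in p) for b in (0, 1)) for p in parts
    )
    assert agree / g.number_of_nodes() >= 0.95
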