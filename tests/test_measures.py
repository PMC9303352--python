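"""PageRank, PPMI, and Katz walk similarity against independent oracles."""

import math

import networkx as nx
import numpy as np
import pytest

from semnet.build import SemanticNetwork
from semnet.measures import (
    ConvergenceError,
    cosine,
    pagerank,
    ppmi_transform,
    walk_similarity,
)

from .conftest import make_net


def dense_pagerank(net, damping=0.85, weighted=False):
    """Independent oracle: direct linear solve of the stationarity equation."""
    nodes = sorted(net.graph.nodes)
    n = len(nodes)
    a = nx.to_numpy_array(net.graph, nodelist=nodes, weight="weight" if weighted else None)
    s = a.sum(axis=1)
    p = np.divide(a, s[:, None], out=np.full_like(a, 1.0 / n), where=s[:, None] > 0)
    # solve pi = (1-d)/n * 1 + d * P^T pi
    pi = np.linalg.solve(np.eye(n) - damping * p.T, np.full(n, (1 - damping) / n))
    pi = pi / pi.sum()
    return nodes, pi * n


def random_net(n, p, seed, weighted=True):
    g = nx.gnp_random_graph(n, p, seed=seed)
    rng = np.random.default_rng(seed)
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in range(n)})
    for _, _, d in g.edges(data=True):
        d["weight"] = int(rng.integers(1, 6)) if weighted else 1
    return SemanticNetwork(graph=g, owner=f"r{seed}")


# ---------------------------------------------------------------------------
# PPMI


def test_ppmi_perfect_association_is_one_bit():
    out = ppmi_transform({("a", "b"): 2, ("c", "d"): 2})
    assert out == pytest.approx({("a", "b"): 1.0, ("c", "d"): 1.0})


def test_ppmi_independence_yields_empty_map():
    # joint equal to product of marginals: complete bipartite uniform counts
    weights = {(a, b): 1 for a in "ab" for b in "cd"}
    assert ppmi_transform(weights) == {}


def test_ppmi_matches_direct_formula_on_random_counts():
    rng = np.random.default_rng(8)
    pairs = {}
    names = [f"w{i}" for i in range(10)]
    for _ in range(25):
        a, b = rng.choice(10, 2, replace=False)
        pairs[(names[min(a, b)], names[max(a, b)])] = int(rng.integers(1, 9))
    out = ppmi_transform(pairs)
    total = sum(pairs.values())
    marg = {}
    for (a, b), w in pairs.items():
        marg[a] = marg.get(a, 0) + w
        marg[b] = marg.get(b, 0) + w
    for pair, w in pairs.items():
        a, b = pair
        val = math.log2((w / total) / (marg[a] / total * marg[b] / total))
        if val > 0:
            assert out[pair] == pytest.approx(val, abs=1e-12)
        else:
            assert pair not in out


def test_ppmi_empty_input_rejected():
    with pytest.raises(ValueError):
        ppmi_transform({})


# ---------------------------------------------------------------------------
# PageRank


def test_pagerank_cycle_symmetry():
    net = make_net([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
    cv = pagerank(net)
    assert cv.scaled == pytest.approx(np.ones(4), abs=1e-9)


def test_pagerank_isolated_node_is_one():
    g = nx.Graph()
    g.add_node("x")
    cv = pagerank(SemanticNetwork(graph=g, owner="i"))
    assert cv["x"] == pytest.approx(1.0)


def test_pagerank_path_worked_example(path3):
    cv = pagerank(path3, damping=0.85)
    assert cv["b"] == pytest.approx(1.4595, abs=5e-5)
    assert cv["a"] == pytest.approx(0.7703, abs=5e-5)
    assert cv["a"] == cv["c"]
    nodes, ref = dense_pagerank(path3)
    assert cv.scaled == pytest.approx(ref, abs=1e-10)


@pytest.mark.parametrize("weighted", [False, True])
def test_pagerank_matches_dense_solve_on_random_graphs(weighted):
    for seed in range(8):
        net = random_net(25, 0.2, seed)
        cv = pagerank(net, weighted=weighted)
        nodes, ref = dense_pagerank(net, weighted=weighted)
        assert list(cv.nodes) == nodes
        assert np.max(np.abs(cv.scaled - ref)) < 1e-10


def test_pagerank_matches_networkx():
    net = random_net(30, 0.15, 3)
    cv = pagerank(net, weighted=True)
    ref = nx.pagerank(net.graph, alpha=0.85, weight="weight", tol=1e-12)
    for v in cv.nodes:
        assert cv[v] / net.n_nodes == pytest.approx(ref[v], abs=1e-8)


def test_pagerank_scaled_mean_is_one():
    for seed in range(3):
        net = random_net(40, 0.1, seed)
        cv = pagerank(net)
        assert cv.scaled.mean() == pytest.approx(1.0, abs=1e-12)


def test_pagerank_nonconvergence_reports_residual(path3):
    with pytest.raises(ConvergenceError) as err:
        pagerank(path3, max_iter=2)
    assert err.value.residual > 0


# ---------------------------------------------------------------------------
# walk similarity


def test_two_node_closed_form_cosine():
    net = make_net([("a", "b")])
    model = walk_similarity(net, alpha=0.5, use_ppmi=False)
    # S' = (I - 0.5 P)^{-1} has rows (4/3, 2/3) and (2/3, 4/3) -> cosine 0.8
    assert model.cosine("a", "b") == pytest.approx(0.8, abs=1e-12)
    assert model.cosine("a", "a") == pytest.approx(1.0)


def test_identical_neighborhoods_cosine_one():
    net = make_net([("hub1", "b"), ("hub1", "c"), ("hub2", "b"), ("hub2", "c")])
    model = walk_similarity(net, alpha=0.6, use_ppmi=False)
    assert model.cosine("hub1", "hub2") == pytest.approx(1.0)


def test_cross_component_cosine_zero():
    net = make_net([("a", "b"), ("x", "y")])
    model = walk_similarity(net, alpha=0.75, use_ppmi=False)
    assert model.cosine("a", "x") == 0.0


def test_cosine_symmetry_and_brute_force():
    for seed in range(5):
        net = random_net(10, 0.4, seed)
        model = walk_similarity(net, alpha=0.7, use_ppmi=False)
        s = model.matrix
        for i, a in enumerate(model.nodes):
            for j, b in enumerate(model.nodes):
                na, nb = np.linalg.norm(s[i]), np.linalg.norm(s[j])
                ref = float(s[i] @ s[j] / (na * nb)) if na > 0 and nb > 0 else 0.0
                assert cosine(model, a, b) == pytest.approx(ref, abs=1e-12)
                assert cosine(model, a, b) == pytest.approx(cosine(model, b, a))


def test_cosine_unknown_node_is_key_error():
    model = walk_similarity(make_net([("a", "b")]), use_ppmi=False)
    with pytest.raises(KeyError):
        model.cosine("a", "zzz")


@pytest.mark.parametrize("use_ppmi", [False, True])
def test_resolvent_inverse_identity(use_ppmi):
    """(I - alpha P)(I + S) = I on random graphs (inverse check)."""
    for seed in range(4):
        net = random_net(30, 0.15, seed)
        alpha = 0.75
        model = walk_similarity(net, alpha=alpha, use_ppmi=use_ppmi)
        n = len(model.nodes)
        from semnet.measures import _transition_matrix

        _, p = _transition_matrix(net, use_ppmi)
        lhs = (np.eye(n) - alpha * p.toarray()) @ (np.eye(n) + model.matrix)
        # rows of words isolated after PPMI stay zero in P; identity holds there too
        assert np.max(np.abs(lhs - np.eye(n))) < 1e-8


def test_truncated_series_agrees_with_closed_form():
    """The geometric series approaches the resolvent at the analytic rate:
    after t terms the gap is below alpha^(t+1)/(1-alpha), and once the
    terms fall below the implementation's tolerance the gap is < 1e-8."""
    alpha = 0.75
    for seed in range(3):
        net = random_net(40, 0.12, seed)
        dense = walk_similarity(net, alpha=alpha, use_ppmi=False)
        from semnet.measures import _transition_matrix

        _, p = _transition_matrix(net, False)
        p = p.toarray()
        series = np.zeros_like(p)
        term = np.eye(p.shape[0])
        for t in range(1, 201):
            term = alpha * term @ p
            series += term
            gap = np.max(np.abs(series - dense.matrix))
            if t == 50:
                assert gap < alpha ** 51 / (1 - alpha)
            if np.max(np.abs(term)) < 1e-10:
                break
        assert gap < 1e-8


def test_dense_and_series_routes_agree():
    net = random_net(35, 0.15, 9)
    dense = walk_similarity(net, alpha=0.75, use_ppmi=True)
    series = walk_similarity(net, alpha=0.75, use_ppmi=True, dense_cutoff=10)
    assert np.max(np.abs(dense.matrix - series.matrix)) < 1e-8
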