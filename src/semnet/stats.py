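"""Macroscopic network structure and group-level summaries.

The four statistics reported per network are the node count |V|, the
unweighted mean degree <k> = 2E/|V|, the mean local clustering coefficient
C (nodes of degree < 2 contribute 0 and stay in the mean), and the average
shortest path length L over unordered node pairs within the largest
connected component, treating edges as unweighted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Hashable, Sequence

import igraph as ig
import networkx as nx
import numpy as np
from scipy import stats as sps

from .build import SemanticNetwork


@dataclass(frozen=True)
class MacroStats:
    n_nodes: int
    mean_degree: float
    clustering: float
    path_length: float


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n_networks: int
    n_nodes: float
    mean_degree: float
    clustering: float
    path_length: float


def _avg_path_length_lcc(g: nx.Graph) -> float:
    """Mean shortest-path length over unordered pairs of the largest component.

    Delegates to igraph's C implementation; for a connected undirected graph
    the mean over ordered pairs equals the mean over unordered pairs.
    """
    if g.number_of_nodes() == 0:
        return math.nan
    comp = max(nx.connected_components(g), key=len)
    if len(comp) < 2:
        return math.nan
    nodes = list(comp)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.subgraph(comp).edges()]
    h = ig.Graph(n=len(nodes), edges=edges, directed=False)
    return float(h.average_path_length(directed=False, unconn=False))


def macro_stats(net: SemanticNetwork) -> MacroStats:
    """Compute |V|, <k>, C and L for one network (weights ignored)."""
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    return MacroStats(
        n_nodes=n,
        mean_degree=2.0 * g.number_of_edges() / n,
        clustering=float(nx.average_clustering(g, count_zeros=True)),
        path_length=_avg_path_length_lcc(g),
    )


def group_summary(
    stats: Sequence[tuple[MacroStats, str]], groups: Sequence[str] = ("young", "old")
) -> list[GroupSummary]:
    """Unweighted arithmetic means of each macro statistic per group."""
    known = set(groups)
    bad = {g for _, g in stats if g not in known}
    if bad:
        raise ValueError(f"unknown group label(s) {sorted(bad)}; expected {sorted(known)}")
    out = []
    for label in groups:
        member = [s for s, g in stats if g == label]
        if not member:
            continue
        out.append(
            GroupSummary(
                group=label,
                n_networks=len(member),
                **{
                    f.name: float(np.mean([getattr(s, f.name) for s in member]))
                    for f in fields(MacroStats)
                },
            )
        )
    return out


def degree_distribution_similarity(net_a: SemanticNetwork, net_b: SemanticNetwork) -> float:
    """Pearson correlation of the two degree vectors over shared nodes."""
    shared = sorted(net_a.nodes & net_b.nodes)
    if len(shared) < 2:
        raise ValueError("need >= 2 shared nodes")
    da = [net_a.graph.degree(v) for v in shared]
    db = [net_b.graph.degree(v) for v in shared]
    if da == db:
        return 1.0  # includes regular graphs compared with themselves
    if len(set(da)) == 1 or len(set(db)) == 1:
        return float("nan")  # correlation with a constant vector is undefined
    return float(sps.pearsonr(da, db).statistic)


def detect_communities(
    net: SemanticNetwork, seed: int = 0, weighted: bool = True
) -> list[set[Hashable]]:
    """Louvain modularity-maximizing partition (deterministic under a seed).

    Nodes are processed in sorted order so ties break reproducibly;
    singleton components become singleton communities.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(net.graph.nodes))
    g.add_weighted_edges_from(
        (u, v, d["weight"] if weighted else 1.0)
        for u, v, d in net.graph.edges(data=True)
    )
    parts = nx.community.louvain_communities(g, weight="weight", seed=seed)
    return [set(p) for p in parts]
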