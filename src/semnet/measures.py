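"""Node-level measures: scaled PageRank centrality and Katz walk similarity.

Centrality is the stationary distribution of a damped random walk on the
(symmetric) word graph, multiplied by |V| so that networks of different
sizes are comparable (the scaled values have mean exactly 1).

Relatedness between words uses Katz walk similarity: with P the
row-normalized (optionally PPMI-reweighted) adjacency matrix and decay
alpha in (0, 1),

    S = sum_{t>=1} alpha^t P^t = (I - alpha P)^{-1} - I,

and a word pair's relatedness is the cosine between their rows of S.
Subtracting I removes self-walks so the cosine reflects shared
neighborhoods. PPMI (positive pointwise mutual information) reweighting
suppresses the contribution of globally frequent responses, which would
otherwise dominate walk profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .build import SemanticNetwork


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach tolerance; carries the last residual."""

    def __init__(self, residual: float, n_iter: int):
        super().__init__(f"no convergence after {n_iter} iterations (residual {residual:.3e})")
        self.residual = residual
        self.n_iter = n_iter


def ppmi_transform(
    weights: dict[tuple[str, str], float],
) -> dict[tuple[str, str], float]:
    """Positive pointwise mutual information of an unordered-pair count map.

    With W the total count, p(i,j) = w_ij / W and marginals
    p(i) = sum_j w_ij / W (each undirected edge feeds both endpoints'
    marginals), PPMI(i,j) = max(0, log2 p(i,j) / (p(i) p(j))). Pairs whose
    PPMI is zero are dropped.
    """
    if not weights:
        raise ValueError("empty weight map")
    total = float(sum(weights.values()))
    marginal: dict[str, float] = {}
    for (a, b), w in weights.items():
        marginal[a] = marginal.get(a, 0.0) + w
        marginal[b] = marginal.get(b, 0.0) + w
    out: dict[tuple[str, str], float] = {}
    for (a, b), w in weights.items():
        val = math.log2((w / total) / ((marginal[a] / total) * (marginal[b] / total)))
        if val > 0.0:
            out[(a, b)] = val
    return out


@dataclass(frozen=True)
class CentralityVector:
    """Scaled PageRank (raw PageRank times |V|) over a fixed node order."""

    nodes: tuple[str, ...]
    scaled: np.ndarray
    damping: float

    def __post_init__(self):
        object.__setattr__(self, "_index", {v: i for i, v in enumerate(self.nodes)})

    def __getitem__(self, word: str) -> float:
        return float(self.scaled[self._index[word]])

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def as_dict(self) -> dict[str, float]:
        return {v: float(s) for v, s in zip(self.nodes, self.scaled)}


def _adjacency(net: SemanticNetwork, weighted: bool) -> tuple[list[str], sp.csr_array]:
    nodes = sorted(net.graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, d in net.graph.edges(data=True):
        w = float(d["weight"]) if weighted else 1.0
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    a = sp.csr_array((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    return nodes, a


def pagerank(
    net: SemanticNetwork,
    damping: float = 0.85,
    weighted: bool = False,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> CentralityVector:
    """Scaled PageRank by power iteration on the symmetrized graph.

    Iterates x <- (1-d)/n + d (A^T (x / s) + m/n) where s is node
    out-strength and m the mass on dangling (isolated) nodes, until the L1
    change drops below ``tol``. The result is normalized to sum 1 and
    returned multiplied by |V|.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    nodes, a = _adjacency(net, weighted)
    n = len(nodes)
    strength = np.asarray(a.sum(axis=1)).ravel()
    dangling = strength == 0
    safe = np.where(dangling, 1.0, strength)
    x = np.full(n, 1.0 / n)
    for it in range(max_iter):
        contrib = x / safe
        contrib[dangling] = 0.0
        x_new = (1.0 - damping) / n + damping * (a.T @ contrib + x[dangling].sum() / n)
        delta = float(np.abs(x_new - x).sum())
        x = x_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(delta, max_iter)
    x = x / x.sum()
    return CentralityVector(nodes=tuple(nodes), scaled=x * n, damping=damping)


@dataclass
class SimilarityModel:
    """Katz walk-similarity rows over a fixed node order, with cosine lookup."""

    nodes: tuple[str, ...]
    matrix: np.ndarray  # S = (I - alpha P)^{-1} - I, row i = walk profile of node i
    alpha: float
    use_ppmi: bool

    def __post_init__(self):
        self._index = {v: i for i, v in enumerate(self.nodes)}
        self._norms = np.linalg.norm(self.matrix, axis=1)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def cosine(self, a: str, b: str) -> float:
        """Cosine between the walk profiles of two words (0 if either is
        isolated in the reweighted graph; 1 for a connected word with itself)."""
        i, j = self._index[a], self._index[b]
        denom = self._norms[i] * self._norms[j]
        if denom == 0.0:
            return 0.0
        return float(self.matrix[i] @ self.matrix[j] / denom)

    def cosine_submatrix(self, words: list[str]) -> np.ndarray:
        """Pairwise cosine matrix for a subset of words (vectorized)."""
        idx = [self._index[w] for w in words]
        rows = self.matrix[idx]
        norms = self._norms[idx]
        safe = np.where(norms == 0.0, 1.0, norms)
        c = (rows @ rows.T) / np.outer(safe, safe)
        c[norms == 0.0, :] = 0.0
        c[:, norms == 0.0] = 0.0
        return c


def _transition_matrix(net: SemanticNetwork, use_ppmi: bool) -> tuple[list[str], sp.csr_array]:
    nodes = sorted(net.graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    weights = net.edge_weights()
    if use_ppmi:
        weights = ppmi_transform(weights)
    rows, cols, vals = [], [], []
    for (a, b), w in weights.items():
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
        vals += [float(w), float(w)]
    adj = sp.csr_array((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    strength = np.asarray(adj.sum(axis=1)).ravel()
    inv = np.where(strength > 0, 1.0 / np.where(strength > 0, strength, 1.0), 0.0)
    p = sp.csr_array(sp.diags_array(inv) @ adj)
    return nodes, p


def walk_similarity(
    net: SemanticNetwork,
    alpha: float = 0.75,
    use_ppmi: bool = True,
    dense_cutoff: int = 2000,
    series_tol: float = 1e-10,
    max_terms: int = 2000,
) -> SimilarityModel:
    """Katz walk similarity S = (I - alpha P)^{-1} - I.

    P row-normalizes the (optionally PPMI-reweighted) adjacency, so its
    spectral radius is at most 1 and the resolvent exists for alpha < 1.
    Networks up to ``dense_cutoff`` nodes use a dense LU solve; larger ones
    accumulate the geometric series sum alpha^t P^t until the largest entry
    of the current term falls below ``series_tol`` (both routes agree to
    high precision on overlapping sizes).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    nodes, p = _transition_matrix(net, use_ppmi)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    if n <= dense_cutoff:
        dense = alpha * p.toarray()
        s = scipy.linalg.solve(np.eye(n) - dense, np.eye(n)) - np.eye(n)
    else:
        term = (alpha * p).toarray()
        s = term.copy()
        p_csr = p.tocsr() if not sp.issparse(p) else p
        for _ in range(max_terms):
            term = alpha * (p_csr @ term)
            s += term
            if np.abs(term).max() < series_tol:
                break
        else:  # pragma: no cover - defensive; alpha < 1 guarantees decay
            raise ConvergenceError(float(np.abs(term).max()), max_terms)
    return SimilarityModel(nodes=tuple(nodes), matrix=s, alpha=alpha, use_ppmi=use_ppmi)


def cosine(model: SimilarityModel, a: str, b: str) -> float:
    """Functional alias for :meth:`SimilarityModel.cosine`."""
    return model.cosine(a, b)
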