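"""Measurement-quality analyses: repeat-encounter consistency, repeated
cue-response pair rates, and correlations of node measures across networks.

Repeat consistency asks: of the responses given at the second encounter of
a repeated cue, what proportion had also been given at the first encounter
(set semantics per cue, response position ignored)? The repeat-association
profile asks how often the same cue-response pair occurs more than once —
a proxy for how graded a network's edge weights can be. Cross-network
correlations quantify how much of a node measure (centrality, or pairwise
cosine structure) two networks share over a common node set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import AssociationRecord
from .measures import SimilarityModel


@dataclass(frozen=True)
class ReliabilityReport:
    participant_id: str
    repeat_consistency: float
    pct_pairs_repeated: float  # percentage of distinct pairs with count > 1
    max_pair_count: int


def repeated_cue_consistency(
    records: Sequence[AssociationRecord], direction: str = "second_vs_first"
) -> float:
    """Proportion of repeat-encounter responses already given at the first
    encounter of the same cue.

    ``direction='first_vs_second'`` checks first-encounter responses against
    the repeat encounter instead (the two differ when response counts do).
    """
    if direction not in {"second_vs_first", "first_vs_second"}:
        raise ValueError(f"unknown direction {direction!r}")
    firsts: dict[str, set[str]] = {}
    seconds: dict[str, set[str]] = {}
    for rec in records:
        store = seconds if rec.is_repeat else firsts
        store.setdefault(rec.cue, set()).update(rec.responses)
    cues = [c for c in seconds if c in firsts]
    if not cues:
        raise ValueError("no repeated cue with a matching first encounter")
    if direction == "first_vs_second":
        firsts, seconds = seconds, firsts
    hits = sum(len(seconds[c] & firsts[c]) for c in cues)
    total = sum(len(seconds[c]) for c in cues)
    return hits / total


def repeat_association_profile(
    records: Sequence[AssociationRecord],
) -> tuple[float, int]:
    """(percentage of distinct cue-response pairs occurring more than once,
    maximum occurrence count of any pair)."""
    if not records:
        raise ValueError("no records")
    counts: Counter = Counter()
    for rec in records:
        for resp in rec.responses:
            counts[(min(rec.cue, resp), max(rec.cue, resp))] += 1
    n_repeated = sum(1 for c in counts.values() if c > 1)
    return 100.0 * n_repeated / len(counts), max(counts.values())


def reliability_report(records: Sequence[AssociationRecord]) -> ReliabilityReport:
    """Bundle the per-participant reliability statistics."""
    pids = {r.participant_id for r in records}
    if len(pids) != 1:
        raise ValueError("records must belong to a single participant")
    pct, mx = repeat_association_profile(records)
    return ReliabilityReport(
        participant_id=pids.pop(),
        repeat_consistency=repeated_cue_consistency(records),
        pct_pairs_repeated=pct,
        max_pair_count=mx,
    )


def cross_network_measure_correlation(
    vectors: Mapping[str, Mapping[str, float]], shared_nodes: Sequence[str]
) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of per-node measures over shared nodes.

    ``vectors`` maps a network label to a word -> value mapping. A pair
    involving a constant vector is reported as NaN (undefined).
    """
    if len(vectors) < 2:
        raise ValueError("need >= 2 networks")
    shared = list(shared_nodes)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared nodes")
    labels = list(vectors)
    data = np.array([[vectors[lab][w] for w in shared] for lab in labels])
    mat = np.eye(len(labels))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if np.ptp(data[i]) == 0 or np.ptp(data[j]) == 0:
                r = np.nan
            else:
                r = sps.pearsonr(data[i], data[j]).statistic
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=labels, columns=labels)


def cosine_triangle_vectors(
    models: Mapping[str, SimilarityModel],
    shared_nodes: Sequence[str],
    max_pairs: int = 100_000,
    seed: int = 0,
) -> tuple[dict[str, dict[str, float]], float | None]:
    """Upper-triangle pairwise-cosine values per network over shared nodes,
    in a form consumable by :func:`cross_network_measure_correlation`.

    When the number of unordered pairs exceeds ``max_pairs``, one common
    seeded subsample of pair indices is used for every network and the
    binomial-style Monte-Carlo standard error of the implied correlation
    estimates is returned; otherwise the SE slot is None.
    """
    shared = list(shared_nodes)
    n = len(shared)
    iu = np.triu_indices(n, k=1)
    n_pairs = iu[0].size
    se = None
    if n_pairs > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(n_pairs, size=max_pairs, replace=False)
        iu = (iu[0][keep], iu[1][keep])
        n_pairs = max_pairs
        se = 1.0 / np.sqrt(n_pairs - 3)  # Fisher-z scale approximation
    out: dict[str, dict[str, float]] = {}
    for label, model in models.items():
        c = model.cosine_submatrix(shared)
        tri = c[iu]
        out[label] = {f"pair{i}": float(v) for i, v in enumerate(tri)}
    return out, se


def cosine_node_mean_vectors(
    models: Mapping[str, SimilarityModel], shared_nodes: Sequence[str]
) -> dict[str, dict[str, float]]:
    """Alternative cosine reading: per-node mean cosine to the other shared
    nodes, one value per node per network."""
    shared = list(shared_nodes)
    n = len(shared)
    out: dict[str, dict[str, float]] = {}
    for label, model in models.items():
        c = model.cosine_submatrix(shared)
        np.fill_diagonal(c, 0.0)
        means = c.sum(axis=1) / (n - 1)
        out[label] = {w: float(v) for w, v in zip(shared, means)}
    return out


def correlation_summary(
    corr: pd.DataFrame, aggregate_label: str = "aggregate"
) -> dict[str, float]:
    """Mean individual-vs-aggregate and individual-vs-individual correlations."""
    labels = list(corr.index)
    ind = [l for l in labels if l != aggregate_label]
    iva = [corr.loc[l, aggregate_label] for l in ind] if aggregate_label in labels else []
    ivi = [corr.loc[a, b] for i, a in enumerate(ind) for b in ind[i + 1 :]]
    return {
        "ind_vs_agg_mean": float(np.nanmean(iva)) if iva else float("nan"),
        "ind_vs_ind_mean": float(np.nanmean(ivi)) if ivi else float("nan"),
    }
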