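"""Construct semantic networks from free-association records.

A cue encounter yields up to three responses; every distinct cue-response
pair becomes a weighted, undirected edge whose weight counts how often the
pair occurred. Aggregate networks pool the pairs of several participants,
so their weights sum and edge strengths become more graded than in any
single individual's network. Common networks restrict each network to the
nodes shared by all participants, equalizing coverage for comparison.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .io import AssociationRecord


@dataclass
class SemanticNetwork:
    """Undirected, weighted word graph with ownership metadata.

    Edge weights are positive co-occurrence counts (or nonnegative reals
    after reweighting). No self-loops.
    """

    graph: nx.Graph
    owner: str = "aggregate"
    group: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_weights(self) -> dict[tuple[str, str], float]:
        """Map from lexicographically ordered word pair to weight."""
        return {
            (min(u, v), max(u, v)): d["weight"] for u, v, d in self.graph.edges(data=True)
        }

    def total_weight(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))


def _pair_counts(records: Iterable["AssociationRecord"], include_repeats: bool) -> Counter:
    counts: Counter = Counter()
    for rec in records:
        if rec.is_repeat and not include_repeats:
            continue
        for resp in rec.responses:
            if resp == rec.cue:  # self-association carries no edge
                continue
            counts[(min(rec.cue, resp), max(rec.cue, resp))] += 1
    return counts


def _network_from_counts(counts: Counter, owner: str, group: str | None) -> SemanticNetwork:
    g = nx.Graph()
    for (a, b), w in counts.items():
        g.add_edge(a, b, weight=w)
    return SemanticNetwork(graph=g, owner=owner, group=group)


def build_individual_network(
    records: Sequence["AssociationRecord"],
    include_repeats: bool = True,
    group: str | None = None,
) -> SemanticNetwork:
    """Build one participant's network from their association records.

    Every cue and every response becomes a node (responses never used as
    cues included); each distinct cue-response pair becomes one edge whose
    weight counts occurrences across positions and encounters. Responses
    identical to their cue are discarded. ``include_repeats`` controls
    whether second encounters of repeated cues contribute.
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    owners = {r.participant_id for r in records}
    if len(owners) != 1:
        raise ValueError(f"records span multiple participants: {sorted(owners)}")
    counts = _pair_counts(records, include_repeats)
    return _network_from_counts(counts, owner=owners.pop(), group=group)


def build_aggregate_network(
    all_records: Sequence["AssociationRecord"],
    participants: Sequence[str] | None = None,
    include_repeats: bool = True,
) -> SemanticNetwork:
    """Pool every participant's cue-response pairs into one aggregate network.

    Weights sum across participants, so shared associations accumulate
    weight while idiosyncratic ones stay at 1.
    """
    all_records = list(all_records)
    present = {r.participant_id for r in all_records}
    if participants is not None:
        unknown = present - set(participants)
        if unknown:
            raise ValueError(f"records from undeclared participants: {sorted(unknown)}")
        all_records = [r for r in all_records if r.participant_id in set(participants)]
        present = {r.participant_id for r in all_records}
    if len(present) < 2:
        raise ValueError("aggregate network requires records from >= 2 participants")
    counts = _pair_counts(all_records, include_repeats)
    return _network_from_counts(counts, owner="aggregate", group=None)


def common_subnetworks(nets: Sequence[SemanticNetwork]) -> list[SemanticNetwork]:
    """Induce each network on the intersection of all node sets.

    All outputs have the same node count; edges are restricted to pairs of
    surviving nodes with weights unchanged.
    """
    if len(nets) < 2:
        raise ValueError("need >= 2 networks")
    shared = set.intersection(*(n.nodes for n in nets))
    if not shared:
        raise ValueError("node-set intersection is empty")
    out = []
    for net in nets:
        sub = net.graph.subgraph(shared).copy()
        out.append(
            SemanticNetwork(graph=sub, owner=net.owner, group=net.group, meta=dict(net.meta))
        )
    return out
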