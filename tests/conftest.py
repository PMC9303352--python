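"""Shared fixtures: tiny hand-built networks and a cached small cohort."""

from __future__ import annotations

import networkx as nx
import pytest

from semnet.build import SemanticNetwork
from semnet.io import AssociationRecord
from semnet.simulate import simulate_cohort, small_cohort_config


def make_net(edges, owner="test", group=None) -> SemanticNetwork:
    """Build a SemanticNetwork from (u, v, w) or (u, v) tuples."""
    g = nx.Graph()
    for e in edges:
        u, v, *w = e
        g.add_edge(u, v, weight=w[0] if w else 1)
    return SemanticNetwork(graph=g, owner=owner, group=group)


def rec(pid, idx, cue, responses, is_repeat=False) -> AssociationRecord:
    return AssociationRecord(
        participant_id=pid,
        encounter_index=idx,
        cue=cue,
        responses=tuple(responses),
        is_repeat=is_repeat,
    )


@pytest.fixture(scope="session")
def triangle():
    return make_net([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture(scope="session")
def path3():
    return make_net([("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def small_cohort():
    """One reduced-scale simulated cohort with behavior, shared across tests."""
    return simulate_cohort(small_cohort_config(), seed=42)
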