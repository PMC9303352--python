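"""Determinism and parameter-recovery properties of the cohort generator."""

import dataclasses

import networkx as nx
import numpy as np
import pytest

from semnet.build import build_individual_network
from semnet.measures import pagerank, walk_similarity
from semnet.reliability import repeated_cue_consistency
from semnet.simulate import (
    ANIMAL_CATEGORY,
    BehaviorParams,
    GroupParams,
    expected_response_yield,
    generate_truth_network,
    make_lexicon,
    simulate_associations,
    simulate_cohort,
    simulate_episodic,
    simulate_fluency,
    simulate_paired,
    small_cohort_config,
)


def test_expected_yield_closed_form():
    assert expected_response_yield(3000, 600) == 10800
    assert expected_response_yield(10, 0, responses_per_cue=2) == 20


def test_lexicon_unique_and_deterministic():
    a = make_lexicon(300, seed=5)
    b = make_lexicon(300, seed=5)
    assert a == b
    assert len(set(a)) == 300


def test_truth_network_deterministic():
    gp = GroupParams("young", n_words=200, target_mean_degree=6, clustering_control=0.8)
    t1 = generate_truth_network(gp, seed=3)
    t2 = generate_truth_network(gp, seed=3)
    assert t1.nodes == t2.nodes
    assert t1.edge_weights() == t2.edge_weights()
    assert t1.meta["categories"] == t2.meta["categories"]


def test_truth_network_clustering_tracks_control():
    lattice = generate_truth_network(
        GroupParams("g", n_words=300, target_mean_degree=6, clustering_control=1.0), seed=1
    )
    rewired = generate_truth_network(
        GroupParams("g", n_words=300, target_mean_degree=6, clustering_control=0.3), seed=1
    )
    assert nx.average_clustering(lattice.graph) > nx.average_clustering(rewired.graph)


def test_truth_network_realized_degree_near_target():
    net = generate_truth_network(
        GroupParams("g", n_words=500, target_mean_degree=6, clustering_control=0.6), seed=2
    )
    mean_deg = 2 * net.n_edges / net.n_nodes
    assert abs(mean_deg - 6) / 6 < 0.10
    assert nx.is_connected(net.graph)


def test_truth_network_unsatisfiable_degree_rejected():
    with pytest.raises(ValueError, match="unsatisfiable"):
        generate_truth_network(
            GroupParams("g", n_words=50, target_mean_degree=60, clustering_control=0.5),
            seed=0,
        )


@pytest.fixture(scope="module")
def truth():
    return generate_truth_network(
        GroupParams(
            "old",
            n_words=400,
            target_mean_degree=6,
            clustering_control=0.5,
            n_categories=4,
            category_size=40,
        ),
        seed=9,
    )


def test_associations_deterministic_and_sized(truth):
    p = BehaviorParams()
    r1 = simulate_associations(truth, 100, 20, p, seed=4)
    r2 = simulate_associations(truth, 100, 20, p, seed=4)
    assert r1 == r2
    assert len(r1) == 120
    assert sum(len(r.responses) for r in r1) == expected_response_yield(100, 20)
    assert sum(r.is_repeat for r in r1) == 20
    # every repeat cue has a first encounter
    firsts = {r.cue for r in r1 if not r.is_repeat}
    assert all(r.cue in firsts for r in r1 if r.is_repeat)


def test_priority_cues_always_present(truth):
    animals = tuple(truth.meta["categories"][ANIMAL_CATEGORY])
    recs = simulate_associations(
        truth, 120, 0, BehaviorParams(), seed=5, priority_cues=animals
    )
    cues = {r.cue for r in recs}
    assert set(animals) <= cues


def test_repeat_fidelity_limits(truth):
    hi = simulate_associations(truth, 200, 60, BehaviorParams(repeat_fidelity=1.0), seed=6)
    assert repeated_cue_consistency(hi) == 1.0
    lo = simulate_associations(truth, 200, 60, BehaviorParams(repeat_fidelity=0.0), seed=6)
    assert repeated_cue_consistency(lo) < 0.05


def test_repeat_fidelity_recovered_at_study_scale():
    gp = GroupParams("old", n_words=3000, target_mean_degree=6, clustering_control=0.4)
    t = generate_truth_network(gp, seed=11)
    recs = simulate_associations(t, 3000, 600, BehaviorParams(repeat_fidelity=0.53), seed=12)
    assert repeated_cue_consistency(recs) == pytest.approx(0.53, abs=0.05)


def test_fluency_beta_infinity_orders_by_centrality(truth):
    cv = pagerank(truth, weighted=True)
    cands = sorted(truth.meta["categories"][ANIMAL_CATEGORY])
    params = BehaviorParams(beta_centrality=500.0, beta_similarity=0.0, fluency_length=10)
    seq = simulate_fluency(cv, None, cands, params, seed=1, participant_id="P", task="category", task_key="x")
    ranked = sorted(cands, key=lambda w: -cv[w])[:10]
    assert list(seq.items) == ranked


def test_fluency_deterministic(truth):
    cv = pagerank(truth, weighted=True)
    model = walk_similarity(truth)
    cands = sorted(truth.meta["categories"][ANIMAL_CATEGORY])
    p = BehaviorParams(fluency_length=8)
    s1 = simulate_fluency(cv, model, cands, p, seed=2, participant_id="P", task="category", task_key="x")
    s2 = simulate_fluency(cv, model, cands, p, seed=2, participant_id="P", task="category", task_key="x")
    assert s1 == s2


def test_episodic_limits(truth):
    cv = pagerank(truth, weighted=True)
    strong = BehaviorParams(beta_centrality=500.0, episodic_list_length=20, intrusion_rate=0.0)
    trial = simulate_episodic(truth, cv, strong, seed=3, participant_id="P")
    recalled_pr = [cv[w] for w in trial.recalled]
    missing_pr = [cv[w] for w in set(trial.studied) - set(trial.recalled)]
    if recalled_pr and missing_pr:
        assert min(recalled_pr) >= max(missing_pr)
    assert set(trial.recalled) <= set(trial.studied)  # intrusion rate 0


def test_paired_limits_and_determinism(truth):
    model = walk_similarity(truth)
    p = BehaviorParams(beta_similarity=500.0, n_pairs=30)
    t1 = simulate_paired(truth, model, p, seed=4, participant_id="P")
    t2 = simulate_paired(truth, model, p, seed=4, participant_id="P")
    assert t1 == t2
    cos = np.array([model.cosine(t.cue, t.target) for t in t1])
    rec = np.array([t.recalled for t in t1])
    if rec.any() and (~rec).any():
        assert cos[rec].mean() > cos[~rec].mean()


def test_cohort_deterministic_and_group_structured():
    cfg = small_cohort_config()
    c1 = simulate_cohort(cfg, seed=7, include_behavior=False)
    c2 = simulate_cohort(cfg, seed=7, include_behavior=False)
    assert [r for r in c1.records] == [r for r in c2.records]
    assert set(c1.participants["group"]) == {"young", "old"}
    assert len(c1.participants) == 2 * cfg.n_per_group
    # young truth nodes are a subset of the shared lexicon prefix
    assert c1.truths["young"].n_nodes < c1.truths["old"].n_nodes


def test_cohort_structure_recovery_single_seed():
    from semnet.stats import group_summary, macro_stats

    c = simulate_cohort(small_cohort_config(), seed=13, include_behavior=False)
    groups = dict(zip(c.participants["participant_id"], c.participants["group"]))
    pairs = [
        (macro_stats(build_individual_network(c.records_for(p))), groups[p])
        for p in sorted(groups)
    ]
    gs = {s.group: s for s in group_summary(pairs)}
    assert gs["old"].n_nodes > gs["young"].n_nodes
    assert gs["old"].mean_degree < gs["young"].mean_degree
    assert gs["old"].clustering < gs["young"].clustering
    assert gs["old"].path_length > gs["young"].path_length
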