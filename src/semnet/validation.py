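"""Self-validation experiments: parameter recovery on simulated cohorts.

These routines run the full analysis on cohorts generated by
:mod:`semnet.simulate` with known ground truth and measure how reliably
the pipeline recovers (a) the young/old structural ordering, (b) the four
behavioral couplings, and (c) the repeat-fidelity parameter. They back
both the test suite and ``scripts/acceptance.py``.

``REFERENCE_FULL_ROWS`` holds published per-participant full-network
macro statistics for an eight-adult free-association study (four young,
four old; columns: group, age, |V|, <k>, C, L). They serve as input data
for validating the group-summary computation against the published group
means (N_old = 5,921, N_young = 5,133, C_old = .053, C_young = .115).
"""

from __future__ import annotations

import tempfile

import numpy as np

from .behavior import (
    UndefinedEffectError,
    episodic_profile,
    fluency_retrieval_effect,
    paired_associate_effect,
)
from .build import build_individual_network
from .measures import pagerank, walk_similarity
from .pipeline import RunConfig, run_pipeline
from .reliability import repeated_cue_consistency
from .simulate import (
    ANIMAL_CATEGORY,
    BehaviorParams,
    CohortConfig,
    GroupParams,
    generate_truth_network,
    simulate_associations,
    simulate_cohort,
    simulate_episodic,
    simulate_fluency,
    simulate_paired,
    small_cohort_config,
)
from .stats import MacroStats, group_summary, macro_stats

REFERENCE_FULL_ROWS = [
    ("young", 24, 5780, 3.03, 0.091, 8.15),
    ("young", 27, 4836, 3.47, 0.115, 7.13),
    ("young", 27, 4920, 3.31, 0.119, 7.36),
    ("young", 28, 4995, 3.44, 0.136, 7.14),
    ("old", 68, 5275, 3.35, 0.059, 6.54),
    ("old", 68, 6461, 2.63, 0.045, 9.33),
    ("old", 69, 6157, 2.78, 0.053, 8.37),
    ("old", 70, 5792, 2.39, 0.055, 11.3),
]


def reference_group_means() -> dict[str, float]:
    """Group means of the reference rows, via the package's own summary op."""
    stats = [
        (MacroStats(n_nodes=v, mean_degree=k, clustering=c, path_length=l), grp)
        for grp, _age, v, k, c, l in REFERENCE_FULL_ROWS
    ]
    by_group = {s.group: s for s in group_summary(stats)}
    return {
        "mean_nodes_old": by_group["old"].n_nodes,
        "mean_nodes_young": by_group["young"].n_nodes,
        "mean_clustering_old": by_group["old"].clustering,
        "mean_clustering_young": by_group["young"].clustering,
        "max_nodes": max(v for _, _, v, *_ in REFERENCE_FULL_ROWS),
    }


def structure_recovery(n_cohorts: int = 100, seed: int = 0) -> float:
    """Fraction of desk-scale cohorts whose built networks show the old
    group with more nodes, lower clustering, and longer paths."""
    rng = np.random.SeedSequence(seed)
    hits = 0
    for child in rng.spawn(n_cohorts):
        s = int(child.generate_state(1)[0] % 2**31)
        cohort = simulate_cohort(CohortConfig(), seed=s, include_behavior=False)
        groups = dict(
            zip(cohort.participants["participant_id"], cohort.participants["group"])
        )
        pairs = [
            (macro_stats(build_individual_network(cohort.records_for(p))), groups[p])
            for p in sorted(groups)
        ]
        gs = {g.group: g for g in group_summary(pairs)}
        hits += int(
            gs["old"].n_nodes > gs["young"].n_nodes
            and gs["old"].clustering < gs["young"].clustering
            and gs["old"].path_length > gs["young"].path_length
        )
    return hits / n_cohorts


def behavior_recovery(n_cohorts: int = 13, seed: int = 0) -> dict[str, float]:
    """Per-effect fraction of simulated participants showing the encoded
    direction, with everything re-estimated from their built networks."""
    rng = np.random.SeedSequence(seed + 1)
    counts: dict[str, list[int]] = {
        "fluency_category_positive": [],
        "fluency_letter_positive": [],
        "lag1_gt_lag3": [],
        "episodic_retrieved_gt_missing": [],
        "paired_positive": [],
    }
    cfg = small_cohort_config()
    workdir = tempfile.mkdtemp(prefix="semnet_behavior_recovery_")
    for child in rng.spawn(n_cohorts):
        s = int(child.generate_state(1)[0] % 2**31)
        cohort = simulate_cohort(cfg, seed=s)
        res = run_pipeline(
            RunConfig(out_dir=workdir, seed=s, cohort=cfg), data=cohort
        )
        eff = res["effects"]
        ind = eff[eff.network_source == "individual"]
        for _pid, grp in ind.groupby("participant_id"):

            def val(task, stat):
                sel = grp[(grp.task == task) & (grp.statistic == stat)]["value"]
                return float(sel.iloc[0]) if len(sel) else float("nan")

            counts["fluency_category_positive"].append(
                int(val("fluency_category", "centrality_retrieved_minus_nonretrieved") > 0)
            )
            counts["fluency_letter_positive"].append(
                int(val("fluency_letter", "centrality_retrieved_minus_nonretrieved") > 0)
            )
            counts["lag1_gt_lag3"].append(
                int(
                    val("fluency_category", "lag1_cosine")
                    > val("fluency_category", "lag3_cosine")
                )
            )
            counts["episodic_retrieved_gt_missing"].append(
                int(val("episodic", "centrality_retrieved_minus_missing") > 0)
            )
            counts["paired_positive"].append(
                int(val("paired_associates", "cosine_recalled_minus_unrecalled") > 0)
            )
    return {k: float(np.mean(v)) for k, v in counts.items()}


def null_calibration(n_reps: int = 200, seed: int = 0) -> dict[str, tuple[float, float]]:
    """Monte-Carlo mean and SE of each effect when both couplings are zero.

    One participant's network is built once (association sampling does not
    depend on the couplings); behavior is then re-simulated ``n_reps``
    times with zero slopes and each effect is measured under the built
    network's own measures.
    """
    rng = np.random.SeedSequence(seed + 2)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in rng.spawn(n_reps + 2)]
    gp = GroupParams(
        "old",
        n_words=600,
        target_mean_degree=6,
        clustering_control=0.4,
        n_categories=4,
        category_size=50,
    )
    null = BehaviorParams(
        beta_centrality=0.0,
        beta_similarity=0.0,
        fluency_length=14,
        episodic_list_length=15,
        n_pairs=40,
        noise_rate=0.02,
    )
    truth = generate_truth_network(gp, seed=seeds[0])
    truth_cent = pagerank(truth, weighted=True)
    truth_model = walk_similarity(truth)
    records = simulate_associations(
        truth,
        315,
        63,
        null,
        seed=seeds[1],
        priority_cues=tuple(truth.meta["categories"][ANIMAL_CATEGORY]),
    )
    net = build_individual_network(records)
    cent = pagerank(net, weighted=True)
    model = walk_similarity(net)
    cands = set(truth.meta["categories"][ANIMAL_CATEGORY]) & net.nodes
    vals: dict[str, list[float]] = {"fluency": [], "episodic": [], "paired": []}
    for i, s in enumerate(seeds[2:]):
        seq = simulate_fluency(
            truth_cent, truth_model, sorted(cands), null, seed=s,
            participant_id="null", task="category", task_key=ANIMAL_CATEGORY,
        )
        try:
            vals["fluency"].append(fluency_retrieval_effect(cent, seq, cands).value)
        except UndefinedEffectError:
            pass
        trial = simulate_episodic(truth, truth_cent, null, seed=s + 1, participant_id="null")
        prof = episodic_profile(cent, None, trial)
        r, m = prof.centrality["retrieved"], prof.centrality["missing"]
        if not (np.isnan(r) or np.isnan(m)):
            vals["episodic"].append(r - m)
        trials = simulate_paired(truth, truth_model, null, seed=s + 2, participant_id="null")
        try:
            vals["paired"].append(paired_associate_effect(model, trials).value)
        except UndefinedEffectError:
            pass
    out = {}
    for k, v in vals.items():
        arr = np.asarray(v)
        out[k] = (float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr))))
    return out


def consistency_recovery(q: float = 0.53, seed: int = 0) -> float:
    """Repeat consistency estimated from a study-scale participant
    (3,000 unique + 600 repeated cues) simulated with fidelity ``q``."""
    rng = np.random.SeedSequence(seed + 3)
    s1, s2 = (int(c.generate_state(1)[0] % 2**31) for c in rng.spawn(2))
    gp = GroupParams("old", n_words=3000, target_mean_degree=6, clustering_control=0.4)
    truth = generate_truth_network(gp, seed=s1)
    records = simulate_associations(
        truth, 3000, 600, BehaviorParams(repeat_fidelity=q), seed=s2
    )
    return repeated_cue_consistency(records)
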