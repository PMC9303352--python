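"""End-to-end orchestration: data in (simulated or loaded), four result
tables out.

Stages: obtain data -> build networks (individual, aggregate, common) ->
macroscopic statistics and group summaries -> node measures -> behavioral
linkage under individual and aggregate networks -> reliability. Outputs
are ``table2.csv`` (macro statistics), ``effects.csv`` (all node-level
behavioral statistics), ``reliability.csv`` and ``provenance.json``.
Identical config and seed give byte-identical CSV contents.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    BehavioralEffect,
    UndefinedEffectError,
    compare_individual_vs_aggregate,
    episodic_profile,
    fluency_lag_similarity,
    fluency_retrieval_effect,
    letter_candidates,
    paired_associate_effect,
)
from .build import (
    build_aggregate_network,
    build_individual_network,
    common_subnetworks,
)
from .io import (
    load_associations,
    load_behavior,
    load_participants,
)
from .measures import pagerank, walk_similarity
from .reliability import (
    correlation_summary,
    cosine_triangle_vectors,
    cross_network_measure_correlation,
    reliability_report,
    repeat_association_profile,
)
from .simulate import ANIMAL_CATEGORY, CohortConfig, CohortData, simulate_cohort
from .stats import group_summary, macro_stats


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """One config object controlling a full run.

    Either ``data_dir`` points at the documented CSV layout, or (default)
    a cohort is simulated from ``cohort`` with the run's seed.
    """

    out_dir: str | Path = "results"
    seed: int = 0
    data_dir: str | Path | None = None  # None -> simulate
    cohort: CohortConfig = field(default_factory=CohortConfig)
    include_repeats: bool = True
    damping: float = 0.85
    alpha: float = 0.75
    use_ppmi: bool = True
    letter_rule: str = "task_letter"  # or "own_initial"
    consistency_direction: str = "second_vs_first"
    max_cosine_pairs: int = 20_000
    category_lists: dict[str, list[str]] | None = None  # task_key -> word list


def _letter_candidate_set(nodes, seq, rule: str) -> set[str]:
    if rule == "task_letter":
        return letter_candidates(nodes, seq.task_key)
    if rule == "own_initial":
        initials = {w[:1] for w in seq.items}
        return {w for w in nodes if w[:1] in initials}
    raise ValueError(f"unknown letter rule {rule!r}")


def _effect_row(e: BehavioralEffect) -> dict:
    return dataclasses.asdict(e)


def _mean_ignore_nan(values) -> float:
    vals = [v for v in values if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def run_pipeline(config: RunConfig, data: CohortData | None = None) -> dict[str, pd.DataFrame]:
    """Execute all stages and write the results bundle to ``config.out_dir``.

    ``data`` may carry a pre-simulated cohort (to avoid regenerating);
    otherwise data is loaded from ``config.data_dir`` or simulated.
    Returns the result tables keyed by output file stem.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ----- stage: data -----------------------------------------------------
    try:
        if data is not None:
            cohort = data
            participants = cohort.participants
            records, sequences = cohort.records, cohort.fluency
            episodic, paired = cohort.episodic, cohort.paired
            category_lists = config.category_lists or {
                ANIMAL_CATEGORY: sorted(
                    set().union(
                        *(
                            net.meta["categories"][ANIMAL_CATEGORY]
                            for net in cohort.truths.values()
                        )
                    )
                )
            }
        elif config.data_dir is None:
            cohort = simulate_cohort(config.cohort, seed=config.seed)
            return run_pipeline(config, data=cohort)
        else:
            d = Path(config.data_dir)
            records = load_associations(d / "associations.csv")
            sequences, episodic, paired = load_behavior(
                d / "fluency.csv", d / "episodic.csv", d / "paired.csv"
            )
            participants = load_participants(d / "participants.csv")
            category_lists = config.category_lists or {}
            cat_file = d / "categories.json"
            if not category_lists and cat_file.exists():
                with cat_file.open(encoding="utf-8") as fh:
                    per_group = json.load(fh)
                merged: dict[str, set[str]] = {}
                for cats in per_group.values():
                    for name, words in cats.items():
                        merged.setdefault(name, set()).update(words)
                category_lists = {k: sorted(v) for k, v in merged.items()}
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("data", exc) from exc

    group_of = dict(zip(participants["participant_id"], participants["group"]))
    age_of = dict(zip(participants["participant_id"], participants["age"]))
    pids = sorted(group_of)

    # ----- stage: build ----------------------------------------------------
    try:
        nets = {
            pid: build_individual_network(
                [r for r in records if r.participant_id == pid],
                include_repeats=config.include_repeats,
                group=group_of[pid],
            )
            for pid in pids
        }
        aggregate = build_aggregate_network(records, include_repeats=config.include_repeats)
        common = dict(zip(pids, common_subnetworks([nets[p] for p in pids])))
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("build", exc) from exc

    # ----- stage: stats ----------------------------------------------------
    try:
        full_stats = {pid: macro_stats(nets[pid]) for pid in pids}
        common_stats = {pid: macro_stats(common[pid]) for pid in pids}
        rows = []
        for pid in pids:
            f, c = full_stats[pid], common_stats[pid]
            rows.append(
                {
                    "participant_id": pid,
                    "group": group_of[pid],
                    "age": age_of[pid],
                    "full_n_nodes": f.n_nodes,
                    "full_mean_degree": f.mean_degree,
                    "full_clustering": f.clustering,
                    "full_path_length": f.path_length,
                    "common_n_nodes": c.n_nodes,
                    "common_mean_degree": c.mean_degree,
                    "common_clustering": c.clustering,
                    "common_path_length": c.path_length,
                }
            )
        groups = sorted(set(group_of.values()))
        for summ_kind, stat_map in (("full", full_stats), ("common", common_stats)):
            for gs in group_summary(
                [(stat_map[p], group_of[p]) for p in pids], groups=groups
            ):
                rows.append(
                    {
                        "participant_id": f"mean:{gs.group}",
                        "group": gs.group,
                        "age": "",
                        f"{summ_kind}_n_nodes": gs.n_nodes,
                        f"{summ_kind}_mean_degree": gs.mean_degree,
                        f"{summ_kind}_clustering": gs.clustering,
                        f"{summ_kind}_path_length": gs.path_length,
                    }
                )
        table2 = pd.DataFrame(rows)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("stats", exc) from exc

    # ----- stage: measures -------------------------------------------------
    try:
        cent = {pid: pagerank(nets[pid], damping=config.damping, weighted=True) for pid in pids}
        cent["aggregate"] = pagerank(aggregate, damping=config.damping, weighted=True)
        sims = {
            pid: walk_similarity(nets[pid], alpha=config.alpha, use_ppmi=config.use_ppmi)
            for pid in pids
        }
        sims["aggregate"] = walk_similarity(
            aggregate, alpha=config.alpha, use_ppmi=config.use_ppmi
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("measures", exc) from exc

    # ----- stage: link -----------------------------------------------------
    try:
        effect_rows: list[dict] = []
        comparable: dict[str, list[BehavioralEffect]] = {"individual": [], "aggregate": []}
        for source in ("individual", "aggregate"):
            for pid in pids:
                key = pid if source == "individual" else "aggregate"
                net_nodes = (nets[pid] if source == "individual" else aggregate).nodes
                c_vec, s_mod = cent[key], sims[key]
                for seq in [s for s in sequences if s.participant_id == pid]:
                    if seq.task == "category":
                        cands = set(category_lists.get(seq.task_key, ())) & net_nodes
                    else:
                        cands = _letter_candidate_set(net_nodes, seq, config.letter_rule)
                    try:
                        eff = fluency_retrieval_effect(c_vec, seq, cands, network_source=source)
                        effect_rows.append(_effect_row(eff))
                        comparable[source].append(eff)
                    except UndefinedEffectError:
                        pass
                    lags = fluency_lag_similarity(s_mod, seq, max_lag=3)
                    for lag, val in lags.items():
                        effect_rows.append(
                            {
                                "participant_id": pid,
                                "task": f"fluency_{seq.task}",
                                "network_source": source,
                                "statistic": f"lag{lag}_cosine",
                                "value": float("nan") if val is None else val,
                                "n_retrieved": len(seq.items),
                                "n_comparison": 0,
                                "n_dropped": 0,
                            }
                        )
                trials = [t for t in episodic if t.participant_id == pid]
                profs = [
                    episodic_profile(c_vec, s_mod, t, network_source=source) for t in trials
                ]
                if profs:
                    for status in ("retrieved", "missing", "intrusion"):
                        c_mean = _mean_ignore_nan(p.centrality[status] for p in profs)
                        effect_rows.append(
                            {
                                "participant_id": pid,
                                "task": "episodic",
                                "network_source": source,
                                "statistic": f"centrality_{status}",
                                "value": c_mean,
                                "n_retrieved": sum(p.n_retrieved for p in profs),
                                "n_comparison": sum(p.n_missing for p in profs),
                                "n_dropped": sum(p.n_dropped for p in profs),
                            }
                        )
                        s_mean = _mean_ignore_nan(
                            p.similarity_to_retrieved[status]
                            for p in profs
                            if p.similarity_to_retrieved is not None
                        )
                        effect_rows.append(
                            {
                                "participant_id": pid,
                                "task": "episodic",
                                "network_source": source,
                                "statistic": f"cosine_to_retrieved_{status}",
                                "value": s_mean,
                                "n_retrieved": sum(p.n_retrieved for p in profs),
                                "n_comparison": sum(p.n_missing for p in profs),
                                "n_dropped": sum(p.n_dropped for p in profs),
                            }
                        )
                    ret = _mean_ignore_nan(p.centrality["retrieved"] for p in profs)
                    mis = _mean_ignore_nan(p.centrality["missing"] for p in profs)
                    eff = BehavioralEffect(
                        participant_id=pid,
                        task="episodic",
                        network_source=source,
                        statistic="centrality_retrieved_minus_missing",
                        value=ret - mis,
                        n_retrieved=sum(p.n_retrieved for p in profs),
                        n_comparison=sum(p.n_missing for p in profs),
                        n_dropped=sum(p.n_dropped for p in profs),
                    )
                    effect_rows.append(_effect_row(eff))
                    comparable[source].append(eff)
                p_trials = [t for t in paired if t.participant_id == pid]
                if p_trials:
                    try:
                        eff = paired_associate_effect(s_mod, p_trials, network_source=source)
                        effect_rows.append(_effect_row(eff))
                        comparable[source].append(eff)
                    except UndefinedEffectError:
                        pass
        effects = pd.DataFrame(effect_rows)
        try:
            comparison = compare_individual_vs_aggregate(
                comparable["individual"], comparable["aggregate"]
            )
        except ValueError:
            comparison = pd.DataFrame(
                columns=["task", "individual", "aggregate", "difference"]
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("link", exc) from exc

    # ----- stage: reliability ----------------------------------------------
    try:
        rel_rows = []
        for pid in pids:
            rep = reliability_report([r for r in records if r.participant_id == pid])
            for stat in ("repeat_consistency", "pct_pairs_repeated", "max_pair_count"):
                rel_rows.append(
                    {
                        "participant_id": pid,
                        "statistic": stat,
                        "value": float(getattr(rep, stat)),
                    }
                )
        agg_pct, agg_max = repeat_association_profile(records)
        rel_rows.append(
            {"participant_id": "aggregate", "statistic": "pct_pairs_repeated", "value": agg_pct}
        )
        rel_rows.append(
            {
                "participant_id": "aggregate",
                "statistic": "max_pair_count",
                "value": float(agg_max),
            }
        )
        shared = sorted(set.intersection(*(nets[p].nodes for p in pids)) & aggregate.nodes)
        if len(shared) >= 3:
            pr_vectors = {pid: cent[pid].as_dict() for pid in pids}
            pr_vectors["aggregate"] = cent["aggregate"].as_dict()
            pr_corr = cross_network_measure_correlation(pr_vectors, shared)
            for name, val in correlation_summary(pr_corr).items():
                rel_rows.append(
                    {"participant_id": "cohort", "statistic": f"pagerank_{name}", "value": val}
                )
            cos_vecs, _se = cosine_triangle_vectors(
                {k: sims[k] for k in [*pids, "aggregate"]},
                shared,
                max_pairs=config.max_cosine_pairs,
                seed=config.seed,
            )
            cos_corr = cross_network_measure_correlation(
                cos_vecs, sorted(next(iter(cos_vecs.values())))
            )
            for name, val in correlation_summary(cos_corr).items():
                rel_rows.append(
                    {"participant_id": "cohort", "statistic": f"cosine_{name}", "value": val}
                )
        reliability = pd.DataFrame(rel_rows)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("reliability", exc) from exc

    # ----- stage: write ----------------------------------------------------
    try:
        table2.to_csv(out_dir / "table2.csv", index=False)
        effects.to_csv(out_dir / "effects.csv", index=False)
        reliability.to_csv(out_dir / "reliability.csv", index=False)
        comparison.to_csv(out_dir / "individual_vs_aggregate.csv", index=False)
        provenance = {
            "semnet_version": __version__,
            "seed": config.seed,
            "config": json.loads(
                json.dumps(
                    dataclasses.asdict(config),
                    default=lambda o: str(o),
                )
            ),
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
        }
        with (out_dir / "provenance.json").open("w", encoding="utf-8") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("write", exc) from exc

    return {
        "table2": table2,
        "effects": effects,
        "reliability": reliability,
        "individual_vs_aggregate": comparison,
    }
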