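"""Link node-level network measures to cognitive-task performance.

Four analyses, each producing a signed per-participant statistic:

* verbal fluency — mean scaled-PageRank difference between retrieved and
  non-retrieved candidate words (candidates: a category word list, or all
  network words sharing the task letter);
* fluency lag similarity — mean walk-similarity cosine of retrieval pairs
  one, two, ... lags apart;
* episodic recall — mean centrality and mean cosine-to-retrieved of
  retrieved, missing, and intrusion words;
* paired associates — mean cue-target cosine of recalled minus
  unrecalled pairs.

Each statistic can be computed under a participant's own network or under
an aggregate network (same code path; only the measures differ), enabling
the individual-versus-aggregate comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import EpisodicTrial, FluencySequence, PairedAssociateTrial
from .measures import CentralityVector, SimilarityModel


class UndefinedEffectError(ValueError):
    """One of the comparison sets needed for an effect is empty."""


@dataclass(frozen=True)
class BehavioralEffect:
    participant_id: str
    task: str
    network_source: str  # "individual" or "aggregate"
    statistic: str
    value: float
    n_retrieved: int
    n_comparison: int
    n_dropped: int = 0  # behavioral items absent from the network


@dataclass(frozen=True)
class RecallStatusProfile:
    """Per-status episodic summary. Similarity fields are None when no
    retrieved word is in the network."""

    participant_id: str
    network_source: str
    n_retrieved: int
    n_missing: int
    n_intrusion: int
    n_dropped: int
    centrality: Mapping[str, float]  # status -> mean scaled PageRank
    similarity_to_retrieved: Mapping[str, float] | None  # status -> mean cosine


def letter_candidates(nodes: Iterable[str], letter: str) -> set[str]:
    """All network words whose first character is the task letter."""
    letter = letter.lower()
    return {w for w in nodes if w[:1] == letter}


def fluency_retrieval_effect(
    centrality: CentralityVector,
    seq: FluencySequence,
    candidates: set[str],
    network_source: str = "individual",
) -> BehavioralEffect:
    """Mean scaled PageRank of retrieved candidates minus non-retrieved ones."""
    in_net = [w for w in seq.items if w in centrality]
    dropped = len(seq.items) - len(in_net)
    retrieved = [w for w in in_net if w in candidates]
    comparison = sorted(candidates - set(retrieved))
    if not retrieved:
        raise UndefinedEffectError("no retrieved words among network candidates")
    if not comparison:
        raise UndefinedEffectError("every candidate was retrieved; no comparison set")
    value = float(
        np.mean([centrality[w] for w in retrieved]) - np.mean([centrality[w] for w in comparison])
    )
    return BehavioralEffect(
        participant_id=seq.participant_id,
        task=f"fluency_{seq.task}",
        network_source=network_source,
        statistic="centrality_retrieved_minus_nonretrieved",
        value=value,
        n_retrieved=len(retrieved),
        n_comparison=len(comparison),
        n_dropped=dropped,
    )


def fluency_lag_similarity(
    model: SimilarityModel, seq: FluencySequence, max_lag: int = 3
) -> dict[int, float | None]:
    """Mean cosine over ordered retrieval pairs ``lag`` positions apart.

    Pairs are indexed on the original sequence; a pair enters lag L iff
    both endpoints are in the network (the sequence is not re-spliced
    around out-of-network items). Lags with no valid pair map to None.
    """
    items = seq.items
    out: dict[int, float | None] = {}
    for lag in range(1, max_lag + 1):
        vals = [
            model.cosine(items[i], items[i + lag])
            for i in range(len(items) - lag)
            if items[i] in model and items[i + lag] in model
        ]
        out[lag] = float(np.mean(vals)) if vals else None
    return out


def episodic_profile(
    centrality: CentralityVector,
    model: SimilarityModel | None,
    trial: EpisodicTrial,
    network_source: str = "individual",
) -> RecallStatusProfile:
    """Mean centrality and cosine-to-retrieved for retrieved / missing /
    intrusion words of one episodic trial.

    Statuses partition the in-network words of studied + recalled:
    retrieved = studied and recalled, missing = studied only, intrusion =
    recalled only. The cosine of a retrieved word is to the *other*
    retrieved words. Words absent from the network are dropped and counted.
    """
    studied, recalled = set(trial.studied), set(trial.recalled)
    in_net = lambda ws: sorted(w for w in ws if w in centrality)
    retrieved = in_net(studied & recalled)
    missing = in_net(studied - recalled)
    intrusion = in_net(recalled - studied)
    dropped = len(studied | recalled) - len(retrieved) - len(missing) - len(intrusion)
    if not retrieved and not missing:
        raise ValueError("no studied word present in the network")
    groups = {"retrieved": retrieved, "missing": missing, "intrusion": intrusion}
    cent = {
        status: float(np.mean([centrality[w] for w in ws])) if ws else float("nan")
        for status, ws in groups.items()
    }
    sim: dict[str, float] | None = None
    if retrieved and model is not None:
        sim = {}
        for status, ws in groups.items():
            vals = []
            for w in ws:
                others = [r for r in retrieved if r != w] if status == "retrieved" else retrieved
                if others and w in model:
                    vals.append(float(np.mean([model.cosine(w, r) for r in others])))
            sim[status] = float(np.mean(vals)) if vals else float("nan")
    return RecallStatusProfile(
        participant_id=trial.participant_id,
        network_source=network_source,
        n_retrieved=len(retrieved),
        n_missing=len(missing),
        n_intrusion=len(intrusion),
        n_dropped=dropped,
        centrality=cent,
        similarity_to_retrieved=sim,
    )


def paired_associate_effect(
    model: SimilarityModel,
    trials: Sequence[PairedAssociateTrial],
    network_source: str = "individual",
) -> BehavioralEffect:
    """Mean cue-target cosine of recalled pairs minus unrecalled pairs."""
    trials = list(trials)
    if not trials:
        raise UndefinedEffectError("no trials")
    pid = trials[0].participant_id
    usable = [t for t in trials if t.cue in model and t.target in model]
    dropped = len(trials) - len(usable)
    hit = [model.cosine(t.cue, t.target) for t in usable if t.recalled]
    miss = [model.cosine(t.cue, t.target) for t in usable if not t.recalled]
    if not hit or not miss:
        raise UndefinedEffectError("need at least one recalled and one unrecalled in-network pair")
    return BehavioralEffect(
        participant_id=pid,
        task="paired_associates",
        network_source=network_source,
        statistic="cosine_recalled_minus_unrecalled",
        value=float(np.mean(hit) - np.mean(miss)),
        n_retrieved=len(hit),
        n_comparison=len(miss),
        n_dropped=dropped,
    )


def compare_individual_vs_aggregate(
    effects_ind: Sequence[BehavioralEffect],
    effects_agg: Sequence[BehavioralEffect],
) -> pd.DataFrame:
    """Per-task means of the same effect under individual vs aggregate networks.

    Both inputs must cover the same (participant, task) cells. Returns a
    table with the two means and their difference (aggregate - individual);
    no significance test is attached.
    """

    def frame(effects, label):
        return pd.DataFrame(
            {
                "task": [e.task for e in effects],
                "participant_id": [e.participant_id for e in effects],
                label: [e.value for e in effects],
            }
        )

    a, b = frame(effects_ind, "individual"), frame(effects_agg, "aggregate")
    for task in set(a["task"]) | set(b["task"]):
        pa = set(a.loc[a["task"] == task, "participant_id"])
        pb = set(b.loc[b["task"] == task, "participant_id"])
        if pa != pb:
            raise ValueError(f"participant sets differ for task {task!r}: {pa ^ pb}")
    merged = a.merge(b, on=["task", "participant_id"])
    out = merged.groupby("task", as_index=False)[["individual", "aggregate"]].mean()
    out["difference"] = out["aggregate"] - out["individual"]
    return out
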