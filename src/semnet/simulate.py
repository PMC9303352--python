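"""Synthetic cohorts: ground-truth lexical networks, free-association
records, and task behavior with known generating structure.

The generator exists so the full analysis pipeline can be exercised and
validated end to end with known ground truth. It emulates a two-group
(young / old adults) free-association study design:

* a group-level ground-truth network per age group, drawn from a
  Watts-Strogatz small-world family over a shared pseudo-word lexicon.
  The old group's network is larger, sparser, and less clustered — the
  age contrast the analysis is meant to detect;
* per-participant association records: each cue encounter samples three
  responses from the cue's truth neighborhood proportional to edge weight,
  with a small uniform-lexicon noise rate that makes individual networks
  diverge; repeated cues get a second encounter whose responses copy a
  first-encounter response with probability ``repeat_fidelity`` and are
  otherwise resampled from the rest of the neighborhood, so that
  ``repeat_fidelity`` is exactly the expected repeat consistency;
* task behavior coupled to the truth network's node measures: retrieval
  log-odds increase with scaled PageRank (fluency, episodic recall) and
  with walk-similarity cosine (fluency transitions, paired associates).

All generators are deterministic given (parameters, seed); randomness
flows from one root seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .behavior import letter_candidates
from .build import SemanticNetwork
from .io import (
    AssociationRecord,
    EpisodicTrial,
    FluencySequence,
    PairedAssociateTrial,
)
from .measures import CentralityVector, SimilarityModel, pagerank, walk_similarity

ANIMAL_CATEGORY = "animals"


@dataclass(frozen=True)
class GroupParams:
    """Ground-truth network family parameters for one age group."""

    label: str
    n_words: int = 2000
    target_mean_degree: float = 6.0
    clustering_control: float = 0.7  # 1 = lattice-like (max clustering), 0 = fully rewired
    n_categories: int = 8
    category_size: int = 40
    max_edge_weight: int = 50
    salience_sigma: float = 0.9  # sd of log node salience; 0 = homogeneous strengths

    def __post_init__(self):
        if self.n_words < 50:
            raise ValueError("n_words must be >= 50")
        if self.target_mean_degree < 2:
            raise ValueError("target_mean_degree must be >= 2")
        if not 0.0 <= self.clustering_control <= 1.0:
            raise ValueError("clustering_control must be in [0, 1]")


@dataclass(frozen=True)
class BehaviorParams:
    """Couplings between truth-network node measures and task behavior.

    Slopes are on the scale of their predictors: scaled PageRank has mean 1
    and sd roughly 0.6-1.3 in this graph family, walk-similarity cosines
    range over roughly 0-0.4, so the defaults make the systematic signal a
    few logits wide. Intercepts left at None are centred at runtime so
    baseline retrieval probability is about one half.
    """

    beta_centrality: float = 4.0
    beta_similarity: float = 8.0
    fluency_length: int = 20
    episodic_list_length: int = 15
    episodic_n_lists: int = 4
    n_pairs: int = 40
    repeat_fidelity: float = 0.53  # q: P(repeat response copies a first-encounter response)
    noise_rate: float = 0.05  # P(response drawn uniformly from lexicon instead of neighbors)
    intrusion_rate: float = 0.1
    episodic_intercept: float | None = None
    paired_intercept: float | None = None

    def __post_init__(self):
        if self.fluency_length < 4:
            raise ValueError("fluency_length must be >= 4")
        if not 0.0 <= self.repeat_fidelity <= 1.0:
            raise ValueError("repeat_fidelity must be in [0, 1]")


def default_group_params() -> dict[str, GroupParams]:
    """Desk-scale group contrast: the old group's truth network has more
    words, lower degree, and less clustering than the young group's."""
    return {
        "young": GroupParams(
            label="young", n_words=1200, target_mean_degree=10, clustering_control=0.85
        ),
        "old": GroupParams(
            label="old", n_words=2000, target_mean_degree=6, clustering_control=0.4
        ),
    }


def small_group_params() -> dict[str, GroupParams]:
    """Reduced-scale variant of the same contrast for fast Monte-Carlo work."""
    return {
        "young": GroupParams(
            label="young",
            n_words=350,
            target_mean_degree=10,
            clustering_control=0.85,
            n_categories=4,
            category_size=50,
        ),
        "old": GroupParams(
            label="old",
            n_words=600,
            target_mean_degree=6,
            clustering_control=0.4,
            n_categories=4,
            category_size=50,
        ),
    }


def expected_response_yield(n_unique: int, n_repeat: int, responses_per_cue: int = 3) -> int:
    """Closed-form expected number of responses a participant produces."""
    return responses_per_cue * (n_unique + n_repeat)


def make_lexicon(n: int, seed: int, alphabet: str = string.ascii_lowercase) -> list[str]:
    """Deterministic list of ``n`` unique 6-letter pseudo-words.

    A restricted ``alphabet`` concentrates initial letters so letter-cued
    candidate sets stay usefully large relative to the lexicon.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < n:
        batch = ["".join(row) for row in letters[rng.integers(0, len(letters), size=(n, 6))]]
        for w in batch:
            if w not in seen:
                seen.add(w)
                words.append(w)
                if len(words) == n:
                    break
    return words


def _salience_rewired_ring(
    n: int, k: int, p_rewire: float, salience: np.ndarray, rng: np.random.Generator
) -> nx.Graph:
    """Ring lattice with salience-biased rewiring.

    Like Watts-Strogatz rewiring, each lattice edge is redirected with
    probability ``p_rewire``; the new endpoint, however, is drawn
    proportional to node salience rather than uniformly. Rewiring thus
    simultaneously destroys local clustering and concentrates edges on
    salient words, giving the heavy-tailed degree distribution real
    lexical networks show. Retries until connected.
    """
    probs = salience / salience.sum()
    for _ in range(200):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for step in range(1, k // 2 + 1):
            for u in range(n):
                v = (u + step) % n
                if rng.random() < p_rewire:
                    for _ in range(50):
                        w = int(rng.choice(n, p=probs))
                        if w != u and not g.has_edge(u, w):
                            v = w
                            break
                if u != v and not g.has_edge(u, v):
                    g.add_edge(u, v)
        if nx.is_connected(g):
            return g
    raise RuntimeError("could not draw a connected rewired ring in 200 tries")


def generate_truth_network(
    params: GroupParams, seed: int, lexicon: list[str] | None = None
) -> SemanticNetwork:
    """Connected ring-rewired ground-truth network with integer edge
    weights, heavy-tailed word salience, and category labels on contiguous
    ring blocks.

    Rewiring probability is 1 - clustering_control, so lowering the control
    lowers realized clustering. Rewired edges attach preferentially to
    salient words (see :func:`_salience_rewired_ring`), and edge weights
    scale with the product of endpoint saliences — both emulate the
    frequency bias of real association norms, and together they give the
    network the centrality variation that the behavioral couplings act on.
    """
    rng = np.random.default_rng(seed)
    n = params.n_words
    k = 2 * int(round(params.target_mean_degree / 2))
    if k < 2 or k >= n:
        raise ValueError(f"unsatisfiable degree {params.target_mean_degree} for n={n}")
    p_rewire = 1.0 - params.clustering_control
    salience_arr = rng.lognormal(0.0, params.salience_sigma, n)
    g = _salience_rewired_ring(n, k, p_rewire, salience_arr, rng)
    if lexicon is None:
        lexicon = make_lexicon(n, seed=int(rng.integers(2**31)))
    if len(lexicon) < n:
        raise ValueError("lexicon smaller than n_words")
    mapping = {i: lexicon[i] for i in range(n)}
    g = nx.relabel_nodes(g, mapping)
    salience = {lexicon[i]: s for i, s in enumerate(salience_arr)}
    for u, v, d in g.edges(data=True):
        d["weight"] = int(
            min(max(1, round(salience[u] * salience[v])), params.max_edge_weight)
        )
    stride = n // params.n_categories
    categories: dict[str, list[str]] = {}
    for c in range(params.n_categories):
        name = ANIMAL_CATEGORY if c == 0 else f"cat{c}"
        start = c * stride
        categories[name] = [lexicon[(start + i) % n] for i in range(params.category_size)]
    return SemanticNetwork(
        graph=g,
        owner=f"truth:{params.label}",
        group=params.label,
        meta={"categories": categories, "params": dataclasses.asdict(params), "seed": seed},
    )


def _weighted_sample_without_replacement(
    rng: np.random.Generator, items: np.ndarray, weights: np.ndarray, k: int
) -> list:
    """Gumbel-top-k trick: k draws without replacement proportional to weight."""
    if len(items) == 0 or k <= 0:
        return []
    k = min(k, len(items))
    keys = np.log(weights) + rng.gumbel(size=len(items))
    return list(items[np.argsort(-keys)[:k]])


def simulate_associations(
    truth: SemanticNetwork,
    n_unique_cues: int,
    n_repeat_cues: int,
    params: BehaviorParams,
    seed: int,
    participant_id: str = "P00",
    priority_cues: tuple[str, ...] = (),
) -> list[AssociationRecord]:
    """Sample one participant's free-association records from a truth network.

    Each encounter draws three responses without replacement from the cue's
    neighborhood proportional to edge weight; with probability
    ``noise_rate`` a slot is instead a uniform lexicon word. Repeat
    encounters copy a first-encounter response with probability
    ``repeat_fidelity`` and otherwise resample from the neighborhood
    *excluding* the first-encounter responses, so downstream repeat
    consistency estimates the fidelity parameter directly.

    ``priority_cues`` are always part of the cue list (the remainder is a
    uniform sample), mirroring how fixed cue lists deliberately cover
    task-relevant words such as category exemplars.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(truth.graph.nodes)
    if n_unique_cues > len(nodes):
        raise ValueError("more unique cues than truth words")
    if n_repeat_cues > n_unique_cues:
        raise ValueError("more repeat cues than unique cues")
    lexicon = np.array(nodes)
    nbrs = {
        v: (
            np.array(sorted(truth.graph[v])),
            np.array([truth.graph[v][u]["weight"] for u in sorted(truth.graph[v])], float),
        )
        for v in nodes
    }
    fixed = [w for w in dict.fromkeys(priority_cues) if w in truth.graph]
    if len(fixed) > n_unique_cues:
        raise ValueError("more priority cues than unique-cue slots")
    remaining = np.array([w for w in nodes if w not in set(fixed)])
    cues = fixed + list(
        rng.choice(remaining, size=n_unique_cues - len(fixed), replace=False)
    )
    cues = [cues[i] for i in rng.permutation(len(cues))]

    def noise_word(cue: str, taken: set[str]) -> str:
        while True:
            w = str(lexicon[rng.integers(len(lexicon))])
            if w != cue and w not in taken:
                return w

    def draw_responses(cue: str, exclude: set[str]) -> list[str]:
        neigh, wts = nbrs[cue]
        if exclude:
            keep = ~np.isin(neigh, list(exclude))
            neigh, wts = neigh[keep], wts[keep]
        n_noise = int(rng.binomial(3, params.noise_rate))
        picks = _weighted_sample_without_replacement(rng, neigh, wts, 3 - n_noise)
        taken = set(picks) | exclude
        for _ in range(3 - len(picks)):
            w = noise_word(cue, taken)
            picks.append(w)
            taken.add(w)
        order = rng.permutation(len(picks))
        return [str(picks[i]) for i in order]

    records: list[AssociationRecord] = []
    first_responses: dict[str, list[str]] = {}
    for i, cue in enumerate(cues, start=1):
        resp = draw_responses(str(cue), exclude=set())
        first_responses[str(cue)] = resp
        records.append(
            AssociationRecord(
                participant_id=participant_id,
                encounter_index=i,
                cue=str(cue),
                responses=tuple(resp),
                is_repeat=False,
            )
        )
    repeat_cues = list(rng.choice(np.array(cues), size=n_repeat_cues, replace=False))
    for j, cue in enumerate(repeat_cues, start=n_unique_cues + 1):
        cue = str(cue)
        first = first_responses[cue]
        resp2: list[str] = []
        for _ in range(3):
            available = [w for w in first if w not in resp2]
            if available and rng.random() < params.repeat_fidelity:
                resp2.append(str(available[int(rng.integers(len(available)))]))
                continue
            neigh, wts = nbrs[cue]
            exclude = set(first) | set(resp2)
            keep = ~np.isin(neigh, list(exclude))
            pick = _weighted_sample_without_replacement(rng, neigh[keep], wts[keep], 1)
            resp2.append(str(pick[0]) if pick else noise_word(cue, exclude | set(first)))
        records.append(
            AssociationRecord(
                participant_id=participant_id,
                encounter_index=j,
                cue=cue,
                responses=tuple(resp2),
                is_repeat=True,
            )
        )
    return records


def _softmax_sample(rng: np.random.Generator, utilities: np.ndarray) -> int:
    z = utilities - utilities.max()
    p = np.exp(z)
    p /= p.sum()
    return int(rng.choice(len(p), p=p))


def simulate_fluency(
    centrality: CentralityVector,
    model: SimilarityModel | None,
    candidates: list[str],
    params: BehaviorParams,
    seed: int,
    participant_id: str,
    task: str,
    task_key: str,
) -> FluencySequence:
    """Sequential softmax retrieval: the first item is drawn proportional to
    exp(beta_c * PageRank); each next item additionally weights similarity
    to the previous retrieval, exp(beta_c * PR + beta_s * cosine)."""
    rng = np.random.default_rng(seed)
    pool = sorted(w for w in candidates if w in centrality)
    if not pool:
        raise ValueError("empty candidate set")
    items: list[str] = []
    while pool and len(items) < params.fluency_length:
        util = np.array([params.beta_centrality * centrality[w] for w in pool])
        if items and model is not None:
            prev = items[-1]
            util = util + np.array(
                [
                    params.beta_similarity * (model.cosine(prev, w) if w in model else 0.0)
                    for w in pool
                ]
            )
        chosen = pool.pop(_softmax_sample(rng, util))
        items.append(chosen)
    return FluencySequence(
        participant_id=participant_id, task=task, task_key=task_key, items=tuple(items)
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_episodic(
    truth: SemanticNetwork,
    centrality: CentralityVector,
    params: BehaviorParams,
    seed: int,
    participant_id: str,
    list_id: str = "L1",
) -> EpisodicTrial:
    """Uniformly sampled study list; recall probability logistic in scaled
    PageRank; intrusions injected from non-studied neighbors of recalled
    words at ``intrusion_rate``."""
    rng = np.random.default_rng(seed)
    nodes = sorted(truth.graph.nodes)
    if params.episodic_list_length > len(nodes):
        raise ValueError("list longer than lexicon")
    studied = [str(w) for w in rng.choice(np.array(nodes), params.episodic_list_length, False)]
    a = (
        params.episodic_intercept
        if params.episodic_intercept is not None
        else -params.beta_centrality  # centre: scaled PageRank has mean 1
    )
    pr = np.array([centrality[w] for w in studied])
    recalled_mask = rng.random(len(studied)) < _sigmoid(a + params.beta_centrality * pr)
    recalled = [w for w, m in zip(studied, recalled_mask) if m]
    intrusions: list[str] = []
    for w in recalled:
        if rng.random() < params.intrusion_rate:
            options = sorted(set(truth.graph[w]) - set(studied) - set(intrusions))
            if options:
                intrusions.append(str(options[int(rng.integers(len(options)))]))
    out = recalled + intrusions
    order = rng.permutation(len(out))
    return EpisodicTrial(
        participant_id=participant_id,
        list_id=list_id,
        studied=tuple(studied),
        recalled=tuple(out[i] for i in order),
    )


def simulate_paired(
    truth: SemanticNetwork,
    model: SimilarityModel,
    params: BehaviorParams,
    seed: int,
    participant_id: str,
) -> list[PairedAssociateTrial]:
    """Cue-target pairs spanning a range of cosines (half neighbor pairs,
    half random pairs); recall Bernoulli with log-odds linear in cosine."""
    if params.n_pairs < 2:
        raise ValueError("need >= 2 pairs")
    rng = np.random.default_rng(seed)
    nodes = sorted(truth.graph.nodes)
    arr = np.array(nodes)
    pairs: list[tuple[str, str]] = []
    while len(pairs) < params.n_pairs:
        cue = str(arr[rng.integers(len(arr))])
        if rng.random() < 0.5:
            neigh = sorted(truth.graph[cue])
            if not neigh:
                continue
            target = str(neigh[int(rng.integers(len(neigh)))])
        else:
            target = str(arr[rng.integers(len(arr))])
        if target != cue and (cue, target) not in pairs:
            pairs.append((cue, target))
    cos = np.array([model.cosine(c, t) for c, t in pairs])
    a = (
        params.paired_intercept
        if params.paired_intercept is not None
        else -params.beta_similarity * float(np.mean(cos))
    )
    recalled = rng.random(len(pairs)) < _sigmoid(a + params.beta_similarity * cos)
    return [
        PairedAssociateTrial(participant_id=participant_id, cue=c, target=t, recalled=bool(r))
        for (c, t), r in zip(pairs, recalled)
    ]


# ---------------------------------------------------------------------------
# whole-cohort generation


@dataclass
class CohortConfig:
    """Study-design parameters for a simulated cohort.

    The default profile is a desk-scale version of a two-group,
    eight-participant free-association study: 600 unique and 120 repeated
    cues per participant (three responses each), category and letter
    fluency, four episodic lists, and forty word pairs.
    """

    n_per_group: int = 4
    n_unique_cues: int = 600
    n_repeat_cues: int = 120
    group_params: dict[str, GroupParams] = field(default_factory=default_group_params)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    fluency_letter: str = "a"
    lexicon_alphabet: str = "abcdefgh"

    def scaled(self, n_unique: int, n_repeat: int) -> "CohortConfig":
        return dataclasses.replace(self, n_unique_cues=n_unique, n_repeat_cues=n_repeat)


def small_cohort_config() -> CohortConfig:
    """Reduced-scale cohort for Monte-Carlo validation work."""
    return CohortConfig(
        n_unique_cues=315,
        n_repeat_cues=63,
        group_params=small_group_params(),
        behavior=BehaviorParams(
            fluency_length=14,
            episodic_list_length=15,
            episodic_n_lists=8,
            n_pairs=40,
            noise_rate=0.02,
        ),
    )


@dataclass
class CohortData:
    """Everything one simulated study produces, in memory."""

    config: CohortConfig
    seed: int
    participants: "pd.DataFrame"  # noqa: F821 - imported lazily below
    records: list[AssociationRecord]
    fluency: list[FluencySequence]
    episodic: list[EpisodicTrial]
    paired: list[PairedAssociateTrial]
    truths: dict[str, SemanticNetwork]
    truth_centrality: dict[str, CentralityVector] | None = None
    truth_similarity: dict[str, SimilarityModel] | None = None

    def records_for(self, participant_id: str) -> list[AssociationRecord]:
        return [r for r in self.records if r.participant_id == participant_id]


def simulate_cohort(
    config: CohortConfig | None = None, seed: int = 0, include_behavior: bool = True
) -> CohortData:
    """Generate a full cohort: truth networks, associations, and (optionally)
    all four behavioral tasks for every participant."""
    import pandas as pd

    config = config or CohortConfig()
    root = np.random.SeedSequence(seed)
    sub = {name: s for name, s in zip(["lexicon", "truth", "ages", "behavior"], root.spawn(4))}
    lex_size = max(p.n_words for p in config.group_params.values())
    lexicon = make_lexicon(
        lex_size,
        seed=int(sub["lexicon"].generate_state(1)[0] % 2**31),
        alphabet=config.lexicon_alphabet,
    )

    truth_seeds = sub["truth"].spawn(len(config.group_params))
    truths = {
        label: generate_truth_network(
            gp, seed=int(s.generate_state(1)[0] % 2**31), lexicon=lexicon
        )
        for (label, gp), s in zip(sorted(config.group_params.items()), truth_seeds)
    }
    centrality = similarity = None
    if include_behavior:
        centrality = {label: pagerank(net, weighted=True) for label, net in truths.items()}
        similarity = {label: walk_similarity(net) for label, net in truths.items()}

    age_rng = np.random.default_rng(sub["ages"])
    age_ranges = {"young": (24, 29), "old": (68, 71)}
    rows, records = [], []
    fluency: list[FluencySequence] = []
    episodic: list[EpisodicTrial] = []
    paired: list[PairedAssociateTrial] = []
    groups = sorted(config.group_params)
    part_seeds = sub["behavior"].spawn(len(groups) * config.n_per_group)
    idx = 0
    for label in groups:
        lo, hi = age_ranges.get(label, (30, 60))
        for _ in range(config.n_per_group):
            pid = f"P{idx + 1:02d}"
            rows.append(
                {
                    "participant_id": pid,
                    "age": int(age_rng.integers(lo, hi)),
                    "group": label,
                }
            )
            streams = part_seeds[idx].spawn(6)
            sgen = lambda k: int(streams[k].generate_state(1)[0] % 2**31)
            truth = truths[label]
            records.extend(
                simulate_associations(
                    truth,
                    config.n_unique_cues,
                    config.n_repeat_cues,
                    config.behavior,
                    seed=sgen(0),
                    participant_id=pid,
                    priority_cues=tuple(truth.meta["categories"][ANIMAL_CATEGORY])
                    + tuple(sorted(letter_candidates(truth.graph.nodes, config.fluency_letter))),
                )
            )
            if include_behavior:
                cent, model = centrality[label], similarity[label]
                animals = truth.meta["categories"][ANIMAL_CATEGORY]
                fluency.append(
                    simulate_fluency(
                        cent, model, animals, config.behavior, sgen(1), pid,
                        task="category", task_key=ANIMAL_CATEGORY,
                    )
                )
                letters = sorted(letter_candidates(truth.graph.nodes, config.fluency_letter))
                fluency.append(
                    simulate_fluency(
                        cent, model, letters, config.behavior, sgen(2), pid,
                        task="letter", task_key=config.fluency_letter,
                    )
                )
                ep_seeds = streams[3].spawn(config.behavior.episodic_n_lists)
                for li, es in enumerate(ep_seeds, start=1):
                    episodic.append(
                        simulate_episodic(
                            truth, cent, config.behavior,
                            seed=int(es.generate_state(1)[0] % 2**31),
                            participant_id=pid, list_id=f"L{li}",
                        )
                    )
                paired.extend(
                    simulate_paired(truth, model, config.behavior, sgen(4), pid)
                )
            idx += 1
    return CohortData(
        config=config,
        seed=seed,
        participants=pd.DataFrame(rows),
        records=records,
        fluency=fluency,
        episodic=episodic,
        paired=paired,
        truths=truths,
        truth_centrality=centrality,
        truth_similarity=similarity,
    )


def write_cohort(data: CohortData, outdir: str | Path) -> None:
    """Write a cohort to the documented delimited-text layout."""
    import pandas as pd

    from . import io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.write_associations(data.records, outdir / "associations.csv")
    data.participants.to_csv(outdir / "participants.csv", index=False)
    pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "task": s.task,
                "task_key": s.task_key,
                "position": i + 1,
                "word": w,
            }
            for s in data.fluency
            for i, w in enumerate(s.items)
        ],
        columns=sio.FLUENCY_COLUMNS,
    ).to_csv(outdir / "fluency.csv", index=False)
    ep_rows = []
    for t in data.episodic:
        for phase, words in (("studied", t.studied), ("recalled", t.recalled)):
            for i, w in enumerate(words):
                ep_rows.append(
                    {
                        "participant_id": t.participant_id,
                        "list_id": t.list_id,
                        "phase": phase,
                        "position": i + 1,
                        "word": w,
                    }
                )
    pd.DataFrame(ep_rows, columns=sio.EPISODIC_COLUMNS).to_csv(
        outdir / "episodic.csv", index=False
    )
    pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "cue": t.cue,
                "target": t.target,
                "recalled": int(t.recalled),
            }
            for t in data.paired
        ],
        columns=sio.PAIRED_COLUMNS,
    ).to_csv(outdir / "paired.csv", index=False)
    for label, net in data.truths.items():
        sio.export_network(net, outdir / f"truth_{label}.tsv", fmt="tsv")
    with (outdir / "categories.json").open("w", encoding="utf-8") as fh:
        json.dump(
            {label: net.meta["categories"] for label, net in data.truths.items()},
            fh,
            indent=2,
            sort_keys=True,
        )
    with (outdir / "generating_params.json").open("w", encoding="utf-8") as fh:
        json.dump(
            {
                "seed": data.seed,
                "n_per_group": data.config.n_per_group,
                "n_unique_cues": data.config.n_unique_cues,
                "n_repeat_cues": data.config.n_repeat_cues,
                "fluency_letter": data.config.fluency_letter,
                "behavior": dataclasses.asdict(data.config.behavior),
                "group_params": {
                    k: dataclasses.asdict(v) for k, v in data.config.group_params.items()
                },
            },
            fh,
            indent=2,
            sort_keys=True,
        )
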