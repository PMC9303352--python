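"""Tabular input/output for free-association and behavioral task data.

All files are UTF-8 delimited text with fixed headers:

``associations.csv``
    participant_id, encounter_index, cue, r1, r2, r3, is_repeat (0/1).
    Empty response cells mean "no response", never an empty-string word.
``fluency.csv``
    participant_id, task (category|letter), task_key, position, word.
``episodic.csv``
    participant_id, list_id, phase (studied|recalled), position, word.
``paired.csv``
    participant_id, cue, target, recalled (0/1).
``participants.csv``
    participant_id, age, group (young|old).

Networks are exported either as a 3-column weighted edge-list TSV
(word_a, word_b, weight; word_a < word_b) or as GraphML with a ``weight``
edge attribute.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx
import pandas as pd

from .build import SemanticNetwork

logger = logging.getLogger(__name__)

_WS_RUN = re.compile(r"\s+")

ASSOCIATION_COLUMNS = ["participant_id", "encounter_index", "cue", "r1", "r2", "r3", "is_repeat"]
FLUENCY_COLUMNS = ["participant_id", "task", "task_key", "position", "word"]
EPISODIC_COLUMNS = ["participant_id", "list_id", "phase", "position", "word"]
PAIRED_COLUMNS = ["participant_id", "cue", "target", "recalled"]
PARTICIPANT_COLUMNS = ["participant_id", "age", "group"]


class SchemaError(ValueError):
    """A file header does not match the documented schema."""


class IntegrityError(ValueError):
    """File contents violate a within-file consistency rule."""


def canonicalize(word: str) -> str:
    """Canonical word form: lower-case, trimmed, internal whitespace collapsed.

    Deliberately minimal — no lemmatization or diacritic folding — so node
    identity in the resulting networks stays auditable. Idempotent.
    """
    return _WS_RUN.sub(" ", str(word).strip()).lower()


@dataclass(frozen=True)
class AssociationRecord:
    """One cue encounter (up to three ordered responses) for one participant."""

    participant_id: str
    encounter_index: int
    cue: str
    responses: tuple[str, ...]
    is_repeat: bool = False

    def __post_init__(self) -> None:
        if len(self.responses) > 3:
            raise ValueError("at most 3 responses per encounter")
        if not self.cue:
            raise ValueError("cue must be non-empty")
        if any(not r for r in self.responses):
            raise ValueError("missing responses must be absent, not empty strings")


@dataclass(frozen=True)
class FluencySequence:
    """Ordered retrievals in one verbal-fluency task run (duplicates removed)."""

    participant_id: str
    task: str  # "category" or "letter"
    task_key: str  # category label, or the initial letter
    items: tuple[str, ...]


@dataclass(frozen=True)
class EpisodicTrial:
    """One studied word list and the participant's free-recall output."""

    participant_id: str
    list_id: str
    studied: tuple[str, ...]
    recalled: tuple[str, ...]


@dataclass(frozen=True)
class PairedAssociateTrial:
    """One cue-target pair from paired-associate learning with its recall outcome."""

    participant_id: str
    cue: str
    target: str
    recalled: bool


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; expected header {list(required)}")
    return df


def load_associations(
    path: str | Path, canonicalizer: Callable[[str], str] = canonicalize
) -> list[AssociationRecord]:
    """Load association records, canonicalized, grouped by participant and
    ordered by encounter index.

    Rows with an empty cue are rejected; duplicate
    (participant, encounter_index) keys raise :class:`IntegrityError`.
    """
    df = _read_table(path, ASSOCIATION_COLUMNS)
    records: list[AssociationRecord] = []
    seen: set[tuple[str, int]] = set()
    for row in df.itertuples(index=False):
        cue = canonicalizer(row.cue)
        if not cue:
            raise IntegrityError(f"{path}: empty cue for participant {row.participant_id}")
        idx = int(row.encounter_index)
        key = (row.participant_id, idx)
        if key in seen:
            raise IntegrityError(f"{path}: duplicate encounter {key}")
        seen.add(key)
        responses = tuple(
            canonicalizer(r) for r in (row.r1, row.r2, row.r3) if str(r).strip() != ""
        )
        records.append(
            AssociationRecord(
                participant_id=str(row.participant_id),
                encounter_index=idx,
                cue=cue,
                responses=responses,
                is_repeat=str(row.is_repeat).strip() in {"1", "True", "true"},
            )
        )
    records.sort(key=lambda r: (r.participant_id, r.encounter_index))
    return records


def write_associations(records: Iterable[AssociationRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        resp = list(r.responses) + [""] * (3 - len(r.responses))
        rows.append(
            {
                "participant_id": r.participant_id,
                "encounter_index": r.encounter_index,
                "cue": r.cue,
                "r1": resp[0],
                "r2": resp[1],
                "r3": resp[2],
                "is_repeat": int(r.is_repeat),
            }
        )
    pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS).to_csv(path, index=False, encoding="utf-8")


def _dedup_keep_first(words: Sequence[str], context: str) -> tuple[str, ...]:
    seen: set[str] = set()
    out: list[str] = []
    dropped = 0
    for w in words:
        if w in seen:
            dropped += 1
            continue
        seen.add(w)
        out.append(w)
    if dropped:
        logger.info("%s: collapsed %d duplicate retrieval(s) to first occurrence", context, dropped)
    return tuple(out)


def load_fluency(
    path: str | Path, canonicalizer: Callable[[str], str] = canonicalize
) -> list[FluencySequence]:
    df = _read_table(path, FLUENCY_COLUMNS)
    df["position"] = df["position"].astype(int)
    out = []
    for (pid, task, key), grp in df.groupby(["participant_id", "task", "task_key"], sort=True):
        words = [canonicalizer(w) for w in grp.sort_values("position")["word"]]
        out.append(
            FluencySequence(
                participant_id=str(pid),
                task=str(task),
                task_key=canonicalizer(key),
                items=_dedup_keep_first(words, f"fluency {pid}/{task}/{key}"),
            )
        )
    return out


def load_episodic(
    path: str | Path, canonicalizer: Callable[[str], str] = canonicalize
) -> list[EpisodicTrial]:
    df = _read_table(path, EPISODIC_COLUMNS)
    df["position"] = df["position"].astype(int)
    out = []
    for (pid, list_id), grp in df.groupby(["participant_id", "list_id"], sort=True):
        by_phase = {
            phase: [canonicalizer(w) for w in sub.sort_values("position")["word"]]
            for phase, sub in grp.groupby("phase")
        }
        unknown = set(by_phase) - {"studied", "recalled"}
        if unknown:
            raise SchemaError(f"{path}: unknown phase value(s) {sorted(unknown)}")
        if "recalled" in by_phase and "studied" not in by_phase:
            raise IntegrityError(f"{path}: recalled list without studied list for {(pid, list_id)}")
        out.append(
            EpisodicTrial(
                participant_id=str(pid),
                list_id=str(list_id),
                studied=tuple(by_phase.get("studied", ())),
                recalled=_dedup_keep_first(
                    by_phase.get("recalled", ()), f"episodic {pid}/{list_id}"
                ),
            )
        )
    return out


def load_paired(
    path: str | Path, canonicalizer: Callable[[str], str] = canonicalize
) -> list[PairedAssociateTrial]:
    df = _read_table(path, PAIRED_COLUMNS)
    return [
        PairedAssociateTrial(
            participant_id=str(row.participant_id),
            cue=canonicalizer(row.cue),
            target=canonicalizer(row.target),
            recalled=str(row.recalled).strip() in {"1", "True", "true"},
        )
        for row in df.itertuples(index=False)
    ]


def load_behavior(
    fluency_path: str | Path,
    episodic_path: str | Path,
    paired_path: str | Path,
    canonicalizer: Callable[[str], str] = canonicalize,
) -> tuple[list[FluencySequence], list[EpisodicTrial], list[PairedAssociateTrial]]:
    """Load all three behavioral-task tables in one call."""
    return (
        load_fluency(fluency_path, canonicalizer),
        load_episodic(episodic_path, canonicalizer),
        load_paired(paired_path, canonicalizer),
    )


def load_participants(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, PARTICIPANT_COLUMNS)
    df["age"] = df["age"].astype(int)
    bad = set(df["group"]) - {"young", "old"}
    if bad:
        raise IntegrityError(f"{path}: unknown group label(s) {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# network export / import

_FORMATS = {"tsv", "graphml"}


def export_network(net: SemanticNetwork, path: str | Path, fmt: str = "tsv") -> None:
    """Write a network as a sorted weighted edge-list TSV or as GraphML.

    TSV rows are ``word_a <TAB> word_b <TAB> weight`` with word_a < word_b;
    reloading reproduces the network exactly (GraphML additionally keeps
    isolated nodes and metadata).
    """
    if net.n_nodes < 1:
        raise ValueError("cannot export an empty network")
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose one of {sorted(_FORMATS)}")
    path = Path(path)
    if fmt == "tsv":
        with path.open("w", encoding="utf-8") as fh:
            for a, b, w in sorted(
                (min(u, v), max(u, v), d["weight"]) for u, v, d in net.graph.edges(data=True)
            ):
                fh.write(f"{a}\t{b}\t{w}\n")
    else:
        g = net.graph.copy()
        g.graph["owner"] = net.owner
        if net.group is not None:
            g.graph["group"] = net.group
        nx.write_graphml(g, path, encoding="utf-8")


def load_network(
    path: str | Path, fmt: str = "tsv", owner: str = "unknown", group: str | None = None
) -> SemanticNetwork:
    """Inverse of :func:`export_network`."""
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose one of {sorted(_FORMATS)}")
    if fmt == "tsv":
        g = nx.Graph()
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                a, b, w = line.rstrip("\n").split("\t")
                g.add_edge(a, b, weight=int(w) if float(w) == int(float(w)) else float(w))
        return SemanticNetwork(graph=g, owner=owner, group=group)
    g = nx.read_graphml(path)
    for _, _, d in g.edges(data=True):
        w = d.get("weight", 1)
        d["weight"] = int(w) if float(w) == int(float(w)) else float(w)
    return SemanticNetwork(
        graph=g,
        owner=g.graph.get("owner", owner),
        group=g.graph.get("group", group),
    )
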