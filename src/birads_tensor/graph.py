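"""Knowledge-graph construction from BI-RADS annotations.

Each annotated image becomes a head entity; each of its characteristic
readings becomes a triple (head, characteristic, value) and its biopsy
result a triple (head, pathology, benign|malignant). Diagnosis is then
knowledge-graph completion: predict the missing pathology edge of an
unseen patient entity whose characteristic edges are known.

Characteristic value tails are namespaced as ``relation=value`` so the
same categorical label under two different characteristics yields two
distinct entities (prevents spurious parameter sharing).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, NamedTuple

import numpy as np

from .records import (
    CHARACTERISTICS,
    PATHOLOGY_RELATION,
    PATHOLOGY_VALUES,
    AnnotationRecord,
    SchemaError,
    head_to_case,
)

__all__ = [
    "Triple",
    "KnowledgeGraph",
    "FoldAssignment",
    "PathologyQuery",
    "annotation_to_triples",
    "build_graph",
    "split_folds",
    "mask_test_pathology",
    "read_triples",
    "write_triples",
]

ALLOWED_RELATIONS = (*CHARACTERISTICS, PATHOLOGY_RELATION)


class Triple(NamedTuple):
    """A knowledge statement K = (h, r, t)."""

    head: str
    relation: str
    tail: str


def annotation_to_triples(
    record: AnnotationRecord, include_pathology: bool = True
) -> list[Triple]:
    """Convert one image record to knowledge triples.

    One triple per characteristic (tails namespaced ``relation=value``),
    plus the pathology triple when ``include_pathology``.
    """
    head = record.head_id
    triples = []
    for name in CHARACTERISTICS:
        if name in record.characteristics:
            triples.append(Triple(head, name, f"{name}={record.characteristics[name]}"))
    if include_pathology:
        triples.append(Triple(head, PATHOLOGY_RELATION, record.pathology))
    return triples


@dataclass
class KnowledgeGraph:
    """Entity/relation vocabularies plus a deduplicated triple set.

    Orderings are first-seen, so identical input order reproduces
    identical integer indices. ``p`` counts entities that appear as heads,
    ``q`` the remaining (tail-only) entities; |E| = p + q with an entity
    appearing in both roles counted once, as a head.
    """

    entities: list[str]
    relations: list[str]
    triples: list[Triple]
    entity_index: dict[str, int]
    relation_index: dict[str, int]

    @property
    def n(self) -> int:
        return len(self.triples)

    @property
    def m(self) -> int:
        return len(self.relations)

    @property
    def heads(self) -> list[str]:
        seen = dict.fromkeys(t.head for t in self.triples)
        return list(seen)

    @property
    def p(self) -> int:
        return len(self.heads)

    @property
    def q(self) -> int:
        return len(self.entities) - self.p


def build_graph(triples: Iterable[Triple]) -> KnowledgeGraph:
    """Build a graph from triples: dedupe, index entities/relations first-seen."""
    deduped = list(dict.fromkeys(Triple(*t) for t in triples))
    if not deduped:
        raise ValueError("cannot build a knowledge graph from an empty triple list")
    entity_index: dict[str, int] = {}
    relation_index: dict[str, int] = {}
    for h, r, t in deduped:
        if not (h and r and t):
            raise SchemaError(f"triple components must be non-empty: {(h, r, t)}")
        for e in (h, t):
            if e not in entity_index:
                entity_index[e] = len(entity_index)
        if r not in relation_index:
            relation_index[r] = len(relation_index)
    return KnowledgeGraph(
        entities=list(entity_index),
        relations=list(relation_index),
        triples=deduped,
        entity_index=entity_index,
        relation_index=relation_index,
    )


@dataclass
class FoldAssignment:
    """Case-level k-fold partition (all images of a case share a fold)."""

    k: int
    assignment: dict[str, int]
    seed: int

    def fold_cases(self, fold: int) -> list[str]:
        return [c for c, f in self.assignment.items() if f == fold]


def split_folds(case_ids: Iterable[str], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Partition cases into k folds of size differing by at most one."""
    cases = list(dict.fromkeys(case_ids))
    if k < 1 or k > len(cases):
        raise ValueError(f"k={k} must be in [1, number of cases={len(cases)}]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    assignment = {cases[idx]: i % k for i, idx in enumerate(order)}
    return FoldAssignment(k=k, assignment={c: assignment[c] for c in cases}, seed=seed)


class PathologyQuery(NamedTuple):
    """A held-out diagnosis query: which pathology tail belongs to this head?"""

    head: str
    true_tail: str


def mask_test_pathology(
    graph: KnowledgeGraph,
    test_cases: Iterable[str],
    case_of_head: Callable[[str], str] = head_to_case,
) -> tuple[list[Triple], list[PathologyQuery]]:
    """Hold out the pathology edges of the test cases.

    Characteristic triples of test cases stay in the training material
    (the model must see a patient's features to diagnose); only their
    pathology triples are removed and returned as queries.
    """
    test = set(test_cases)
    known = {case_of_head(t.head) for t in graph.triples}
    missing = test - known
    if missing:
        raise ValueError(f"test cases absent from graph: {sorted(missing)}")
    train: list[Triple] = []
    queries: list[PathologyQuery] = []
    heads_with_pathology: set[str] = set()
    test_heads: set[str] = set()
    for t in graph.triples:
        case = case_of_head(t.head)
        if case in test:
            test_heads.add(t.head)
            if t.relation == PATHOLOGY_RELATION:
                heads_with_pathology.add(t.head)
                queries.append(PathologyQuery(t.head, t.tail))
                continue
        train.append(t)
    unqueried = test_heads - heads_with_pathology
    if unqueried:
        raise ValueError(f"test images without a pathology triple: {sorted(unqueried)}")
    return train, queries


def write_triples(triples: Iterable[Triple], path: str | Path) -> None:
    """Write triples as three-column tab-separated head/relation/tail."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for t in triples:
            writer.writerow(t)


def read_triples(path: str | Path) -> list[Triple]:
    """Read a triple TSV, preserving order."""
    triples = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if len(row) != 3:
                raise SchemaError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            triples.append(Triple(*row))
    return triples
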