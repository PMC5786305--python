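"""Ontology-anchored coherence evaluation of disease topics.

Two diseases count as related when any of their annotated ontology terms
share an ancestor within a fixed number of levels (default three) of the
ontology hierarchy, the term itself included. A topic's ranked disease list
is then scored by cumulative precision/recall: precision is the fraction of
extracted diseases that are annotated and have at least one related partner
among the extracted diseases; recall divides the same numerator by the
number of gold-standard diseases — annotated diseases of the full topic with
at least one related partner in the topic. The area under the resulting
curve summarizes topic-ontology agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np


@dataclass
class OntologyDAG:
    """Rooted DAG of disease terms with a disease-to-term annotation map."""

    terms: set[str]
    parents: dict[str, set[str]]
    annotations: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                if child not in self.terms or p not in self.terms:
                    raise ValueError(f"edge {child}->{p} references unknown term")
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        for disease, ts in self.annotations.items():
            missing = ts - self.terms
            if missing:
                raise ValueError(f"disease {disease} annotated to unknown terms {missing}")

    def is_annotated(self, disease: str) -> bool:
        return bool(self.annotations.get(disease))


@dataclass
class PRPoint:
    """One precision/recall point of the cumulative fold curve."""

    precision: float
    recall: float
    fold: int
    recall_defined: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.precision <= 1.0:
            raise ValueError("precision out of [0, 1]")
        if self.recall_defined and not 0.0 <= self.recall <= 1.0:
            raise ValueError("recall out of [0, 1]")


def read_ontology_tsv(path: str | Path) -> OntologyDAG:
    """Read a parent-child edge list (columns: child, parent)."""
    terms: set[str] = set()
    parents: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        child, parent = line.split("\t")[:2]
        terms.update((child, parent))
        parents.setdefault(child, set()).add(parent)
    return OntologyDAG(terms=terms, parents=parents)


def read_obo(path: str | Path) -> OntologyDAG:
    """Read an OBO-subset ontology (id / is_a structure) via obonet."""
    import obonet

    graph = obonet.read_obo(str(path))
    terms = set(graph.nodes)
    parents: dict[str, set[str]] = {}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents.setdefault(child, set()).add(parent)
    return OntologyDAG(terms=terms, parents=parents)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read disease-to-term annotations (columns: disease id, term id)."""
    annotations: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        disease, term = line.split("\t")[:2]
        annotations.setdefault(disease, set()).add(term)
    return annotations


def ancestors_within(dag: OntologyDAG, term: str, levels: int = 3) -> set[str]:
    """Terms reachable from ``term`` via at most ``levels`` parent edges.

    BFS over the DAG; the term itself is excluded.
    """
    if term not in dag.terms:
        raise KeyError(f"unknown term {term!r}")
    if levels < 1:
        raise ValueError("levels must be positive")
    found: set[str] = set()
    frontier = {term}
    for _ in range(levels):
        frontier = {p for t in frontier for p in dag.parents.get(t, ())}
        frontier -= found
        if not frontier:
            break
        found |= frontier
    return found


def diseases_similar(
    dag: OntologyDAG, d1: str, d2: str, levels: int = 3
) -> bool | None:
    """Whether two diseases share an ancestor within ``levels`` of the hierarchy.

    Each annotated term contributes itself plus its ancestors within
    ``levels``; the diseases are related when those term sets intersect.
    Returns ``None`` (not ``False``) when either disease is unannotated.
    """
    if not dag.is_annotated(d1) or not dag.is_annotated(d2):
        return None
    up1 = set()
    for t in dag.annotations[d1]:
        up1.add(t)
        up1 |= ancestors_within(dag, t, levels)
    for t in dag.annotations[d2]:
        if t in up1 or (ancestors_within(dag, t, levels) | {t}) & up1:
            return True
    return False


def _has_partner(disease: str, pool, dag: OntologyDAG, levels: int) -> bool:
    return any(
        other != disease and diseases_similar(dag, disease, other, levels) is True
        for other in pool
    )


def precision_recall(
    topic_diseases: list[str],
    dag: OntologyDAG,
    folds: int = 10,
    levels: int = 3,
    mode: str = "cumulative",
) -> list[PRPoint]:
    """Cumulative precision/recall curve of a topic's ranked disease list.

    Fold f extracts the top ``ceil(f * n / folds)`` diseases (``cumulative``
    mode) or the f-th disjoint rank block (``partition`` mode). Precision is
    the number of annotated extracted diseases with a related partner among
    the extracted diseases over the number of extracted diseases; recall
    divides by the gold-standard count — annotated diseases of the full list
    with a related partner anywhere in the list. Unannotated diseases count
    in precision's denominator but never the numerator. When the gold
    standard is empty every recall is flagged undefined.
    """
    if not topic_diseases:
        raise ValueError("topic_diseases must be non-empty")
    if folds < 1:
        raise ValueError("folds must be >= 1")
    n = len(topic_diseases)
    gold = [
        d
        for d in topic_diseases
        if dag.is_annotated(d) and _has_partner(d, topic_diseases, dag, levels)
    ]
    points: list[PRPoint] = []
    for f in range(1, folds + 1):
        if mode == "cumulative":
            extracted = topic_diseases[: math.ceil(f * n / folds)]
        elif mode == "partition":
            lo = math.ceil((f - 1) * n / folds)
            hi = math.ceil(f * n / folds)
            extracted = topic_diseases[lo:hi]
            if not extracted:
                continue
        else:
            raise ValueError("mode must be 'cumulative' or 'partition'")
        hits = sum(
            1
            for d in extracted
            if dag.is_annotated(d) and _has_partner(d, extracted, dag, levels)
        )
        precision = hits / len(extracted)
        if gold:
            points.append(PRPoint(precision=precision, recall=hits / len(gold), fold=f))
        else:
            points.append(
                PRPoint(precision=precision, recall=float("nan"), fold=f, recall_defined=False)
            )
    return points


def auc(points: list[PRPoint]) -> float:
    """Trapezoidal area under a precision/recall curve, clipped to [0, 1].

    Points are sorted by recall; duplicate recalls collapse to their maximum
    precision, so the result is order-invariant.
    """
    if len(points) < 2:
        raise ValueError("need at least two PR points")
    defined = [p for p in points if p.recall_defined]
    if not defined:
        raise ValueError("no measurable recall")
    best: dict[float, float] = {}
    for p in defined:
        best[p.recall] = max(best.get(p.recall, 0.0), p.precision)
    recalls = sorted(best)
    if len(recalls) == 1:
        return float(np.clip(best[recalls[0]] * recalls[0], 0.0, 1.0))
    precisions = [best[r] for r in recalls]
    return float(np.clip(np.trapezoid(precisions, recalls), 0.0, 1.0))
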