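"""Semantic and functional similarity kernels.

Two kernels feed the heterogeneous graph:

* **Disease semantic similarity** over an ontology DAG.  Each disease W
  receives a semantic profile: its own contribution is 1 and each
  ancestor d contributes ``max(delta * contribution(child))`` over d's
  children inside Col(W), with decay factor ``delta`` (default 0.5).
  Similarity between two diseases is the overlap of their profiles,

      DS(di, dj) = sum_{t in Col(di) ∩ Col(dj)} (D_di(t) + D_dj(t))
                   / (DV(di) + DV(dj)),

  where DV is the sum of a profile's contributions.

* **Functional similarity** between two RNAs (lncRNA or miRNA) from
  their associated disease sets: best-match averaging of the disease
  similarities in both directions, normalised by the total number of
  associated diseases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .ontology import DiseaseOntology, OntologyError

__all__ = [
    "SemanticProfile",
    "SimilarityMatrix",
    "semantic_contributions",
    "disease_semantic_similarity",
    "disease_similarity_matrix",
    "functional_similarity",
    "functional_similarity_matrix",
]

DEFAULT_DELTA = 0.5


@dataclass(frozen=True)
class SemanticProfile:
    """Decayed ancestor contributions of one disease term."""

    target: str
    contributions: Mapping[str, float]
    delta: float

    @property
    def dv(self) -> float:
        """Semantic value: sum of all contributions (>= 1)."""
        return float(sum(self.contributions.values()))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix with unit diagonal in [0, 1]."""

    entity_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if v.shape != (n, n):
            raise ValueError(f"expected {(n, n)} matrix, got {v.shape}")
        if len(set(self.entity_ids)) != n:
            raise ValueError("duplicate entity ids in similarity matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("similarity matrix diagonal is not 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity values outside [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "_index", {e: i for i, e in enumerate(self.entity_ids)})

    def loc(self, a: str, b: str) -> float:
        idx = self._index  # type: ignore[attr-defined]
        try:
            return float(self.values[idx[a], idx[b]])
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in similarity matrix") from None


def semantic_contributions(
    ontology: DiseaseOntology, target: str, delta: float = DEFAULT_DELTA
) -> SemanticProfile:
    """Compute the semantic profile D_target(·) over Col(target).

    The target's own contribution is 1; each proper ancestor takes the
    maximum of ``delta`` times the contribution of any of its children
    lying inside Col(target).  Propagation runs in reverse-topological
    order of the induced ancestor sub-DAG, so multiple inheritance is
    handled by the max exactly once per node.
    """
    if not 0 < delta < 1:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    closure = ontology.ancestor_closure(target)
    # order ancestors child-before-parent: topological order of the
    # parent->child sub-DAG, reversed
    sub = nx.DiGraph()
    sub.add_nodes_from(closure)
    for node in closure:
        for child in ontology.children(node):
            if child in closure:
                sub.add_edge(node, child)
    contributions: dict[str, float] = {target: 1.0}
    for node in reversed(list(nx.topological_sort(sub))):
        if node == target:
            continue
        best = max(
            contributions[child]
            for child in sub.successors(node)
            # every child inside the closure is already resolved
        )
        contributions[node] = delta * best
    return SemanticProfile(target=target, contributions=contributions, delta=delta)


def disease_semantic_similarity(p1: SemanticProfile, p2: SemanticProfile) -> float:
    """Overlap similarity of two semantic profiles (symmetric, in [0, 1])."""
    if p1.delta != p2.delta:
        raise ValueError(
            f"profiles computed with different delta ({p1.delta} vs {p2.delta})"
        )
    shared = p1.contributions.keys() & p2.contributions.keys()
    if not shared:
        return 0.0
    num = sum(p1.contributions[t] + p2.contributions[t] for t in shared)
    return num / (p1.dv + p2.dv)


def disease_similarity_matrix(
    ontology: DiseaseOntology,
    disease_ids: Sequence[str],
    delta: float = DEFAULT_DELTA,
) -> SimilarityMatrix:
    """Pairwise disease semantic similarity for an ordered id list."""
    if len(set(disease_ids)) != len(disease_ids):
        dupes = sorted({d for d in disease_ids if list(disease_ids).count(d) > 1})
        raise ValueError(f"duplicate disease ids: {dupes}")
    missing = [d for d in disease_ids if d not in ontology]
    if missing:
        raise OntologyError(f"diseases missing from ontology: {missing}")
    profiles = [semantic_contributions(ontology, d, delta) for d in disease_ids]
    n = len(disease_ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = disease_semantic_similarity(
                profiles[i], profiles[j]
            )
    return SimilarityMatrix(entity_ids=tuple(disease_ids), values=values)


def functional_similarity(
    diseases_of_z1: Iterable[str],
    diseases_of_z2: Iterable[str],
    ds: SimilarityMatrix,
) -> float:
    """Best-match-average similarity of two associated-disease sets."""
    set1, set2 = list(set(diseases_of_z1)), list(set(diseases_of_z2))
    if not set1 or not set2:
        raise ValueError("functional similarity requires non-empty disease sets")
    for d in set1 + set2:
        if d not in ds.entity_ids:
            raise KeyError(f"disease id {d!r} not covered by similarity matrix")
    forward = sum(max(ds.loc(a, b) for b in set2) for a in set1)
    backward = sum(max(ds.loc(b, a) for a in set1) for b in set2)
    return (forward + backward) / (len(set1) + len(set2))


def functional_similarity_matrix(
    entity_disease_map: Mapping[str, Iterable[str]],
    ds: SimilarityMatrix,
    entity_order: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Pairwise functional similarity for all entities of one class.

    Entities with an empty associated-disease set get 0 off-diagonal and
    1 on the diagonal, keeping the block a valid similarity matrix.
    """
    ids = tuple(entity_order if entity_order is not None else entity_disease_map)
    sets = {e: set(entity_disease_map.get(e, ())) for e in ids}
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sets[ids[i]], sets[ids[j]]
            if a and b:
                values[i, j] = values[j, i] = functional_similarity(a, b, ds)
    return SimilarityMatrix(entity_ids=ids, values=values)
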