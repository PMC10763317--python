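"""Disease ontology as a rooted directed acyclic graph.

Disease terms live in a DAG whose edges point from parent (more general
term) to child (more specific term).  For a term ``d`` the set ``Col(d)``
— the term itself plus all of its ancestors — is the support on which
semantic similarity between diseases is computed.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable

import networkx as nx

__all__ = ["DiseaseOntology", "OntologyError"]


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or unknown term ids."""


class DiseaseOntology:
    """A DAG of disease terms with parent→child edges.

    Parameters
    ----------
    parent_edges:
        Iterable of ``(parent_id, child_id)`` pairs.
    terms:
        Optional iterable of term ids; ids appearing in edges are always
        included, so this is only needed for isolated terms.

    Raises
    ------
    OntologyError
        If the edge set contains a cycle or a self-edge.
    """

    def __init__(
        self,
        parent_edges: Iterable[tuple[str, str]],
        terms: Iterable[str] | None = None,
    ) -> None:
        g = nx.DiGraph()
        if terms is not None:
            g.add_nodes_from(terms)
        for parent, child in parent_edges:
            if parent == child:
                raise OntologyError(f"self-edge on term {parent!r}")
            g.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyError(f"ontology contains a cycle: {path}")
        self._graph = g
        # cache per instance; ontology is immutable after construction
        self._closure_cache: dict[str, frozenset[str]] = {}

    # -- basic accessors -------------------------------------------------

    @property
    def terms(self) -> list[str]:
        return list(self._graph.nodes)

    @property
    def parent_edges(self) -> set[tuple[str, str]]:
        return set(self._graph.edges)

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def parents(self, term: str) -> set[str]:
        self._require(term)
        return set(self._graph.predecessors(term))

    def children(self, term: str) -> set[str]:
        self._require(term)
        return set(self._graph.successors(term))

    def roots(self) -> set[str]:
        return {t for t in self._graph.nodes if self._graph.in_degree(t) == 0}

    # -- closures --------------------------------------------------------

    def ancestor_closure(self, term: str) -> frozenset[str]:
        """``Col(term)``: the term plus every ancestor reachable child→parent."""
        self._require(term)
        cached = self._closure_cache.get(term)
        if cached is None:
            cached = frozenset(nx.ancestors(self._graph, term)) | {term}
            self._closure_cache[term] = cached
        return cached

    def _require(self, term: str) -> None:
        if term not in self._graph:
            raise OntologyError(f"unknown term id {term!r}")
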