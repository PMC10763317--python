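"""End-to-end plumbing: similarity blocks → heterogeneous graph → labels.

Convenience layer the CLI, examples and acceptance script share: build
the intraclass similarity blocks from an ontology and association
matrices, assemble the heterogeneous graph, and derive a labeled pair
set (all known positives plus an equal number of sampled negatives).
"""

from __future__ import annotations

import numpy as np

from .evaluation import sample_negatives
from .graph import HeterogeneousGraph, assemble_adjacency
from .ontology import DiseaseOntology
from .similarity import (
    SimilarityMatrix,
    disease_similarity_matrix,
    functional_similarity_matrix,
)
from .synthetic import SyntheticDataset

__all__ = ["build_heterogeneous_graph", "graph_from_dataset", "labeled_pairs"]


def build_heterogeneous_graph(
    ontology: DiseaseOntology,
    lnc_ids,
    dis_ids,
    mir_ids,
    Z_ld: np.ndarray,
    Z_lm: np.ndarray,
    Z_md: np.ndarray,
    delta: float = 0.5,
) -> HeterogeneousGraph:
    """Derive S blocks (semantic + functional similarity) and assemble.

    Disease similarity comes from the ontology; lncRNA and miRNA
    functional similarities come from each entity's associated-disease
    set as recorded in ``Z_ld`` and ``Z_md`` respectively.
    """
    s_dd = disease_similarity_matrix(ontology, list(dis_ids), delta=delta)
    lnc_map = {
        l: {dis_ids[j] for j in np.flatnonzero(Z_ld[i])}
        for i, l in enumerate(lnc_ids)
    }
    mir_map = {
        m: {dis_ids[j] for j in np.flatnonzero(Z_md[i])}
        for i, m in enumerate(mir_ids)
    }
    s_ll = functional_similarity_matrix(lnc_map, s_dd, entity_order=lnc_ids)
    s_mm = functional_similarity_matrix(mir_map, s_dd, entity_order=mir_ids)
    return assemble_adjacency(
        s_ll, s_dd, s_mm, Z_ld, Z_lm, Z_md,
        lnc_ids=lnc_ids, dis_ids=dis_ids, mir_ids=mir_ids,
    )


def graph_from_dataset(data: SyntheticDataset, delta: float = 0.5) -> HeterogeneousGraph:
    return build_heterogeneous_graph(
        data.ontology, data.lnc_ids, data.dis_ids, data.mir_ids,
        data.Z_ld, data.Z_lm, data.Z_md, delta=delta,
    )


def labeled_pairs(
    Z_ld: np.ndarray, seed: int = 0, negative_ratio: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """All positive pairs plus sampled negatives with binary labels."""
    positives = np.argwhere(np.asarray(Z_ld) == 1)
    n_lnc, n_dis = np.asarray(Z_ld).shape
    n_neg = int(round(negative_ratio * len(positives)))
    negatives = sample_negatives(
        {tuple(p) for p in positives}, n_lnc, n_dis, n=n_neg, seed=seed
    )
    pairs = np.concatenate([positives, negatives])
    labels = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    return pairs, labels.astype(int)
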