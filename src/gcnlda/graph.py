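"""Heterogeneous graph assembly and normalisation.

The adjacency matrix of the lncRNA/disease/miRNA graph is a 3×3 block
matrix with intraclass similarity blocks S on the diagonal and binary
interclass association blocks Z off-diagonal, in fixed node order
[lncRNA, disease, miRNA]:

    X = [[S_ll,    Z_ld,   Z_lm ],
         [Z_ld^T,  S_dd,   Z_md^T],
         [Z_lm^T,  Z_md,   S_mm ]]

The feature matrix is the row-normalised X (without self-loops); the
propagation operator adds self-loops and applies symmetric Laplacian
normalisation  X~ = E^{-1/2} (X + I) E^{-1/2}  with E the degree matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "HeterogeneousGraph",
    "NormalizedGraph",
    "assemble_adjacency",
    "build_feature_matrix",
    "add_self_loops",
    "symmetric_normalize",
    "mask_fold_edges",
    "normalize_graph",
]


def _check_binary(name: str, block: np.ndarray) -> np.ndarray:
    block = np.asarray(block, dtype=float)
    bad = ~np.isin(block, (0.0, 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"association block {name} must be binary; "
            f"found {block[i, j]!r} at ({i}, {j})"
        )
    return block


@dataclass(frozen=True)
class HeterogeneousGraph:
    """Entity id lists, similarity/association blocks and the assembled matrix."""

    lnc_ids: tuple[str, ...]
    dis_ids: tuple[str, ...]
    mir_ids: tuple[str, ...]
    S_ll: np.ndarray = field(repr=False)
    S_dd: np.ndarray = field(repr=False)
    S_mm: np.ndarray = field(repr=False)
    Z_ld: np.ndarray = field(repr=False)
    Z_lm: np.ndarray = field(repr=False)
    Z_md: np.ndarray = field(repr=False)

    @property
    def n_lnc(self) -> int:
        return len(self.lnc_ids)

    @property
    def n_dis(self) -> int:
        return len(self.dis_ids)

    @property
    def n_mir(self) -> int:
        return len(self.mir_ids)

    @property
    def n_total(self) -> int:
        return self.n_lnc + self.n_dis + self.n_mir

    @property
    def x_complex(self) -> np.ndarray:
        """Assemble the full block adjacency matrix (symmetric)."""
        return np.block(
            [
                [self.S_ll, self.Z_ld, self.Z_lm],
                [self.Z_ld.T, self.S_dd, self.Z_md.T],
                [self.Z_lm.T, self.Z_md, self.S_mm],
            ]
        )


@dataclass(frozen=True)
class NormalizedGraph:
    """Derived matrices used by the GCN encoder."""

    x_hat: np.ndarray = field(repr=False)
    degree: np.ndarray = field(repr=False)
    x_tilde: np.ndarray = field(repr=False)
    x_feature: np.ndarray = field(repr=False)


def assemble_adjacency(
    S_ll: SimilarityMatrix | np.ndarray,
    S_dd: SimilarityMatrix | np.ndarray,
    S_mm: SimilarityMatrix | np.ndarray,
    Z_ld: np.ndarray,
    Z_lm: np.ndarray,
    Z_md: np.ndarray,
    lnc_ids: Sequence[str] | None = None,
    dis_ids: Sequence[str] | None = None,
    mir_ids: Sequence[str] | None = None,
) -> HeterogeneousGraph:
    """Validate block shapes and build the heterogeneous graph.

    ``Z_ld`` is N_l×N_d, ``Z_lm`` is N_l×N_m and ``Z_md`` is N_m×N_d;
    transposed copies fill the mirrored block positions.
    """

    def _unpack(s, default_prefix, n=None):
        if isinstance(s, SimilarityMatrix):
            return s.values, s.entity_ids
        s = np.asarray(s, dtype=float)
        count = s.shape[0] if n is None else n
        return s, tuple(f"{default_prefix}{i}" for i in range(count))

    s_ll, auto_l = _unpack(S_ll, "l")
    s_dd, auto_d = _unpack(S_dd, "d")
    s_mm, auto_m = _unpack(S_mm, "m")
    lnc = tuple(lnc_ids) if lnc_ids is not None else auto_l
    dis = tuple(dis_ids) if dis_ids is not None else auto_d
    mir = tuple(mir_ids) if mir_ids is not None else auto_m

    z_ld = _check_binary("Z_ld", Z_ld)
    z_lm = _check_binary("Z_lm", Z_lm)
    z_md = _check_binary("Z_md", Z_md)

    nl, nd, nm = len(lnc), len(dis), len(mir)
    expected = {
        "S_ll": ((nl, nl), s_ll.shape),
        "S_dd": ((nd, nd), s_dd.shape),
        "S_mm": ((nm, nm), s_mm.shape),
        "Z_ld": ((nl, nd), z_ld.shape),
        "Z_lm": ((nl, nm), z_lm.shape),
        "Z_md": ((nm, nd), z_md.shape),
    }
    bad = {k: v for k, v in expected.items() if v[0] != v[1]}
    if bad:
        detail = ", ".join(f"{k}: expected {e} got {a}" for k, (e, a) in bad.items())
        raise ValueError(f"inconsistent block dimensions — {detail}")

    return HeterogeneousGraph(
        lnc_ids=lnc, dis_ids=dis, mir_ids=mir,
        S_ll=s_ll, S_dd=s_dd, S_mm=s_mm,
        Z_ld=z_ld, Z_lm=z_lm, Z_md=z_md,
    )


def build_feature_matrix(g: HeterogeneousGraph) -> np.ndarray:
    """Row-normalise the assembled adjacency; all-zero rows stay zero."""
    x = g.x_complex
    sums = x.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, x / sums, 0.0)
    return out


def add_self_loops(x_complex: np.ndarray) -> np.ndarray:
    """X + I, applied literally (a unit diagonal becomes 2)."""
    x = np.asarray(x_complex, dtype=float)
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {x.shape}")
    return x + np.eye(x.shape[0])


def symmetric_normalize(x_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degree vector and E^{-1/2} X^ E^{-1/2}."""
    x_hat = np.asarray(x_hat, dtype=float)
    degree = x_hat.sum(axis=1)
    if (degree <= 0).any():
        raise RuntimeError("zero or negative degree after self-loops")
    inv_sqrt = 1.0 / np.sqrt(degree)
    x_tilde = x_hat * inv_sqrt[:, None] * inv_sqrt[None, :]
    return degree, x_tilde


def normalize_graph(g: HeterogeneousGraph) -> NormalizedGraph:
    """Full derivation: features, self-loops and symmetric normalisation."""
    x_feature = build_feature_matrix(g)
    x_hat = add_self_loops(g.x_complex)
    degree, x_tilde = symmetric_normalize(x_hat)
    return NormalizedGraph(
        x_hat=x_hat, degree=degree, x_tilde=x_tilde, x_feature=x_feature
    )


def mask_fold_edges(
    g: HeterogeneousGraph, held_out_pairs: Sequence[tuple[int, int]]
) -> HeterogeneousGraph:
    """Copy the graph with held-out (lncRNA, disease) entries zeroed in Z_ld."""
    z = g.Z_ld.copy()
    for li, di in held_out_pairs:
        if not (0 <= li < g.n_lnc and 0 <= di < g.n_dis):
            raise IndexError(
                f"pair ({li}, {di}) out of range for "
                f"{g.n_lnc} lncRNAs x {g.n_dis} diseases"
            )
        z[li, di] = 0.0
    return replace(g, Z_ld=z)
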