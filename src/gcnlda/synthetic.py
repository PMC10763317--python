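"""Seeded synthetic ontology and association benchmark.

Emulates the structure of a curated lncRNA/miRNA/disease corpus: a
rooted disease-term DAG and binary association matrices with planted
block structure.  Disease groups are ontology branches (subtrees under
the root), so disease semantic similarity genuinely correlates with
the planted association pattern — mirroring the premise that
functionally similar RNAs attach to semantically similar diseases.
Within a matched latent group a pair is associated with probability
``p_in``, otherwise ``p_out``.  All randomness derives from one seed
through independent child streams, so each artifact is reproducible
independent of generation order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ontology import DiseaseOntology

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_ontology",
           "generate_heterogeneous_associations", "generate_dataset",
           "generate_benchmark", "resolve_preset", "SMALL_PRESET"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Benchmark shape: entity counts, ontology shape, block structure."""

    n_lnc: int = 60
    n_dis: int = 40
    n_mir: int = 50
    n_terms: int = 80
    max_parents: int = 2
    depth: int = 6
    n_groups: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lnc, self.n_dis, self.n_mir) < 1:
            raise ValueError("entity counts must be positive")
        if not 0 <= self.p_out <= self.p_in <= 1:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.n_terms < self.n_dis:
            raise ValueError("n_terms must be >= n_dis")
        if self.n_terms < self.n_groups + 1:
            raise ValueError("n_terms must cover root plus one term per group")


SMALL_PRESET = SyntheticSpec()  # the default benchmark condition

_PRESETS = {"small": SMALL_PRESET}


@dataclass
class SyntheticDataset:
    """In-memory benchmark: ontology, id lists, Z blocks and truth groups."""

    spec: SyntheticSpec
    ontology: DiseaseOntology
    lnc_ids: tuple[str, ...]
    dis_ids: tuple[str, ...]
    mir_ids: tuple[str, ...]
    Z_ld: np.ndarray = field(repr=False)
    Z_lm: np.ndarray = field(repr=False)
    Z_md: np.ndarray = field(repr=False)
    groups: dict[str, int]

    @property
    def positive_pairs(self) -> np.ndarray:
        """Index pairs of all planted lncRNA-disease associations."""
        return np.argwhere(self.Z_ld == 1)


def _term_name(i: int) -> str:
    return f"T{i:04d}"


def generate_ontology(spec: SyntheticSpec) -> tuple[DiseaseOntology, dict[str, int]]:
    """Random rooted DAG whose top-level branches define term groups.

    Returns the ontology and a term→branch map (root maps to -1).
    Each non-root term draws 1..max_parents parents among shallower
    terms of its own branch, so the graph is acyclic by construction
    and every branch is a subtree-like component under the root.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    root = _term_name(0)
    edges: list[tuple[str, str]] = []
    branch_of: dict[str, int] = {root: -1}
    # one branch head per group directly under the root
    by_branch: dict[int, list[list[str]]] = {}
    for g in range(spec.n_groups):
        head = _term_name(1 + g)
        edges.append((root, head))
        branch_of[head] = g
        by_branch[g] = [[head]]  # levels, starting below the root
    next_id = 1 + spec.n_groups
    while next_id < spec.n_terms:
        term = _term_name(next_id)
        g = int(rng.integers(spec.n_groups))
        levels = by_branch[g]
        depth_here = min(len(levels), spec.depth - 1)
        level = int(rng.integers(depth_here)) + 1 if depth_here > 0 else 1
        shallower = [t for lv in levels[:level] for t in lv]
        k = int(rng.integers(1, spec.max_parents + 1))
        parents = rng.choice(shallower, size=min(k, len(shallower)), replace=False)
        for p in parents:
            edges.append((str(p), term))
        if level >= len(levels):
            levels.append([])
        levels[level].append(term)
        branch_of[term] = g
        next_id += 1
    return DiseaseOntology(edges), branch_of


def generate_heterogeneous_associations(
    spec: SyntheticSpec, ontology: DiseaseOntology, branch_of: dict[str, int]
) -> SyntheticDataset:
    """Planted-block binary association matrices tied to ontology branches."""
    ss = np.random.SeedSequence([spec.seed, 1])
    rng_groups, rng_ld, rng_lm, rng_md, rng_dis = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    # diseases are ontology terms drawn across branches; group = branch
    candidates = [t for t, g in branch_of.items() if g >= 0]
    order = rng_dis.permutation(len(candidates))
    dis_terms = [candidates[i] for i in order[: spec.n_dis]]
    dis_groups = np.array([branch_of[t] for t in dis_terms])

    lnc_ids = tuple(f"L{i:04d}" for i in range(spec.n_lnc))
    mir_ids = tuple(f"M{i:04d}" for i in range(spec.n_mir))
    lnc_groups = rng_groups.integers(spec.n_groups, size=spec.n_lnc)
    mir_groups = rng_groups.integers(spec.n_groups, size=spec.n_mir)

    def planted(rng, rows, cols):
        match = rows[:, None] == cols[None, :]
        prob = np.where(match, spec.p_in, spec.p_out)
        return (rng.random(prob.shape) < prob).astype(float)

    z_ld = planted(rng_ld, lnc_groups, dis_groups)
    z_lm = planted(rng_lm, lnc_groups, mir_groups)
    z_md = planted(rng_md, mir_groups, dis_groups)

    groups = {**{l: int(g) for l, g in zip(lnc_ids, lnc_groups)},
              **{d: int(g) for d, g in zip(dis_terms, dis_groups)},
              **{m: int(g) for m, g in zip(mir_ids, mir_groups)}}
    return SyntheticDataset(
        spec=spec, ontology=ontology,
        lnc_ids=lnc_ids, dis_ids=tuple(dis_terms), mir_ids=mir_ids,
        Z_ld=z_ld, Z_lm=z_lm, Z_md=z_md, groups=groups,
    )


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Ontology plus associations in one call."""
    ontology, branch_of = generate_ontology(spec)
    return generate_heterogeneous_associations(spec, ontology, branch_of)


def resolve_preset(name: str) -> SyntheticSpec:
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")


def generate_benchmark(spec: SyntheticSpec, out_dir: str | Path) -> SyntheticDataset:
    """Generate and write the benchmark as TSV files plus a JSON manifest."""
    from . import io as gio  # local import to avoid a cycle

    data = generate_dataset(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_ontology(out / "ontology.tsv", data.ontology)
    gio.write_entity_list(out / "lncrnas.txt", data.lnc_ids)
    gio.write_entity_list(out / "diseases.txt", data.dis_ids)
    gio.write_entity_list(out / "mirnas.txt", data.mir_ids)
    gio.write_edge_list(out / "lncrna_disease.tsv", data.Z_ld, data.lnc_ids, data.dis_ids)
    gio.write_edge_list(out / "lncrna_mirna.tsv", data.Z_lm, data.lnc_ids, data.mir_ids)
    gio.write_edge_list(out / "mirna_disease.tsv", data.Z_md, data.mir_ids, data.dis_ids)
    with open(out / "groups.tsv", "w") as fh:
        fh.write("entity\tgroup\n")
        for ent, grp in data.groups.items():
            fh.write(f"{ent}\t{grp}\n")
    manifest = {"spec": dataclasses.asdict(spec), "seed": spec.seed}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return data
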