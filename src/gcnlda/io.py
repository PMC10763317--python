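"""TSV readers/writers, entity indexing and configuration.

Conventions: two-column tab-separated edge lists with optional single
header line and ``#`` comments; dense similarity matrices as TSV with
an id header row and column; entity universes as one-column id files.
Ids are opaque strings, trimmed but otherwise untouched.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import ModelConfig
from .ontology import DiseaseOntology
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EntityIndex", "RunConfig", "load_config",
    "read_entity_list", "write_entity_list",
    "read_edge_list", "write_edge_list",
    "read_ontology", "write_ontology",
    "read_matrix", "write_matrix", "write_manifest",
]


class ParseError(ValueError):
    """Raised for malformed input files; carries file and line context."""


@dataclass(frozen=True)
class EntityIndex:
    """Ordered per-class id lists with id↔index maps."""

    lnc_ids: tuple[str, ...]
    dis_ids: tuple[str, ...]
    mir_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, ids in (("lncRNA", self.lnc_ids), ("disease", self.dis_ids),
                          ("miRNA", self.mir_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")
        object.__setattr__(self, "lnc_index", {e: i for i, e in enumerate(self.lnc_ids)})
        object.__setattr__(self, "dis_index", {e: i for i, e in enumerate(self.dis_ids)})
        object.__setattr__(self, "mir_index", {e: i for i, e in enumerate(self.mir_ids)})

    def maps_for(self, kind: str) -> tuple[dict, dict]:
        kinds = {
            "ld": (self.lnc_index, self.dis_index),
            "lm": (self.lnc_index, self.mir_index),
            "md": (self.mir_index, self.dis_index),
        }
        if kind not in kinds:
            raise ValueError(f"unknown edge kind {kind!r}; use one of {sorted(kinds)}")
        return kinds[kind]  # type: ignore[return-value]


def _data_lines(path: Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_entity_list(path: str | Path) -> tuple[str, ...]:
    ids = []
    for lineno, line in _data_lines(Path(path)):
        ids.append(line.strip())
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate ids in entity list")
    return tuple(ids)


def write_entity_list(path: str | Path, ids: Sequence[str]) -> None:
    Path(path).write_text("".join(f"{e}\n" for e in ids))


def _read_pairs(path: Path) -> list[tuple[int, str, str]]:
    rows = []
    for lineno, line in _data_lines(path):
        cols = [c.strip() for c in line.split("\t")]
        if len(cols) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns, "
                             f"got {len(cols)}")
        rows.append((lineno, cols[0], cols[1]))
    return rows


def read_edge_list(path: str | Path, index: EntityIndex, kind: str) -> np.ndarray:
    """Binary association block sized by the entity index.

    ``kind`` selects (row, column) classes: ``ld`` lncRNA×disease,
    ``lm`` lncRNA×miRNA, ``md`` miRNA×disease.  Duplicate edges collapse
    to 1 with a warning; unknown ids are errors naming the line.
    """
    row_map, col_map = index.maps_for(kind)
    block = np.zeros((len(row_map), len(col_map)))
    rows = _read_pairs(Path(path))
    # a single leading header line is tolerated when its ids are unknown
    if rows and (rows[0][1] not in row_map and rows[0][2] not in col_map):
        rows = rows[1:]
    for lineno, a, b in rows:
        if a not in row_map:
            raise ParseError(f"{path}:{lineno}: unknown id {a!r}")
        if b not in col_map:
            raise ParseError(f"{path}:{lineno}: unknown id {b!r}")
        if block[row_map[a], col_map[b]] == 1:
            logger.warning("%s:%d: duplicate edge (%s, %s) collapsed", path, lineno, a, b)
        block[row_map[a], col_map[b]] = 1.0
    return block


def write_edge_list(
    path: str | Path, block: np.ndarray, row_ids: Sequence[str], col_ids: Sequence[str]
) -> None:
    block = np.asarray(block)
    with open(path, "w") as fh:
        for i, j in np.argwhere(block == 1):
            fh.write(f"{row_ids[i]}\t{col_ids[j]}\n")


def read_ontology(path: str | Path) -> DiseaseOntology:
    """Parent→child TSV into a validated acyclic ontology."""
    rows = _read_pairs(Path(path))
    if rows and rows[0][1:] == ("parent", "child"):
        rows = rows[1:]
    for lineno, parent, child in rows:
        if parent == child:
            raise ParseError(f"{path}:{lineno}: self-edge on {parent!r}")
    return DiseaseOntology([(p, c) for _, p, c in rows])


def write_ontology(path: str | Path, ontology: DiseaseOntology) -> None:
    with open(path, "w") as fh:
        fh.write("parent\tchild\n")
        for parent, child in sorted(ontology.parent_edges):
            fh.write(f"{parent}\t{child}\n")


def read_matrix(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: matrix row and column ids differ")
    return SimilarityMatrix(entity_ids=tuple(df.index), values=df.to_numpy(dtype=float))


def write_matrix(path: str | Path, ids: Sequence[str], values: np.ndarray) -> None:
    pd.DataFrame(values, index=list(ids), columns=list(ids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: kernels, model and protocol knobs."""

    delta: float = 0.5
    threshold: float = 0.5
    negative_ratio: float = 1.0
    model: ModelConfig = ModelConfig()

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValueError(f"delta must be in (0, 1), got {self.delta}")
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")


_SECTIONS = {
    "delta": None,
    "threshold": None,
    "negative_ratio": None,
    "gcn": {"layers": "gcn_layers", "embedding": "embedding",
            "hidden_activation": "gcn_hidden_activation",
            "final_activation": "gcn_final_activation"},
    "transformer": {"heads": "heads", "encoder_layers": "encoder_layers",
                    "ffn_multiplier": "ffn_multiplier",
                    "use_residual": "use_residual", "use_norm": "use_norm",
                    "use_ffn": "use_ffn"},
    "train": {"learning_rate": "learning_rate", "epochs": "epochs",
              "score_clamp": "score_clamp", "dropout": "dropout",
              "weight_decay": "weight_decay", "edge_dropout": "edge_dropout"},
}


def load_config(path: str | Path | None = None) -> RunConfig:
    """YAML config with defaults; unknown keys are rejected by name."""
    raw = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        raw = loaded if loaded is not None else {}
        if not isinstance(raw, dict):
            raise ParseError(f"{path}: config must be a mapping")

    top = {}
    model_kwargs = {}
    for key, value in raw.items():
        if key not in _SECTIONS:
            raise ValueError(f"unknown config key {key!r}")
        mapping = _SECTIONS[key]
        if mapping is None:
            top[key] = value
            continue
        if not isinstance(value, dict):
            raise ValueError(f"config section {key!r} must be a mapping")
        for sub, sub_value in value.items():
            if sub not in mapping:
                raise ValueError(f"unknown config key {key}.{sub!r}")
            model_kwargs[mapping[sub]] = sub_value
    try:
        config = RunConfig(model=ModelConfig(**model_kwargs), **top)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
    logger.info("configuration: %s", config)
    return config


def write_manifest(path: str | Path, **entries) -> None:
    """JSON manifest (config echo, seeds, versions) for regenerability."""
    import numpy

    def _clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return _clean(dataclasses.asdict(obj))
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj

    payload = {"numpy_version": numpy.__version__, **{k: _clean(v) for k, v in entries.items()}}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
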