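"""GCN node encoder and transformer pair classifier.

The encoder stacks graph-convolution layers

    H_{l+1} = activation( X~ · H_l · W_l ),

starting from the row-normalised feature matrix, where X~ is the
symmetric-Laplacian-normalised adjacency with self-loops.  Hidden
layers use ReLU; the final layer's activation is configurable
(``relu`` by default — a literal row softmax over the embedding
dimension flattens node representations and stops learning, so it is
kept only as an optional reading of the propagation rule).

Each candidate (lncRNA, disease) pair becomes a two-token sequence
[z_lnc, z_dis] fed through a transformer encoder: multi-head scaled
dot-product attention, residual Add & LayerNorm, and a ReLU
feed-forward block.  The two output tokens are concatenated and mapped
by a sigmoid-activated linear head to an association score in (0, 1);
training minimises mean binary cross-entropy with Adam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .graph import NormalizedGraph
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "PairBatch",
    "GCNTransformer",
    "gcn_layer",
    "encode_nodes",
    "multihead_attention",
    "add_and_norm",
    "feed_forward",
    "bce_loss",
    "train_model",
    "TrainingDiverged",
]

_ACTIVATIONS = ("relu", "softmax", "identity")


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the encoder/classifier stack."""

    gcn_layers: int = 2
    embedding: int = 128
    gcn_hidden_activation: str = "relu"
    gcn_final_activation: str = "relu"
    heads: int = 4
    encoder_layers: int = 2
    ffn_multiplier: int = 4
    layer_norm_eps: float = 1e-5
    use_residual: bool = True
    use_norm: bool = True
    use_ffn: bool = True
    learning_rate: float = 1e-3
    epochs: int = 200
    score_clamp: float = 1e-7
    dropout: float = 0.4
    weight_decay: float = 0.01
    edge_dropout: float = 0.3

    def __post_init__(self) -> None:
        if self.gcn_layers < 1:
            raise ValueError("gcn_layers must be >= 1")
        if self.embedding < 1:
            raise ValueError("embedding size must be >= 1")
        if self.embedding % self.heads != 0:
            raise ValueError(
                f"head count {self.heads} must divide embedding size {self.embedding}"
            )
        for name in (self.gcn_hidden_activation, self.gcn_final_activation):
            if name not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}; use one of {_ACTIVATIONS}")


@dataclass
class PairBatch:
    """Candidate (lncRNA index, disease index) pairs with binary labels."""

    pairs: np.ndarray  # (B, 2) int
    labels: np.ndarray  # (B,) in {0, 1}
    scores: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=float).ravel()
        if len(self.labels) != len(self.pairs):
            raise ValueError("pairs and labels length mismatch")
        if not np.isin(self.labels, (0.0, 1.0)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.pairs)


def _activate(x: Tensor, name: str) -> Tensor:
    if name == "relu":
        return nn.relu(x)
    if name == "softmax":
        return nn.softmax(x, axis=-1)
    if name == "identity":
        return x
    raise ValueError(f"unknown activation {name!r}")


def gcn_layer(x_tilde, h_in, w, activation: str = "identity") -> Tensor:
    """One graph convolution: activation(X~ · H · W)."""
    x_tilde = x_tilde if isinstance(x_tilde, Tensor) else Tensor(x_tilde)
    h_in = h_in if isinstance(h_in, Tensor) else Tensor(h_in)
    w = w if isinstance(w, Tensor) else Tensor(w)
    if x_tilde.shape[1] != h_in.shape[0] or h_in.shape[1] != w.shape[0]:
        raise ValueError(
            f"non-conformable shapes: X~{x_tilde.shape} H{h_in.shape} W{w.shape}"
        )
    return _activate(nn.matmul(nn.matmul(x_tilde, h_in), w), activation)


def multihead_attention(
    tokens: Tensor,
    head_weights: Sequence[tuple[Tensor, Tensor, Tensor]],
    w_out: Tensor,
    record: list[np.ndarray] | None = None,
) -> Tensor:
    """Scaled dot-product attention per head, concatenated and projected.

    ``tokens`` has shape (..., T, D).  Each head owns (w_q, w_k, w_v)
    projections D×p; head outputs are concatenated on the feature axis
    and mapped by ``w_out``.  If ``record`` is given, each head's
    attention-weight array is appended to it (rows sum to 1).
    """
    outputs = []
    for w_q, w_k, w_v in head_weights:
        q = nn.matmul(tokens, w_q)
        k = nn.matmul(tokens, w_k)
        v = nn.matmul(tokens, w_v)
        scale = 1.0 / math.sqrt(w_k.shape[1])
        scores = nn.mul(nn.matmul(q, nn.swap_last_axes(k)), Tensor(scale))
        weights = nn.softmax(scores, axis=-1)
        if record is not None:
            record.append(weights.data.copy())
        outputs.append(nn.matmul(weights, v))
    return nn.matmul(nn.concat(outputs, axis=-1), w_out)


def add_and_norm(
    x: Tensor,
    fx: Tensor,
    gain: Tensor,
    bias: Tensor,
    eps: float = 1e-5,
    use_residual: bool = True,
    use_norm: bool = True,
) -> Tensor:
    """LayerNorm(f(x) + x) with learned affine; both stages can be ablated."""
    out = nn.add(fx, x) if use_residual else fx
    if use_norm:
        out = nn.add(nn.mul(nn.layer_norm(out, eps=eps), gain), bias)
    return out


def feed_forward(x: Tensor, w1: Tensor, b1: Tensor, w2: Tensor, b2: Tensor) -> Tensor:
    """ReLU(x·w1 + b1)·w2 + b2."""
    hidden = nn.relu(nn.add(nn.matmul(x, w1), b1))
    return nn.add(nn.matmul(hidden, w2), b2)


def bce_loss(scores: Tensor, labels: np.ndarray, clamp: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy with score clamping away from {0, 1}."""
    y = Tensor(np.asarray(labels, dtype=float))
    p = nn.clip(scores, clamp, 1.0 - clamp)
    pos = nn.mul(y, nn.log(p))
    neg = nn.mul(1.0 - y, nn.log(1.0 - p))
    return -nn.mean(nn.add(pos, neg))


class GCNTransformer:
    """Trainable GCN encoder + transformer pair classifier."""

    def __init__(self, n_total: int, config: ModelConfig, seed: int = 0):
        self.config = config
        self.n_total = n_total
        rng = np.random.default_rng(seed)
        d = config.embedding

        self.gcn_weights: list[Tensor] = []
        in_dim = n_total
        for _ in range(config.gcn_layers):
            self.gcn_weights.append(nn.glorot_uniform(rng, in_dim, d))
            in_dim = d

        p = d // config.heads
        self.encoder: list[dict] = []
        for _ in range(config.encoder_layers):
            layer = {
                "heads": [
                    (
                        nn.glorot_uniform(rng, d, p),
                        nn.glorot_uniform(rng, d, p),
                        nn.glorot_uniform(rng, d, p),
                    )
                    for _ in range(config.heads)
                ],
                "w_out": nn.glorot_uniform(rng, d, d),
                "gain1": Tensor(np.ones(d), requires_grad=True),
                "bias1": Tensor(np.zeros(d), requires_grad=True),
                "w1": nn.glorot_uniform(rng, d, config.ffn_multiplier * d),
                "b1": Tensor(np.zeros(config.ffn_multiplier * d), requires_grad=True),
                "w2": nn.glorot_uniform(rng, config.ffn_multiplier * d, d),
                "b2": Tensor(np.zeros(d), requires_grad=True),
                "gain2": Tensor(np.ones(d), requires_grad=True),
                "bias2": Tensor(np.zeros(d), requires_grad=True),
            }
            self.encoder.append(layer)

        self.head_w = nn.glorot_uniform(rng, 2 * d, 1)
        self.head_b = Tensor(np.zeros(1), requires_grad=True)
        self.last_attention: list[np.ndarray] = []
        self._drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    def _dropout(self, x: Tensor, training: bool) -> Tensor:
        p = self.config.dropout
        if not training or p <= 0:
            return x
        mask = (self._drop_rng.random(x.shape) >= p) / (1.0 - p)
        return nn.mul(x, Tensor(mask))

    # -- parameter plumbing -------------------------------------------

    def parameters(self) -> list[Tensor]:
        params = list(self.gcn_weights)
        for layer in self.encoder:
            for triple in layer["heads"]:
                params.extend(triple)
            params.extend(
                layer[k]
                for k in ("w_out", "gain1", "bias1", "w1", "b1", "w2", "b2", "gain2", "bias2")
            )
        params.extend([self.head_w, self.head_b])
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[f"param_{i}"]

    # -- forward passes ------------------------------------------------

    def encode(self, norm: NormalizedGraph) -> Tensor:
        cfg = self.config
        h: Tensor | np.ndarray = norm.x_feature
        for i, w in enumerate(self.gcn_weights):
            last = i == len(self.gcn_weights) - 1
            act = cfg.gcn_final_activation if last else cfg.gcn_hidden_activation
            h = gcn_layer(norm.x_tilde, h, w, activation=act)
        return h

    def _encode_tokens(self, tokens: Tensor, training: bool = False) -> Tensor:
        cfg = self.config
        self.last_attention = []
        for layer in self.encoder:
            attended = multihead_attention(
                tokens, layer["heads"], layer["w_out"], record=self.last_attention
            )
            tokens = add_and_norm(
                tokens, self._dropout(attended, training),
                layer["gain1"], layer["bias1"],
                eps=cfg.layer_norm_eps,
                use_residual=cfg.use_residual, use_norm=cfg.use_norm,
            )
            if cfg.use_ffn:
                ff = feed_forward(
                    tokens, layer["w1"], layer["b1"], layer["w2"], layer["b2"]
                )
                tokens = add_and_norm(
                    tokens, self._dropout(ff, training),
                    layer["gain2"], layer["bias2"],
                    eps=cfg.layer_norm_eps,
                    use_residual=cfg.use_residual, use_norm=cfg.use_norm,
                )
        return tokens

    def score_pairs(self, norm: NormalizedGraph, batch: PairBatch,
                    n_lnc: int, training: bool = False) -> Tensor:
        """Score (lncRNA, disease) pairs; returns a (B,) tensor in (0, 1)."""
        if (batch.pairs[:, 0] >= n_lnc).any() or (batch.pairs[:, 0] < 0).any():
            raise IndexError("lncRNA index out of range")
        if (batch.pairs[:, 1] >= self.n_total - n_lnc).any() or (batch.pairs[:, 1] < 0).any():
            raise IndexError("disease index out of range")
        emb = self.encode(norm)
        node_idx = np.stack(
            [batch.pairs[:, 0], n_lnc + batch.pairs[:, 1]], axis=1
        )  # (B, 2) rows into the [lnc, dis, mir] node order
        tokens = nn.gather_rows(emb, node_idx)  # (B, 2, D)
        encoded = self._encode_tokens(tokens, training=training)
        flat = nn.reshape(encoded, (len(batch), 2 * self.config.embedding))
        logits = nn.add(nn.matmul(flat, self.head_w), self.head_b)
        return nn.sigmoid(nn.reshape(logits, (len(batch),)))


def encode_nodes(norm: NormalizedGraph, model: GCNTransformer) -> np.ndarray:
    """Node embedding matrix (N_t × n) from the trained GCN encoder."""
    return model.encode(norm).data


def train_model(
    norm: NormalizedGraph,
    train_batch: PairBatch,
    config: ModelConfig,
    n_lnc: int,
    seed: int = 0,
    graph=None,
) -> tuple[GCNTransformer, list[float]]:
    """Fit the model with full-batch Adam; returns (model, loss trace).

    Fully reproducible given (seed, config, data).  Aborts with
    :class:`TrainingDiverged` if the loss becomes non-finite.

    With ``config.edge_dropout > 0`` (requires ``graph``), a fresh
    random fraction of known association edges is dropped from the
    adjacency every epoch before renormalisation, so the classifier
    cannot rely on reading a pair's own edge out of the graph and must
    learn from indirect paths — the regime it faces on held-out pairs.
    """
    from .graph import normalize_graph  # local import avoids a cycle

    model = GCNTransformer(norm.x_tilde.shape[0], config, seed=seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    if config.edge_dropout > 0 and graph is None:
        raise ValueError("edge_dropout requires the heterogeneous graph")
    edge_rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    trace: list[float] = []
    for epoch in range(config.epochs):
        epoch_norm = norm
        if config.edge_dropout > 0:
            keep = edge_rng.random(graph.Z_ld.shape) >= config.edge_dropout
            dropped = graph.__class__(**{
                **{f: getattr(graph, f) for f in (
                    "lnc_ids", "dis_ids", "mir_ids",
                    "S_ll", "S_dd", "S_mm", "Z_lm", "Z_md")},
                "Z_ld": graph.Z_ld * keep,
            })
            epoch_norm = normalize_graph(dropped)
        opt.zero_grad()
        scores = model.score_pairs(epoch_norm, train_batch, n_lnc, training=True)
        loss = bce_loss(scores, train_batch.labels, clamp=config.score_clamp)
        value = float(loss.data)
        if not np.isfinite(value):
            raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
        trace.append(value)
        loss.backward()
        opt.step()
    return model, trace
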