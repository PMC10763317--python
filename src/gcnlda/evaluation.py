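"""Evaluation protocol: negative sampling, cross-validation, metrics.

The protocol holds out 20% of labeled pairs as a test set, splits the
remaining 80% into five stratified folds, and for each fold trains on
the other four with the fold's (and the test set's) positive edges
masked out of the lncRNA-disease association block, so the model never
sees an edge it is evaluated on.  Metrics: AUC, AUPR, accuracy, F1,
Matthews correlation, precision and recall at a fixed threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .graph import HeterogeneousGraph, mask_fold_edges, normalize_graph
from .model import ModelConfig, PairBatch, train_model
from .similarity import SimilarityMatrix, functional_similarity_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "CVPlan",
    "MetricsReport",
    "sample_negatives",
    "make_cv_plan",
    "make_cv_plans",
    "confusion_at_threshold",
    "compute_metrics",
    "roc_auc",
    "aupr",
    "score_metrics",
    "run_cross_validation",
    "equal_variance_t_test",
    "run_ablation",
    "run_parameter_sweep",
]

METRIC_NAMES = ("auc", "aupr", "acc", "f1", "mcc", "precision", "recall")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class CVPlan:
    """20% held-out test pairs plus five stratified folds over the rest."""

    test_pairs: np.ndarray  # (n_test, 2)
    test_labels: np.ndarray
    folds: tuple[np.ndarray, ...]  # index arrays into cv_pairs
    cv_pairs: np.ndarray
    cv_labels: np.ndarray
    seed: int

    def fold_batch(self, k: int) -> PairBatch:
        idx = self.folds[k]
        return PairBatch(self.cv_pairs[idx], self.cv_labels[idx])

    def train_batch(self, k: int) -> PairBatch:
        idx = np.concatenate([f for i, f in enumerate(self.folds) if i != k])
        return PairBatch(self.cv_pairs[idx], self.cv_labels[idx])


@dataclass(frozen=True)
class MetricsReport:
    """Per-fold metrics, their mean, and the final test-set evaluation."""

    folds: tuple[dict, ...]
    mean: dict
    test: dict | None
    threshold: float


def sample_negatives(
    known_positives: set[tuple[int, int]],
    n_lnc: int,
    n_dis: int,
    n: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Uniformly sample unknown (lncRNA, disease) pairs without replacement."""
    n = len(known_positives) if n is None else n
    universe = n_lnc * n_dis
    available = universe - len(known_positives)
    if n > available:
        raise ValueError(f"requested {n} negatives but only {available} unknown pairs")
    pos_flat = {li * n_dis + di for li, di in known_positives}
    candidates = np.setdiff1d(
        np.arange(universe), np.fromiter(pos_flat, dtype=int, count=len(pos_flat)),
        assume_unique=True,
    )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n, replace=False)
    return np.stack([chosen // n_dis, chosen % n_dis], axis=1)


def _stratified_split(labels: np.ndarray, fractions: int, rng: np.random.Generator):
    """Partition indices into `fractions` near-equal label-stratified parts.

    Per class the part sizes differ by at most one; each class's
    remainder items go to the currently smallest parts, so total part
    sizes also differ by at most one.
    """
    parts: list[list[int]] = [[] for _ in range(fractions)]
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        base, rem = divmod(len(idx), fractions)
        sizes = np.array([len(p) for p in parts])
        counts = np.full(fractions, base)
        counts[np.argsort(sizes, kind="stable")[:rem]] += 1
        start = 0
        for i in range(fractions):
            parts[i].extend(idx[start : start + counts[i]].tolist())
            start += counts[i]
    return [np.asarray(sorted(p), dtype=int) for p in parts]


def make_cv_plan(
    pairs: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_folds: int = 5,
    test_fraction: float = 0.2,
) -> CVPlan:
    """Stratified 20% test split and five-fold partition of the rest."""
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    labels = np.asarray(labels, dtype=int).ravel()
    if len(pairs) < 10:
        raise ValueError("need at least 10 labeled pairs for the CV protocol")
    for cls in (0, 1):
        if (labels == cls).sum() < n_folds:
            raise ValueError(f"too few samples of class {cls} for {n_folds} folds")
    rng = np.random.default_rng(seed)
    n_test_parts = round(1 / test_fraction)
    test_idx, *rest = _stratified_split(labels, n_test_parts, rng)
    cv_idx = np.concatenate(rest)
    folds = _stratified_split(labels[cv_idx], n_folds, rng)
    return CVPlan(
        test_pairs=pairs[test_idx],
        test_labels=labels[test_idx],
        folds=tuple(folds),
        cv_pairs=pairs[cv_idx],
        cv_labels=labels[cv_idx],
        seed=seed,
    )


def make_cv_plans(
    pairs: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_repeats: int = 10,
    n_folds: int = 5,
    test_fraction: float = 0.2,
) -> list[CVPlan]:
    """Independent repeats of the split protocol (10 by default)."""
    return [
        make_cv_plan(pairs, labels, seed=seed + r, n_folds=n_folds,
                     test_fraction=test_fraction)
        for r in range(n_repeats)
    ]


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if scores.size == 0:
        raise ValueError("empty score array")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def _guarded(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("metric %s has zero denominator; reporting 0", name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> dict:
    """Precision, recall, accuracy, F1 and Matthews correlation."""
    precision = _guarded(c.tp, c.tp + c.fp, "precision")
    recall = _guarded(c.tp, c.tp + c.fn, "recall")
    acc = _guarded(c.tp + c.tn, c.total, "acc")
    f1 = _guarded(2 * precision * recall, precision + recall, "f1")
    mcc_den = np.sqrt(
        float(c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _guarded(c.tp * c.tn - c.fp * c.fn, mcc_den, "mcc")
    return {
        "precision": precision,
        "recall": recall,
        "acc": acc,
        "f1": f1,
        "mcc": mcc,
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (equals the Mann-Whitney statistic)."""
    labels = np.asarray(labels, dtype=int).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float).ravel()))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under precision-recall by descending-score step integration."""
    labels = np.asarray(labels, dtype=int).ravel()
    if (labels == 1).sum() == 0:
        raise ValueError("aupr needs at least one positive label")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float).ravel()))


def score_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict:
    """Full metric dictionary for one scored set."""
    out = {"auc": roc_auc(scores, labels), "aupr": aupr(scores, labels)}
    out.update(compute_metrics(confusion_at_threshold(scores, labels, threshold)))
    return out


def equal_variance_t_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-tailed pooled-variance Student t-test."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# cross-validated training


def _masked_normalized(
    graph: HeterogeneousGraph,
    held_out: np.ndarray,
    refit_similarity: bool = False,
):
    positives = [tuple(p) for p in np.asarray(held_out, dtype=int)]
    masked = mask_fold_edges(graph, positives)
    if refit_similarity:
        masked = _refit_functional_blocks(masked)
    return masked, normalize_graph(masked)


def _refit_functional_blocks(g: HeterogeneousGraph) -> HeterogeneousGraph:
    """Recompute lncRNA/miRNA functional similarity from the masked Z_ld."""
    ds = SimilarityMatrix(entity_ids=g.dis_ids, values=g.S_dd)
    lnc_map = {
        l: {g.dis_ids[j] for j in np.flatnonzero(g.Z_ld[i])}
        for i, l in enumerate(g.lnc_ids)
    }
    s_ll = functional_similarity_matrix(lnc_map, ds, entity_order=g.lnc_ids)
    return replace(g, S_ll=s_ll.values)


def run_cross_validation(
    graph: HeterogeneousGraph,
    pairs: np.ndarray,
    labels: np.ndarray,
    model_config: ModelConfig,
    plan: CVPlan,
    threshold: float = 0.5,
    mask: bool = True,
    refit_similarity: bool = False,
    evaluate_test: bool = True,
) -> MetricsReport:
    """Train/evaluate per fold with leak-free masking; mean over folds.

    For fold k the positives of fold k *and* of the held-out test set
    are removed from the association block before normalisation and
    training on the remaining four folds.  The final test evaluation
    trains on all five folds with only test positives masked.
    """
    fold_metrics = []
    test_pos = plan.test_pairs[plan.test_labels == 1]
    for k in range(len(plan.folds)):
        val = plan.fold_batch(k)
        train = plan.train_batch(k)
        if mask:
            val_pos = val.pairs[val.labels == 1]
            held = np.concatenate([val_pos, test_pos]) if len(test_pos) else val_pos
            fold_graph, norm = _masked_normalized(graph, held, refit_similarity)
        else:
            fold_graph, norm = graph, normalize_graph(graph)
        model, _ = train_model(
            norm, train, model_config, n_lnc=graph.n_lnc, seed=plan.seed + k,
            graph=fold_graph,
        )
        scores = model.score_pairs(norm, val, graph.n_lnc).data
        fold_metrics.append(score_metrics(scores, val.labels, threshold))
        logger.info("fold %d: %s", k, fold_metrics[-1])

    mean = {k: float(np.mean([m[k] for m in fold_metrics])) for k in METRIC_NAMES}

    test_result = None
    if evaluate_test and len(plan.test_pairs):
        if mask:
            test_graph, norm = _masked_normalized(graph, test_pos, refit_similarity)
        else:
            test_graph, norm = graph, normalize_graph(graph)
        full_train = PairBatch(plan.cv_pairs, plan.cv_labels)
        model, _ = train_model(
            norm, full_train, model_config, n_lnc=graph.n_lnc, seed=plan.seed + 100,
            graph=test_graph,
        )
        test_scores = model.score_pairs(
            norm, PairBatch(plan.test_pairs, plan.test_labels), graph.n_lnc
        ).data
        test_result = score_metrics(test_scores, plan.test_labels, threshold)

    return MetricsReport(
        folds=tuple(fold_metrics), mean=mean, test=test_result, threshold=threshold
    )


# ---------------------------------------------------------------------------
# ablation and hyperparameter sweep harnesses


def run_ablation(
    graph: HeterogeneousGraph,
    pairs: np.ndarray,
    labels: np.ndarray,
    model_config: ModelConfig,
    seed: int = 0,
    evaluate_test: bool = False,
) -> dict[str, list[dict]]:
    """Graph-block and transformer-module ablations.

    Returns two tables: ``graph`` rows toggle the interclass (Z) and
    intraclass (S) blocks; ``transformer`` rows toggle the residual
    Add, the LayerNorm and the feed-forward network.
    """
    plan = make_cv_plan(pairs, labels, seed=seed)

    def _evaluate(g: HeterogeneousGraph, cfg: ModelConfig) -> dict:
        rep = run_cross_validation(
            g, pairs, labels, cfg, plan, evaluate_test=evaluate_test
        )
        return {"auc": rep.mean["auc"], "aupr": rep.mean["aupr"]}

    eye = np.eye
    z_only = replace(
        graph,
        S_ll=eye(graph.n_lnc), S_dd=eye(graph.n_dis), S_mm=eye(graph.n_mir),
    )
    s_only = replace(
        graph,
        Z_ld=np.zeros_like(graph.Z_ld),
        Z_lm=np.zeros_like(graph.Z_lm),
        Z_md=np.zeros_like(graph.Z_md),
    )
    graph_rows = [
        {"interclass_Z": True, "intraclass_S": False, **_evaluate(z_only, model_config)},
        {"interclass_Z": False, "intraclass_S": True, **_evaluate(s_only, model_config)},
        {"interclass_Z": True, "intraclass_S": True, **_evaluate(graph, model_config)},
    ]

    transformer_rows = []
    for add_on, norm_on, ffn_on in [
        (False, True, True), (True, False, True), (True, True, False), (True, True, True)
    ]:
        cfg = replace(
            model_config, use_residual=add_on, use_norm=norm_on, use_ffn=ffn_on
        )
        transformer_rows.append(
            {"add": add_on, "norm": norm_on, "ffn": ffn_on, **_evaluate(graph, cfg)}
        )
    return {"graph": graph_rows, "transformer": transformer_rows}


def run_parameter_sweep(
    graph: HeterogeneousGraph,
    pairs: np.ndarray,
    labels: np.ndarray,
    base_config: ModelConfig,
    layer_counts: list[int],
    embedding_sizes: list[int],
    seed: int = 0,
) -> list[dict]:
    """AUC grid over GCN layer counts and embedding sizes."""
    plan = make_cv_plan(pairs, labels, seed=seed)
    rows = []
    for layers in layer_counts:
        for size in embedding_sizes:
            cfg = replace(base_config, gcn_layers=layers, embedding=size)
            rep = run_cross_validation(
                graph, pairs, labels, cfg, plan, evaluate_test=False
            )
            rows.append(
                {"gcn_layers": layers, "embedding": size,
                 "auc": rep.mean["auc"], "aupr": rep.mean["aupr"]}
            )
    return rows
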