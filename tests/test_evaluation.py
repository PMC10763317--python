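"""Metric formulas, CV protocol invariants and the comparison t-test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from gcnlda import (
    ConfusionCounts,
    ModelConfig,
    aupr,
    compute_metrics,
    confusion_at_threshold,
    equal_variance_t_test,
    make_cv_plan,
    roc_auc,
    run_ablation,
    run_cross_validation,
    run_parameter_sweep,
    sample_negatives,
)


def mann_whitney_auc(scores, labels):
    """Concordant-pair counting oracle with ties worth one half."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestSampleNegatives:
    def test_matches_positive_count_by_default(self):
        pos = {(0, 0), (1, 1), (2, 2)}
        neg = sample_negatives(pos, 5, 5, seed=0)
        assert len(neg) == len(pos)

    def test_disjoint_from_positives(self):
        pos = {(i, j) for i in range(4) for j in range(4) if (i + j) % 2 == 0}
        neg = sample_negatives(pos, 4, 4, n=5, seed=1)
        assert {tuple(p) for p in neg}.isdisjoint(pos)

    def test_reproducible_given_seed(self):
        pos = {(0, 1)}
        a = sample_negatives(pos, 10, 10, seed=42)
        b = sample_negatives(pos, 10, 10, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_oversampling_rejected_with_available_count(self):
        with pytest.raises(ValueError, match="3"):
            sample_negatives({(0, 0)}, 2, 2, n=4, seed=0)


class TestCVPlan:
    def _pairs(self, n):
        pairs = np.stack([np.arange(n), np.arange(n)], axis=1)
        labels = np.tile([1, 0], n // 2)
        return pairs, labels

    def test_stated_proportions_for_200_pairs(self):
        pairs, labels = self._pairs(200)
        plan = make_cv_plan(pairs, labels, seed=0)
        assert len(plan.test_pairs) == 40
        assert len(plan.cv_pairs) == 160
        assert all(len(f) == 32 for f in plan.folds)

    def test_folds_partition_cv_split(self):
        pairs, labels = self._pairs(120)
        plan = make_cv_plan(pairs, labels, seed=3)
        all_idx = np.concatenate(plan.folds)
        assert len(all_idx) == len(plan.cv_pairs)
        assert len(np.unique(all_idx)) == len(all_idx)

    def test_partition_invariants_over_many_seeds(self):
        rng = np.random.default_rng(0)
        for seed in range(100):
            n = int(rng.integers(40, 200))
            pairs = np.stack([np.arange(n), np.arange(n)], axis=1)
            labels = (np.arange(n) < n // 2).astype(int)
            plan = make_cv_plan(pairs, labels, seed=seed)
            test_set = {tuple(p) for p in plan.test_pairs}
            cv_set = {tuple(p) for p in plan.cv_pairs}
            assert test_set.isdisjoint(cv_set)
            sizes = [len(f) for f in plan.folds]
            assert max(sizes) - min(sizes) <= 1
            for fold in plan.folds:
                fold_labels = plan.cv_labels[fold]
                others = [f for f in plan.folds if f is not fold]
                for other in others:
                    assert set(fold) .isdisjoint(set(other))
                # class balance within +-1 of the proportional share
                expected = fold_labels.size * plan.cv_labels.mean()
                assert abs(fold_labels.sum() - expected) <= 1 + 1e-9

    def test_seed_controls_plan(self):
        pairs, labels = self._pairs(60)
        p1 = make_cv_plan(pairs, labels, seed=1)
        p2 = make_cv_plan(pairs, labels, seed=1)
        p3 = make_cv_plan(pairs, labels, seed=2)
        np.testing.assert_array_equal(p1.test_pairs, p2.test_pairs)
        assert not np.array_equal(p1.test_pairs, p3.test_pairs)

    def test_too_few_pairs_rejected(self):
        pairs, labels = self._pairs(8)
        with pytest.raises(ValueError, match="at least 10"):
            make_cv_plan(pairs, labels, seed=0)


class TestConfusionAndMetrics:
    def test_perfect_scores(self):
        c = confusion_at_threshold([0.9, 0.8, 0.1], [1, 1, 0])
        assert (c.fp, c.fn) == (0, 0)

    def test_all_below_threshold(self):
        c = confusion_at_threshold([0.1, 0.2], [1, 1])
        assert (c.tp, c.fn) == (0, 2)

    def test_mixed_hand_case(self):
        c = confusion_at_threshold([0.9, 0.6, 0.4, 0.1], [1, 0, 1, 0], 0.5)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_at_threshold([], [])

    def test_hand_derived_metric_values(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["acc"] == pytest.approx(0.8)
        assert m["f1"] == pytest.approx(0.75)
        assert m["mcc"] == pytest.approx(14 / 24)

    def test_degenerate_all_tp_guarded(self):
        m = compute_metrics(ConfusionCounts(tp=4, fp=0, tn=0, fn=0))
        assert m["precision"] == 1 and m["recall"] == 1 and m["acc"] == 1
        assert m["mcc"] == 0.0  # undefined denominator guarded to 0

    def test_matches_formula_oracle_on_all_small_grids(self):
        """Exhaustive agreement with direct formula evaluation, total <= 20."""
        for tp, fp, tn, fn in itertools.product(range(8), repeat=4):
            if tp + fp + tn + fn == 0 or tp + fp + tn + fn > 20:
                continue
            m = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            acc = (tp + tn) / (tp + fp + tn + fn)
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            den = np.sqrt(float(tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
            mcc = (tp * tn - fp * fn) / den if den else 0.0
            assert m["precision"] == pytest.approx(prec)
            assert m["recall"] == pytest.approx(rec)
            assert m["acc"] == pytest.approx(acc)
            assert m["f1"] == pytest.approx(f1)
            assert m["mcc"] == pytest.approx(mcc)


class TestRankingMetrics:
    def test_perfect_and_inverted_auc(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_hand_counted_auc(self):
        assert roc_auc([0.8, 0.6, 0.4, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_auc([0.5, 0.6], [1, 1])

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert roc_auc(scores, labels) == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-9
            )

    def test_aupr_step_integration_hand_case(self):
        assert aupr([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(0.5 + 0.5 * 2 / 3)

    def test_aupr_perfect_and_all_positive(self):
        assert aupr([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0
        assert aupr([0.5, 0.2], [1, 1]) == 1.0

    def test_aupr_without_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            aupr([0.5], [0])

    def test_random_scores_near_half_auc(self):
        rng = np.random.default_rng(123)
        labels = rng.integers(0, 2, size=10_000)
        scores = rng.random(10_000)
        assert 0.45 <= roc_auc(scores, labels) <= 0.55


class TestTTest:
    def test_identical_samples(self):
        t, p = equal_variance_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_hand_derived_case(self):
        t, p = equal_variance_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=1e-3)
        # cross-check against the pooled-variance closed form
        sp2 = (2 * 1 + 2 * 1) / 4
        expected_t = (2 - 5) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(expected_t, rel=1e-9)
        assert p == pytest.approx(2 * stats.t.sf(abs(expected_t), df=4), rel=1e-9)

    def test_swap_negates_t_keeps_p(self):
        t1, p1 = equal_variance_t_test([1, 2, 3], [2, 4, 9])
        t2, p2 = equal_variance_t_test([2, 4, 9], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            equal_variance_t_test([1.0], [2.0, 3.0])


class TestCrossValidationProtocol:
    def test_report_shape_and_masking(self, small_graph, small_labeled, tiny_config):
        pairs, labels = small_labeled
        plan = make_cv_plan(pairs, labels, seed=5)
        report = run_cross_validation(small_graph, pairs, labels, tiny_config,
                                      plan, evaluate_test=True)
        assert len(report.folds) == 5
        assert set(report.mean) >= {"auc", "aupr", "acc", "f1", "mcc"}
        assert report.test is not None

    def test_fixed_seed_bitwise_reproducible(self, small_graph, small_labeled, tiny_config):
        pairs, labels = small_labeled
        plan = make_cv_plan(pairs, labels, seed=6)
        r1 = run_cross_validation(small_graph, pairs, labels, tiny_config, plan,
                                  evaluate_test=False)
        r2 = run_cross_validation(small_graph, pairs, labels, tiny_config, plan,
                                  evaluate_test=False)
        assert r1.folds == r2.folds

    def test_masked_graph_contains_no_heldout_positive(self, small_graph, small_labeled):
        from gcnlda.graph import mask_fold_edges
        pairs, labels = small_labeled
        plan = make_cv_plan(pairs, labels, seed=7)
        test_pos = plan.test_pairs[plan.test_labels == 1]
        for k in range(5):
            val = plan.fold_batch(k)
            val_pos = val.pairs[val.labels == 1]
            held = np.concatenate([val_pos, test_pos])
            masked = mask_fold_edges(small_graph, [tuple(p) for p in held])
            assert masked.Z_ld[held[:, 0], held[:, 1]].sum() == 0


class TestHarnesses:
    def test_ablation_tables_have_expected_rows(self, small_graph, small_labeled, tiny_config):
        pairs, labels = small_labeled
        tables = run_ablation(small_graph, pairs, labels, tiny_config, seed=0)
        graph_rows = tables["graph"]
        assert [(r["interclass_Z"], r["intraclass_S"]) for r in graph_rows] == [
            (True, False), (False, True), (True, True)
        ]
        tf_rows = tables["transformer"]
        assert [(r["add"], r["norm"], r["ffn"]) for r in tf_rows] == [
            (False, True, True), (True, False, True), (True, True, False),
            (True, True, True),
        ]
        for row in graph_rows + tf_rows:
            assert 0 <= row["auc"] <= 1 and 0 <= row["aupr"] <= 1

    def test_sweep_emits_full_grid(self, small_graph, small_labeled, tiny_config):
        pairs, labels = small_labeled
        rows = run_parameter_sweep(small_graph, pairs, labels, tiny_config,
                                   layer_counts=[1, 2], embedding_sizes=[8, 16],
                                   seed=0)
        assert {(r["gcn_layers"], r["embedding"]) for r in rows} == {
            (1, 8), (1, 16), (2, 8), (2, 16)
        }
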