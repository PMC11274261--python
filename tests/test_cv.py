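"""Cross-validation protocol: stratified folds, schedule, metric formulas
(against brute-force oracles), early stopping and seeded training."""

import math

import numpy as np
import pytest

from dmfnet.augment import AugmentPolicy, augment_offline
from dmfnet.cv import (ConfusionCounts, TrainConfig, compute_metrics,
                       confusion_from_scores, early_stop_epoch, lr_schedule,
                       predict, roc_auc, roc_points, stratified_kfold,
                       train_fold)
from dmfnet.model import ModelConfig
from dmfnet.synthetic import CohortSpec, generate_cohort_memory
from dmfnet.types import CohortManifest, MultiViewRecord, ViewRole


def label_manifest(labels):
    img = np.zeros((4, 4), dtype=np.uint8)
    return CohortManifest([
        MultiViewRecord(f"s{i:04d}", int(y), {r: img for r in ViewRole.ordered()})
        for i, y in enumerate(labels)])


class TestStratifiedKFold:
    def test_cohort_fold_arithmetic(self):
        man = label_manifest([1] * 25 + [0] * 200)
        split = stratified_kfold(man, k=5, seed=0)
        labels = {r.subject_id: r.label for r in man.records}
        for fold in range(5):
            sids = split.fold_subjects(fold)
            assert len(sids) == 45
            pos = sum(labels[s] for s in sids)
            assert (pos, 45 - pos) == (5, 40)
        assert len(man) - len(split.fold_subjects(0)) == 180

    def test_partition_property(self):
        man = label_manifest([0, 1] * 20 + [0] * 13)
        split = stratified_kfold(man, k=5, seed=3)
        all_ids = [s for f in range(5) for s in split.fold_subjects(f)]
        assert sorted(all_ids) == sorted(r.subject_id for r in man.records)
        assert len(set(all_ids)) == len(all_ids)

    def test_minimal_balanced_cohort(self):
        man = label_manifest([0, 1] * 5)
        split = stratified_kfold(man, k=5, seed=1)
        labels = {r.subject_id: r.label for r in man.records}
        for fold in range(5):
            sids = split.fold_subjects(fold)
            assert sorted(labels[s] for s in sids) == [0, 1]

    def test_seed_determinism(self):
        man = label_manifest([0] * 30 + [1] * 10)
        a = stratified_kfold(man, k=5, seed=9).assignments
        b = stratified_kfold(man, k=5, seed=9).assignments
        assert a == b

    def test_class_smaller_than_k_rejected(self):
        man = label_manifest([0] * 20 + [1] * 3)
        with pytest.raises(ValueError, match="fewer than"):
            stratified_kfold(man, k=5, seed=0)


class TestLrSchedule:
    @pytest.mark.parametrize("epoch,lr", [(0, 1e-3), (29, 1e-3), (30, 1e-4),
                                          (60, 1e-5), (95, 1e-6)])
    def test_step_decay(self, epoch, lr):
        assert lr_schedule(epoch, TrainConfig()) == pytest.approx(lr, rel=1e-12)

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            lr_schedule(120, TrainConfig())


class TestMetrics:
    def test_headline_confusion_row(self):
        m = compute_metrics(ConfusionCounts(TP=66, FN=14, TN=121, FP=39))
        assert m.acc == pytest.approx(0.77917, abs=5e-6)
        assert m.spe == pytest.approx(0.75625, abs=5e-6)
        assert m.sen == pytest.approx(0.82500, abs=5e-6)
        assert m.f1 == pytest.approx(0.71351, abs=5e-6)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(TP=5, FN=0, TN=40, FP=0))
        assert (m.acc, m.spe, m.sen, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_true_positives(self):
        m = compute_metrics(ConfusionCounts(TP=0, FN=5, TN=10, FP=2))
        assert m.sen == 0.0 and m.f1 == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_identities_on_random_confusions(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            p_count, n_count = tp + fn, tn + fp
            assert m.acc == pytest.approx(
                (m.sen * p_count + m.spe * n_count) / (p_count + n_count), rel=1e-12)
            precision = tp / (tp + fp) if tp + fp else 0.0
            recall = m.sen
            if precision + recall > 0:
                assert m.f1 == pytest.approx(
                    2 * precision * recall / (precision + recall), rel=1e-9)


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_three_quarters(self):
        assert roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    @pytest.mark.parametrize("n", [10, 57, 200])
    def test_matches_pairwise_oracle_with_ties(self, n):
        rng = np.random.default_rng(n)
        labels = (rng.random(n) < 0.4).astype(int)
        labels[:2] = [0, 1]  # both classes present
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_roc_points_cover_thresholds(self):
        pts = roc_points([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert pts.shape[1] == 3
        tpr, fpr = pts[:, 1], pts[:, 2]
        assert tpr[0] == 0.0 and tpr[-1] == 1.0
        assert (np.diff(tpr) >= 0).all() and (np.diff(fpr) >= 0).all()


class TestConfusionFromScores:
    def test_threshold_half(self):
        counts = confusion_from_scores([0.6, 0.4, 0.5, 0.2], [1, 1, 0, 0])
        assert (counts.TP, counts.FN, counts.FP, counts.TN) == (1, 1, 1, 1)


class TestEarlyStopping:
    def test_patience_rule_on_constructed_sequence(self):
        stop, best = early_stop_epoch([1.0, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9], 5)
        assert (stop, best) == (6, 1)

    def test_improvement_resets_counter(self):
        stop, best = early_stop_epoch([1.0, 0.9, 0.95, 0.8, 0.9, 0.9], 3)
        assert best == 3
        assert stop == len([1.0, 0.9, 0.95, 0.8, 0.9, 0.9]) - 1  # never triggers

    def test_best_is_global_minimum_of_prefix(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            losses = list(rng.random(20))
            stop, best = early_stop_epoch(losses, 4)
            assert losses[best] == min(losses[:stop + 1])


@pytest.fixture(scope="module")
def tiny():
    man, _ = generate_cohort_memory(
        CohortSpec(n_pos=3, n_neg=3, seed=21, class_separation=2.0, image_size=32))
    return man


class TestTraining:

    def test_single_class_training_rejected(self, tiny):
        recs = [r for r in tiny.records if r.label == 0]
        with pytest.raises(ValueError, match="both classes"):
            train_fold(recs, ModelConfig(), TrainConfig(epochs=1, early_stop_patience=1, image_size=32))

    def test_seeded_training_determinism(self, tiny):
        tc = TrainConfig(epochs=2, batch_size=6, seed=5, early_stop_patience=2, image_size=32)
        m1, h1 = train_fold(tiny.records, ModelConfig(seed=1), tc)
        m2, h2 = train_fold(tiny.records, ModelConfig(seed=1), tc)
        assert [h["total"] for h in h1] == [h["total"] for h in h2]
        for (k1, p1), (k2, p2) in zip(m1.named_parameters(), m2.named_parameters()):
            assert k1 == k2
            np.testing.assert_array_equal(p1.data, p2.data)
        s1 = predict(m1, tiny.records, 32)
        s2 = predict(m2, tiny.records, 32)
        np.testing.assert_array_equal(s1, s2)

    def test_history_records_loss_components_and_lr(self, tiny):
        tc = TrainConfig(epochs=2, batch_size=6, seed=5, early_stop_patience=2, image_size=32)
        _, hist = train_fold(tiny.records, ModelConfig(seed=1), tc)
        assert len(hist) == 2
        assert {"total", "classification", "complementarity", "consistency",
                "lr", "epoch"} <= set(hist[0])
        assert hist[0]["lr"] == 1e-3


class TestLeakageGuard:
    def test_augmented_copies_follow_their_source_subject(self):
        man, _ = generate_cohort_memory(
            CohortSpec(n_pos=5, n_neg=10, seed=8, image_size=16))
        aug = augment_offline(man, AugmentPolicy(pos_multiplier=3, neg_multiplier=2, seed=1))
        split = stratified_kfold(man, k=5, seed=0)
        test_ids = set(split.fold_subjects(0))
        train_samples = [r for r in aug.records if r.source_id not in test_ids]
        assert all(r.source_id not in test_ids for r in train_samples)
        # and every test subject's copies were excluded together
        excluded = {r.source_id for r in aug.records if r.source_id in test_ids}
        assert excluded == test_ids
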