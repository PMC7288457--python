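import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from m6acnn.architecture import TrainingConfig
from m6acnn.train_eval import (
    ConfusionMatrix,
    MetricSet,
    compute_metrics,
    confusion_from_scores,
    cross_validate,
    make_folds,
    roc_auc,
    train_fold,
)

# ---------------------------------------------------------------------------
# independent oracles


def metrics_oracle(tp, tn, fp, fn):
    """Literal transcription of the four definitional formulas."""
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return acc, sn, sp, mcc


def concordance_oracle(scores, labels):
    """Mann-Whitney pairwise concordance, ties counted half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_tally(scores, labels, threshold):
    tp = tn = fp = fn = 0
    for s, lab in zip(scores, labels):
        pred = 1 if s >= threshold else 0
        if pred == 1 and lab == 1:
            tp += 1
        elif pred == 0 and lab == 0:
            tn += 1
        elif pred == 1 and lab == 0:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


# ---------------------------------------------------------------------------


class TestMakeFolds:
    def test_benchmark_size_fold_sizes(self):
        labels = np.repeat([0, 1], 1307)
        folds = make_folds(labels, k=10, seed=0)
        sizes = sorted(np.bincount(folds.fold_of, minlength=10), reverse=True)
        assert sizes == [262] * 4 + [261] * 6

    def test_partition(self):
        labels = np.repeat([0, 1], 50)
        folds = make_folds(labels, k=10, seed=1)
        assert np.all((folds.fold_of >= 0) & (folds.fold_of < 10))
        assert len(folds.fold_of) == 100

    def test_stratified_class_balance(self):
        labels = np.repeat([0, 1], 1307)
        folds = make_folds(labels, k=10, seed=2)
        for fold in range(10):
            pos = np.sum(labels[folds.fold_indices(fold)])
            neg = len(folds.fold_indices(fold)) - pos
            assert abs(pos - neg) <= 1

    def test_unstratified_sizes_within_one(self):
        folds = make_folds(np.repeat([0, 1], 1307), k=10, seed=0, stratified=False)
        sizes = np.bincount(folds.fold_of, minlength=10)
        assert sizes.max() - sizes.min() <= 1

    def test_deterministic_and_seed_sensitive(self):
        labels = np.repeat([0, 1], 100)
        a = make_folds(labels, k=10, seed=5)
        b = make_folds(labels, k=10, seed=5)
        c = make_folds(labels, k=10, seed=6)
        assert np.array_equal(a.fold_of, b.fold_of)
        assert not np.array_equal(a.fold_of, c.fold_of)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array([0, 1, 0]), k=10)

    def test_k_below_2_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.repeat([0, 1], 10), k=1)

    def test_rotation_split_disjoint_and_covering(self):
        labels = np.repeat([0, 1], 60)
        folds = make_folds(labels, k=10, seed=3)
        tested = np.zeros(len(labels), dtype=int)
        for t in range(10):
            train, val, test = folds.split(t)
            combined = np.concatenate([train, val, test])
            assert len(combined) == len(labels)
            assert len(np.unique(combined)) == len(labels)
            tested[test] += 1
        assert np.all(tested == 1)


class TestConfusion:
    def test_perfect_scores(self):
        labels = np.array([1, 0, 1, 0])
        cm = confusion_from_scores(labels.astype(float), labels)
        assert (cm.fp, cm.fn) == (0, 0)

    def test_all_zero_scores_balanced(self):
        labels = np.repeat([0, 1], 5)
        cm = confusion_from_scores(np.zeros(10), labels)
        assert (cm.tn, cm.fn, cm.tp, cm.fp) == (5, 5, 0, 0)

    def test_score_range_enforced(self):
        with pytest.raises(ValueError):
            confusion_from_scores(np.array([1.5]), np.array([1]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_from_scores(np.zeros(3), np.zeros(4))

    def test_1000_random_pairs_vs_brute_force(self, rng):
        scores = rng.random(1000)
        labels = rng.integers(0, 2, 1000)
        cm = confusion_from_scores(scores, labels, threshold=0.5)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == brute_force_tally(scores, labels, 0.5)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, tn=0, fp=0, fn=0)


class TestMetrics:
    def test_symmetric_case(self):
        m = compute_metrics(ConfusionMatrix(25, 25, 25, 25))
        assert (m.acc, m.sn, m.sp, m.mcc) == (0.5, 0.5, 0.5, 0.0)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix(50, 50, 0, 0))
        assert (m.acc, m.mcc) == (1.0, 1.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_zero_denominator_mcc_is_zero(self):
        m = compute_metrics(ConfusionMatrix(tp=5, tn=0, fp=5, fn=0))
        assert m.mcc == 0.0

    def test_1000_random_matrices_match_oracle(self, rng):
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 500, 4))
            if tp + tn + fp + fn == 0:
                continue
            m = compute_metrics(ConfusionMatrix(tp, tn, fp, fn))
            acc, sn, sp, mcc = metrics_oracle(tp, tn, fp, fn)
            assert m.acc == pytest.approx(acc, abs=1e-12)
            assert m.sn == pytest.approx(sn, abs=1e-12)
            assert m.sp == pytest.approx(sp, abs=1e-12)
            assert m.mcc == pytest.approx(mcc, abs=1e-12)
            assert -1.0 <= m.mcc <= 1.0

    @settings(max_examples=200)
    @given(counts=st.tuples(*[st.integers(0, 10_000)] * 4))
    def test_mcc_antisymmetric_under_label_flip(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0:
            return
        original = compute_metrics(ConfusionMatrix(tp, tn, fp, fn)).mcc
        # flipping the true labels maps TP->FP, FP->TP, TN->FN, FN->TN
        flipped = compute_metrics(ConfusionMatrix(fp, fn, tp, tn)).mcc
        assert flipped == pytest.approx(-original, abs=1e-12)


class TestRocAuc:
    def test_perfect_scores(self):
        labels = np.array([0, 1, 0, 1, 1])
        _, _, auc = roc_auc(labels.astype(float), labels)
        assert auc == 1.0

    def test_constant_scores(self):
        labels = np.repeat([0, 1], 10)
        _, _, auc = roc_auc(np.full(20, 0.4), labels)
        assert auc == pytest.approx(0.5, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_50_random_sets_match_concordance(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            _, _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(concordance_oracle(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        scores = rng.random(500)
        labels = rng.integers(0, 2, 500)
        _, _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_random_scores_calibrate_to_half(self):
        rng = np.random.default_rng(42)
        aucs = []
        for _ in range(50):
            scores = rng.random(10_000)
            labels = np.repeat([0, 1], 5_000)
            _, _, auc = roc_auc(scores, labels)
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_curve_endpoints(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        fpr, tpr, _ = roc_auc(scores, labels)
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)


@pytest.fixture(scope="module")
def cv_dataset():
    from m6acnn import generate_dataset

    return generate_dataset(150, 150, seed=7)


@pytest.fixture(scope="module")
def cv_result(cv_dataset):
    from m6acnn.architecture import default_model_spec

    cfg = TrainingConfig(epochs=30, early_stop_patience=30, batch_size=16, seed=0)
    return cross_validate(cv_dataset, default_model_spec(), cfg, k=5, seed=0)


class TestCrossValidate:
    def test_mean_is_arithmetic_mean(self, cv_result):
        assert cv_result.mean.acc == pytest.approx(
            np.mean([m.acc for m in cv_result.fold_metrics])
        )
        assert cv_result.mean.mcc == pytest.approx(
            np.mean([m.mcc for m in cv_result.fold_metrics])
        )

    def test_every_record_scored_once(self, cv_result, cv_dataset):
        assert len(cv_result.pooled_scores) == len(cv_dataset)
        assert np.all((cv_result.pooled_scores >= 0) & (cv_result.pooled_scores <= 1))

    def test_learns_planted_motif(self, cv_result):
        assert cv_result.mean.acc >= 0.9
        assert cv_result.pooled_auc >= 0.95

    def test_confusion_totals(self, cv_result, cv_dataset):
        assert sum(cm.total for cm in cv_result.fold_confusions) == len(cv_dataset)

    def test_per_fold_table_has_mean_row(self, cv_result):
        table = cv_result.per_fold_table()
        assert len(table) == 6
        assert table[-1]["fold"] == "mean"


class TestTrainFold:
    def test_empty_sets_rejected(self, tiny_encoded, fast_config):
        from m6acnn.architecture import default_model_spec

        X, y = tiny_encoded
        with pytest.raises(ValueError):
            train_fold(default_model_spec(), fast_config, X[:0], y[:0], X[:5], y[:5])
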