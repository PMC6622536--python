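import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

import roiselect as rs
from roiselect.classify import SplitEvaluator
from roiselect.features import dataset_to_design


def brute_force_ap(scores, targets):
    """Independent oracle: enumerate every distinct threshold, compute
    precision/recall from confusion counts, step-integrate."""
    scores = np.asarray(scores, float)
    targets = np.asarray(targets, int)
    thresholds = sorted(set(scores), reverse=True)
    n_pos = targets.sum()
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        pred = scores >= t
        tp = int(np.sum(pred & (targets == 1)))
        fp = int(np.sum(pred & (targets == 0)))
        prec = 1.0 if tp + fp == 0 else tp / (tp + fp)
        rec = tp / n_pos
        ap += (rec - prev_recall) * prec
        prev_recall = rec
    return ap


class TestPrecisionRecall:
    def test_perfect_predictor(self):
        assert rs.precision(5, 0) == 1.0

    def test_direct_substitution(self):
        assert rs.precision(3, 1) == 0.75
        assert rs.recall(3, 3) == 0.5

    def test_zero_predicted_positives_convention(self):
        assert rs.precision(0, 0) == 1.0

    def test_recall_without_positives_is_error(self):
        with pytest.raises(ValueError, match="no positives"):
            rs.recall(0, 0)


class TestPrAuc:
    def test_perfect_ranking(self):
        assert rs.pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_positive_ranked_last(self):
        assert rs.pr_auc([0.9, 0.1], [0, 1]) == 0.5

    def test_all_positive(self):
        assert rs.pr_auc([0.3, 0.9, 0.1], [1, 1, 1]) == 1.0

    def test_no_positives_is_error(self):
        with pytest.raises(ValueError, match="no positives"):
            rs.pr_auc([0.5, 0.3], [0, 0])

    def test_tied_scores_single_threshold(self):
        # all scores equal: one threshold, precision = prevalence at recall 1
        assert rs.pr_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_against_brute_force_small(self):
        rng = np.random.default_rng(0)
        for n in range(2, 7):
            for _ in range(20):
                scores = rng.choice([0.1, 0.4, 0.4, 0.8], size=n)
                targets = rng.integers(0, 2, n)
                if targets.sum() == 0:
                    targets[0] = 1
                assert rs.pr_auc(scores, targets) == pytest.approx(
                    brute_force_ap(scores, targets), abs=1e-12)

    def test_against_sklearn(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            scores = rng.normal(size=12)
            targets = rng.integers(0, 2, 12)
            if targets.sum() == 0:
                targets[3] = 1
            assert rs.pr_auc(scores, targets) == pytest.approx(
                average_precision_score(targets, scores), abs=1e-12)

    @given(st.lists(st.floats(min_value=-5, max_value=5), min_size=2,
                    max_size=12))
    @settings(deadline=None, max_examples=100)
    def test_monotone_transform_invariance(self, raw):
        rng = np.random.default_rng(len(raw))
        # coarsen so strictly monotone transforms cannot collapse distinct
        # scores through floating-point rounding
        scores = np.round(np.array(raw), 3)
        targets = rng.integers(0, 2, scores.size)
        if targets.sum() == 0:
            targets[0] = 1
        base = rs.pr_auc(scores, targets)
        assert rs.pr_auc(3.0 * scores + 2.0, targets) == pytest.approx(
            base, abs=1e-12)
        assert rs.pr_auc(np.tanh(scores), targets) == pytest.approx(
            base, abs=1e-12)

    def test_bounded(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            scores = rng.normal(size=10)
            targets = np.r_[1, rng.integers(0, 2, 9)]
            assert 0.0 <= rs.pr_auc(scores, targets) <= 1.0


class TestSplit:
    def _dataset(self, n0, n1, seed=0):
        rng = np.random.default_rng(seed)
        mats = []
        for _ in range(n0 + n1):
            a = rng.normal(size=(4, 4))
            m = (a + a.T) / 2
            np.fill_diagonal(m, 0)
            mats.append(m)
        ds = rs.ConnectivityDataset(
            matrices=np.stack(mats),
            subject_ids=[f"s{i}" for i in range(n0 + n1)],
            groups=["healthy"] * n0 + ["UWS"] * n1,
        )
        ds.targets = np.r_[np.zeros(n0, int), np.ones(n1, int)]
        return ds

    def test_test_size_is_ceil(self):
        ds = self._dataset(30, 29)
        train, test = rs.split(ds, rs.SplitSpec(seed=1))
        assert test.n_subjects == 20  # ceil(0.33 * 59)
        assert train.n_subjects == 39

    def test_deterministic(self):
        ds = self._dataset(10, 10)
        a = rs.split(ds, rs.SplitSpec(seed=5))
        b = rs.split(ds, rs.SplitSpec(seed=5))
        assert a[0].subject_ids == b[0].subject_ids
        assert a[1].subject_ids == b[1].subject_ids

    def test_stratified_keeps_both_classes(self):
        ds = self._dataset(3, 3)
        for seed in range(20):
            train, test = rs.split(ds, rs.SplitSpec(seed=seed))
            assert set(test.targets) == {0, 1}
            assert set(train.targets) == {0, 1}

    def test_unlabeled_rejected(self, random_labeled_dataset):
        with pytest.raises(ValueError, match="targets"):
            rs.split(random_labeled_dataset, rs.SplitSpec(seed=0))


class TestEvaluateMask:
    def test_degenerate_mask_scores_zero(self, small_split):
        train, test = small_split
        fv = rs.evaluate_mask(rs.ROIMask(np.zeros(12, bool)), train, test)
        assert fv.auc_pr == 0.0 and fv.n_features == 0

    def test_planted_mask_near_perfect(self, small_cohort, small_split):
        spec, _ = small_cohort
        train, test = small_split
        fv = rs.evaluate_mask(
            rs.ROIMask.from_indices(spec.planted_set, 12), train, test)
        assert fv.auc_pr >= 0.95

    def test_single_class_train_rejected(self, small_split):
        train, _ = small_split
        healthy_only = train.subset(np.flatnonzero(train.targets == 0))
        with pytest.raises(ValueError, match="single class"):
            rs.evaluate_mask(rs.ROIMask.full(12), healthy_only, train)

    def test_matches_public_sklearn_pipeline(self, small_split):
        # fast liblinear path == StandardScaler + LinearSVC(hinge) + sklearn AP
        train, test = small_split
        rng = np.random.default_rng(0)
        for _ in range(10):
            bits = rng.random(12) < 0.4
            if bits.sum() < 2:
                continue
            mask = rs.ROIMask(bits)
            mine = rs.evaluate_mask(mask, train, test).auc_pr
            Xtr, ytr = dataset_to_design(train, mask)
            Xte, yte = dataset_to_design(test, mask)
            scaler = StandardScaler().fit(Xtr)
            clf = LinearSVC(C=1.0, loss="hinge", tol=1e-4, max_iter=20000,
                            random_state=0)
            clf.fit(scaler.transform(Xtr), ytr)
            ref = average_precision_score(
                yte, clf.decision_function(scaler.transform(Xte)))
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_null_fitness_near_prevalence(self):
        # no class difference: mean AP over splits ~ positive-class prevalence
        spec = rs.SyntheticSpec(n_per_class=(12, 8), n_rois=10,
                                planted_set=(0, 1), base_corr=0.2,
                                effect_corr=0.2, series_length=60, seed=99)
        ds = rs.generate_cohort(spec)
        two = rs.select_pair(ds, rs.GroupPair("healthy", "UWS"))
        prevalence = two.targets.mean()
        mask = rs.ROIMask.from_indices(range(5), 10)
        vals = []
        for seed in range(100):
            tr, te = rs.split(two, rs.SplitSpec(seed=seed))
            vals.append(rs.evaluate_mask(mask, tr, te).auc_pr)
        assert abs(np.mean(vals) - prevalence) < 0.1


class TestSplitEvaluator:
    def test_agrees_with_evaluate_mask(self, small_split):
        train, test = small_split
        ev = SplitEvaluator(train, test)
        rng = np.random.default_rng(4)
        for _ in range(10):
            bits = rng.random(12) < 0.5
            mask = rs.ROIMask(bits)
            assert ev.fitness(mask).auc_pr == rs.evaluate_mask(
                mask, train, test).auc_pr

    def test_memoization_counts_distinct_masks_once(self, small_split):
        train, test = small_split
        ev = SplitEvaluator(train, test)
        bits = np.ones(12, bool)
        ev.fitness_bits(bits)
        ev.fitness_bits(bits.copy())
        assert ev.n_evaluations == 1
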