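"""SVM training and precision-recall-AUC fitness on a train/test split.

Fitness of a candidate ROI mask is the area under the precision-recall
curve (average precision) of a support-vector machine trained on the masked
feature vectors of the training partition and scored, via its decision
function, on the held-out partition.  PR-AUC rather than accuracy because
the cohorts of interest are imbalanced.

The default classifier is an L2-regularized hinge-loss linear SVM
(the liblinear formulation behind :class:`sklearn.svm.LinearSVC`), with
features standardized using training-partition statistics only.  For speed
the default path calls scikit-learn's compiled liblinear entry point
directly — the study evaluates on the order of a million tiny SVMs — and a
test pins its decision values to the public estimator.  An rbf kernel is
available through :class:`sklearn.svm.SVC`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .features import ROIMask, dataset_to_design, mask_to_columns, pair_indices

try:  # compiled fast path; falls back to the public estimator if absent
    from sklearn.svm import _liblinear as _ll
    from sklearn.svm._base import _get_liblinear_solver_type

    _ll.set_verbosity_wrap(0)
    _HINGE_DUAL = _get_liblinear_solver_type("ovr", "l2", "hinge", True)
    _FAST_LINEAR = True
except Exception:  # pragma: no cover - exercised only on other sklearn builds
    _FAST_LINEAR = False

# liblinear shuffles coordinates with srand(seed); fixed for reproducibility
_LIBLINEAR_SEED = 12345
_LINEAR_TOL = 1e-4
_LINEAR_MAX_ITER = 20000


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split parameters (held-out fraction 0.33 by default)."""

    test_fraction: float = 0.33
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "linear"
    C: float = 1.0
    gamma: str | float = "scale"
    standardize: bool = True

    def __post_init__(self):
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be 'linear' or 'rbf', got {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass(frozen=True)
class FitnessValue:
    auc_pr: float
    n_features: int

    def __post_init__(self):
        if not (0.0 <= self.auc_pr <= 1.0):
            raise ValueError("auc_pr must lie in [0, 1]")


def precision(tp: int, fp: int) -> float:
    """TP / (TP + FP); returns 1.0 when nothing was predicted positive."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        return 1.0
    return tp / (tp + fp)


def recall(tp: int, fn: int) -> float:
    """TP / (TP + FN); undefined (error) when the set holds no positives."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        raise ValueError("recall undefined: no positives in the evaluation set")
    return tp / (tp + fn)


def pr_auc(scores, targets) -> float:
    """Area under the precision-recall curve, average-precision form.

    AP = sum_k (R_k - R_{k-1}) * P_k over thresholds placed at each distinct
    score, descending; tied scores enter at a single threshold.  The curve
    starts at recall 0 with precision 1 (the zero-predicted-positives
    convention), so a perfect ranking scores 1.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    targets = np.asarray(targets).ravel().astype(int)
    if scores.shape != targets.shape:
        raise ValueError("scores and targets must have equal length")
    n_pos = int(targets.sum())
    if n_pos == 0:
        raise ValueError("pr_auc undefined: targets contain no positives")
    order = np.argsort(-scores, kind="stable")
    y = targets[order]
    s = scores[order]
    tp = np.cumsum(y)
    # last index of each run of tied scores = one threshold
    cut = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tp_c = tp[cut].astype(float)
    pred_pos = cut + 1.0
    prec = tp_c / pred_pos
    rec = tp_c / n_pos
    return float(np.sum(np.diff(np.r_[0.0, rec]) * prec))


def split(dataset, spec: SplitSpec):
    """Partition a labeled dataset into (train, test) cohorts.

    Test-set size is ceil(test_fraction * n); stratification by target keeps
    both classes in both partitions.  Deterministic given ``spec.seed``.
    """
    if dataset.targets is None:
        raise ValueError("split requires a dataset with binary targets")
    y = dataset.targets
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls} has fewer than 2 subjects; cannot split")
    idx = np.arange(dataset.n_subjects)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=spec.test_fraction,
        stratify=y if spec.stratified else None,
        random_state=spec.seed % (2**32),
        shuffle=True,
    )
    return dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(test_idx))


def _fit_linear_fast(X: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    """Weight-plus-bias vector of the hinge-loss linear SVM via liblinear."""
    raw, _ = _ll.train_wrap(
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.float64),
        False,
        _HINGE_DUAL,
        _LINEAR_TOL,
        1.0,  # bias (intercept) column scale
        C,
        np.ones(2),
        _LINEAR_MAX_ITER,
        _LIBLINEAR_SEED,
        0.1,
        np.ones(X.shape[0]),
    )
    return raw[0]


def linear_svm_scores(X_train, y_train, X_test, C: float = 1.0) -> np.ndarray:
    """Decision-function values on X_test of a linear SVM fit on the train set.

    Positive scores favor class 1; identical (within solver tolerance) to
    ``LinearSVC(loss="hinge", C=C).fit(...).decision_function(X_test)``.
    """
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training partition holds a single class; cannot fit SVM")
    if _FAST_LINEAR:
        wb = _fit_linear_fast(X_train, y_train, C)
        return X_test @ wb[:-1] + wb[-1]
    from sklearn.svm import LinearSVC  # pragma: no cover

    clf = LinearSVC(
        C=C, loss="hinge", tol=_LINEAR_TOL, max_iter=_LINEAR_MAX_ITER,
        random_state=_LIBLINEAR_SEED,
    )
    return clf.fit(X_train, y_train).decision_function(X_test)  # pragma: no cover


def _standardize_pair(X_train, X_test):
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X_train - mu) / sd, (X_test - mu) / sd


def _svm_test_scores(X_train, y_train, X_test, config: SVMConfig) -> np.ndarray:
    if config.standardize:
        X_train, X_test = _standardize_pair(X_train, X_test)
    if config.kernel == "linear":
        return linear_svm_scores(X_train, y_train, X_test, C=config.C)
    from sklearn.svm import SVC

    clf = SVC(kernel="rbf", C=config.C, gamma=config.gamma)
    return clf.fit(X_train, y_train).decision_function(X_test)


def evaluate_mask(mask: ROIMask, train, test,
                  svm_config: SVMConfig = SVMConfig()) -> FitnessValue:
    """Fitness of one ROI mask on one fixed train/test split.

    Degenerate masks (< 2 active ROIs) score 0 without error, so selection
    can eliminate them.  A single-class training partition is an error.
    """
    if mask.active_count < 2:
        return FitnessValue(auc_pr=0.0, n_features=0)
    X_train, y_train = dataset_to_design(train, mask)
    X_test, y_test = dataset_to_design(test, mask)
    if y_train is None or y_test is None:
        raise ValueError("evaluate_mask requires labeled train and test sets")
    if np.unique(y_train).size < 2:
        raise ValueError("training partition holds a single class; cannot fit SVM")
    scores = _svm_test_scores(X_train, y_train, X_test, svm_config)
    return FitnessValue(
        auc_pr=pr_auc(scores, y_test), n_features=X_train.shape[1]
    )


class SplitEvaluator:
    """Memoized mask-fitness evaluator for one fixed train/test split.

    The full all-pairs design (every strict-upper-triangle entry of every
    subject) is built and standardized once; a mask then maps to a column
    subset, because column selection commutes with per-column
    standardization and both layouts share row-major upper-triangle order.
    Fitness of a given mask on a given split is deterministic, so results
    are cached by mask bits.
    """

    def __init__(self, train, test, svm_config: SVMConfig = SVMConfig()):
        self.config = svm_config
        self.n_rois = train.n_rois
        full = ROIMask.full(train.n_rois)
        Xtr, ytr = dataset_to_design(train, full)
        Xte, yte = dataset_to_design(test, full)
        if ytr is None or yte is None:
            raise ValueError("SplitEvaluator requires labeled train and test sets")
        if np.unique(ytr).size < 2:
            raise ValueError("training partition holds a single class; cannot fit SVM")
        if yte.sum() == 0:
            raise ValueError("test partition holds no positives; PR-AUC undefined")
        if svm_config.standardize:
            Xtr, Xte = _standardize_pair(Xtr, Xte)
        self._Xtr, self._ytr = Xtr, ytr.astype(np.float64)
        self._Xte, self._yte = Xte, yte
        self._iu, self._ju = pair_indices(train.n_rois)
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def fitness_bits(self, bits: np.ndarray) -> float:
        key = bits.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if int(bits.sum()) < 2:
            value = 0.0
        else:
            cols = mask_to_columns(bits, self._iu, self._ju)
            Xtr = np.ascontiguousarray(self._Xtr[:, cols])
            Xte = self._Xte[:, cols]
            if self.config.kernel == "linear":
                scores = linear_svm_scores(Xtr, self._ytr, Xte, C=self.config.C)
            else:
                from sklearn.svm import SVC

                clf = SVC(kernel="rbf", C=self.config.C, gamma=self.config.gamma)
                scores = clf.fit(Xtr, self._ytr).decision_function(Xte)
            value = pr_auc(scores, self._yte)
            self.n_evaluations += 1
        self._cache[key] = value
        return value

    def fitness(self, mask: ROIMask) -> FitnessValue:
        return FitnessValue(
            auc_pr=self.fitness_bits(mask.bits),
            n_features=mask.active_count * (mask.active_count - 1) // 2,
        )
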