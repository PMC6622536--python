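"""Synthetic cohorts with a planted discriminative ROI subset.

Real resting-state cohorts for this problem are clinical and not publicly
deposited, so validation runs on simulated data built to exercise the same
pipeline: per-subject multivariate Gaussian "BOLD-like" time series whose
covariance differs between the two classes only inside a small planted set S
of ROIs, converted to sample Pearson correlation and then Fisher Z.  Because
the class difference lives on nodes (every pair within S), not on isolated
edges, recovering S is exactly the node-selection task the wrapper addresses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .connectome import ConnectivityDataset, fisher_z

logger = logging.getLogger(__name__)

#: Largest entrywise perturbation allowed when repairing a template to PSD.
PSD_REPAIR_BOUND = 0.05


@dataclass
class SyntheticSpec:
    """Parameters of a two-class planted-signal cohort.

    Defaults describe the reference validation cohort used throughout the
    test-bench: 30 ROIs, 5 planted, within-set correlation 0.1 vs 0.7
    (difference 0.6), independent background, 400 time points, 20 subjects
    per class.
    """

    n_per_class: tuple[int, int] = (20, 20)
    n_rois: int = 30
    planted_set: tuple[int, ...] = (0, 1, 2, 3, 4)
    base_corr: float = 0.1
    effect_corr: float = 0.7
    background_corr: float = 0.0
    series_length: int = 400
    seed: int = 0
    class_labels: tuple[str, str] = ("healthy", "UWS")

    def __post_init__(self):
        self.planted_set = tuple(sorted(int(i) for i in self.planted_set))
        self.n_per_class = tuple(int(n) for n in self.n_per_class)
        self.class_labels = tuple(self.class_labels)
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if len(self.planted_set) < 2:
            raise ValueError(
                "planted_set needs >= 2 ROIs: an isolated node changes no "
                "pairwise correlation"
            )
        if len(set(self.planted_set)) != len(self.planted_set):
            raise ValueError("planted_set has duplicate indices")
        if not all(0 <= i < self.n_rois for i in self.planted_set):
            raise ValueError("planted_set indices out of range")
        for name in ("base_corr", "effect_corr", "background_corr"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if self.series_length < 20:
            raise ValueError("series_length must be >= 20")
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("n_per_class entries must be positive")
        # fail fast if either class template cannot be made PSD
        for c in (0, 1):
            build_class_covariance(self, c)


def build_class_covariance(spec: SyntheticSpec, class_index: int) -> np.ndarray:
    """Covariance (= correlation) template for one class.

    Unit diagonal; within-planted-set off-diagonal entries equal
    ``base_corr`` (class 0) or ``effect_corr`` (class 1); every other
    off-diagonal entry equals ``background_corr``.  The result is checked to
    be positive semi-definite; a small eigenvalue floor is applied and logged
    when rounding pushes the spectrum slightly negative.
    """
    if class_index not in (0, 1):
        raise ValueError("class_index must be 0 or 1")
    rho_set = spec.base_corr if class_index == 0 else spec.effect_corr
    cov = np.full((spec.n_rois, spec.n_rois), spec.background_corr)
    s = np.array(spec.planted_set)
    cov[np.ix_(s, s)] = rho_set
    np.fill_diagonal(cov, 1.0)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] < 0:
        repaired = _psd_repair(cov)
        delta = np.abs(repaired - cov).max()
        if delta > PSD_REPAIR_BOUND:
            raise ValueError(
                f"class-{class_index} covariance template is not PSD and the "
                f"repair would perturb entries by {delta:.3g} "
                f"(> {PSD_REPAIR_BOUND})"
            )
        logger.warning(
            "covariance template repaired to PSD (max entry change %.3g)", delta
        )
        cov = repaired
    return cov


def _psd_repair(cov: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    w, v = np.linalg.eigh(cov)
    w = np.maximum(w, floor)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def simulate_subject(covariance: np.ndarray, series_length: int,
                     rng: np.random.Generator) -> np.ndarray:
    """One subject's Fisher-Z connectivity matrix from simulated time series.

    Draws ``series_length`` i.i.d. Gaussian vectors with the given covariance,
    forms the sample Pearson correlation matrix, and Fisher-Z-transforms the
    off-diagonal.  The diagonal is stored as 0 (the Z value of a
    self-correlation is infinite and is never used downstream).
    """
    if series_length < 3:
        raise ValueError(
            f"series_length must be >= 3 for a sample correlation, got "
            f"{series_length}"
        )
    cov = np.asarray(covariance, float)
    r = cov.shape[0]
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        chol = v * np.sqrt(np.maximum(w, 0.0))
    series = rng.standard_normal((series_length, r)) @ chol.T
    corr = np.corrcoef(series, rowvar=False)
    # BLAS products are not bitwise symmetric; mirror the upper triangle
    iu, ju = np.triu_indices(r, k=1)
    z = np.zeros_like(corr)
    z[iu, ju] = z[ju, iu] = fisher_z(corr[iu, ju])
    return z


def generate_cohort(spec: SyntheticSpec) -> ConnectivityDataset:
    """Simulate the full two-class cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    mats, ids, groups = [], [], []
    for class_index, (n, label) in enumerate(zip(spec.n_per_class, spec.class_labels)):
        cov = build_class_covariance(spec, class_index)
        for k in range(n):
            mats.append(simulate_subject(cov, spec.series_length, rng))
            ids.append(f"{label}_{k:03d}")
            groups.append(label)
    return ConnectivityDataset(
        matrices=np.stack(mats),
        subject_ids=ids,
        groups=groups,
        roi_labels=[f"ROI{i:03d}" for i in range(spec.n_rois)],
    )
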