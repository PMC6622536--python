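"""From ROI mask + correlation matrix to the SVM feature vector.

An :class:`ROIMask` keeps rows/columns of the connectivity matrix whose bit
is 1; the truncated k-by-k matrix's strict upper triangle, read row-major,
is the feature vector (length k(k-1)/2).  The diagonal is always excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateMaskError(ValueError):
    """Mask with fewer than 2 active ROIs: no pairwise feature exists."""


@dataclass(frozen=True)
class ROIMask:
    """Boolean inclusion vector over ROIs — the GA genotype."""

    bits: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))
        if self.bits.ndim != 1:
            raise ValueError("mask bits must be a 1-d vector")

    @classmethod
    def from_indices(cls, indices, n_rois: int) -> "ROIMask":
        bits = np.zeros(n_rois, dtype=bool)
        bits[list(indices)] = True
        return cls(bits)

    @classmethod
    def full(cls, n_rois: int) -> "ROIMask":
        return cls(np.ones(n_rois, dtype=bool))

    @property
    def n_rois(self) -> int:
        return self.bits.size

    @property
    def active_count(self) -> int:
        return int(self.bits.sum())

    @property
    def active_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def __eq__(self, other):
        return isinstance(other, ROIMask) and np.array_equal(self.bits, other.bits)

    def __hash__(self):
        return hash(self.bits.tobytes())


@dataclass(frozen=True)
class FeatureVector:
    """Flattened upper triangle plus the (i, j) ROI pair behind each entry."""

    values: np.ndarray
    pair_index: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(self.pair_index) != self.values.size:
            raise ValueError("pair_index and values disagree in length")


def apply_mask(matrix: np.ndarray, mask: ROIMask) -> np.ndarray:
    """Truncate a matrix to the active rows/columns, order preserved."""
    matrix = np.asarray(matrix, float)
    if matrix.shape[0] != matrix.shape[1] or matrix.shape[0] != mask.n_rois:
        raise ValueError(
            f"matrix shape {matrix.shape} incompatible with mask of length "
            f"{mask.n_rois}"
        )
    if mask.active_count < 2:
        raise DegenerateMaskError(
            f"mask keeps {mask.active_count} ROI(s); at least 2 are needed "
            "for pairwise features"
        )
    idx = mask.active_indices
    return matrix[np.ix_(idx, idx)]


def flatten_upper(truncated: np.ndarray,
                  roi_indices: np.ndarray | None = None) -> FeatureVector:
    """Strict upper triangle in row-major order.

    ``roi_indices`` maps truncated positions back to original ROI indices for
    ``pair_index``; identity if omitted.
    """
    truncated = np.asarray(truncated, float)
    k = truncated.shape[0]
    if k < 2 or truncated.shape[0] != truncated.shape[1]:
        raise ValueError("flatten_upper needs a square matrix with k >= 2")
    if roi_indices is None:
        roi_indices = np.arange(k)
    iu, ju = np.triu_indices(k, k=1)
    pairs = tuple(
        (int(roi_indices[i]), int(roi_indices[j])) for i, j in zip(iu, ju)
    )
    return FeatureVector(values=truncated[iu, ju], pair_index=pairs)


def mask_features(matrix: np.ndarray, mask: ROIMask) -> FeatureVector:
    """apply_mask then flatten_upper, with original-ROI pair indices."""
    return flatten_upper(apply_mask(matrix, mask), mask.active_indices)


def pair_indices(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major strict-upper-triangle (i, j) index vectors for R ROIs."""
    return np.triu_indices(n_rois, k=1)


def mask_to_columns(bits: np.ndarray, iu: np.ndarray, ju: np.ndarray) -> np.ndarray:
    """Columns of the full all-pairs design selected by a mask.

    Because both the full design and the truncated design are laid out in
    row-major upper-triangle order, selecting the full-design columns whose
    two ROIs are both active reproduces the truncated flattening exactly.
    """
    return np.flatnonzero(bits[iu] & bits[ju])


def dataset_to_design(dataset, mask: ROIMask) -> tuple[np.ndarray, np.ndarray | None]:
    """Stack per-subject feature vectors into a design matrix.

    Returns (X, y): X has one row per subject in dataset order and
    k(k-1)/2 columns; y is the target vector, or None for unlabeled data.
    """
    if dataset.n_rois != mask.n_rois:
        raise ValueError(
            f"dataset has {dataset.n_rois} ROIs but mask has {mask.n_rois}"
        )
    if mask.active_count < 2:
        raise DegenerateMaskError(
            f"mask keeps {mask.active_count} ROI(s); at least 2 are needed"
        )
    idx = mask.active_indices
    sub = dataset.matrices[np.ix_(np.arange(dataset.n_subjects), idx, idx)]
    iu, ju = np.triu_indices(idx.size, k=1)
    X = sub[:, iu, ju]
    return np.ascontiguousarray(X), dataset.targets
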