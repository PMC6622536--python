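"""Connectivity datasets: domain types, Fisher-Z transform, and text I/O.

The unit of data is a cohort of subjects, each carrying one square symmetric
ROI-by-ROI matrix of Fisher-Z-transformed Pearson correlations between
regional BOLD time series, plus a group label (healthy / MCS / UWS or any
free-form string).  Diagonal entries are carried but ignored everywhere
downstream: the self-correlation is 1 and its Fisher-Z value is infinite, so
it holds no information.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Largest tolerated asymmetry |M - M.T| before a warning is emitted and the
#: matrix is symmetrized as (M + M.T)/2.
SYMMETRY_TOL = 1e-8

#: Virtual group label expanding to the union of the two patient groups.
PATIENTS = "patients"
PATIENT_GROUPS = ("MCS", "UWS")


class DomainError(ValueError):
    """A value outside the mathematical domain of an operation."""


def fisher_z(r):
    """Fisher Z (variance-stabilizing) transform z = arctanh(r).

    Parameters
    ----------
    r : float or array-like
        Pearson correlation(s), each strictly inside (-1, 1).

    Returns
    -------
    float or ndarray
        arctanh(r), an odd and strictly increasing map of (-1, 1) onto the
        real line.

    Raises
    ------
    DomainError
        If any |r| >= 1, naming the offending value.
    """
    arr = np.asarray(r, dtype=float)
    bad = np.abs(arr) >= 1.0
    if np.any(bad):
        offending = arr[bad].ravel()[0] if arr.ndim else float(arr)
        raise DomainError(
            f"fisher_z requires |r| < 1; got r = {offending!r}"
        )
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


@dataclass(frozen=True)
class GroupPair:
    """A two-class comparison, e.g. ('healthy', 'patients').

    ``positive_class`` names the class scored as 1 for precision/recall;
    it defaults (in :func:`select_pair`) to the patient-side class, or to
    ``class_b`` when neither side is a patient group.
    """

    class_a: str
    class_b: str
    positive_class: str | None = None

    def __post_init__(self):
        if self.class_a == self.class_b:
            raise ValueError(
                f"GroupPair requires two distinct classes, got "
                f"({self.class_a!r}, {self.class_b!r})"
            )
        if self.positive_class is not None and self.positive_class not in (
            self.class_a,
            self.class_b,
        ):
            raise ValueError(
                f"positive_class {self.positive_class!r} is neither "
                f"{self.class_a!r} nor {self.class_b!r}"
            )

    def resolved_positive(self) -> str:
        if self.positive_class is not None:
            return self.positive_class
        a_pat = self.class_a in PATIENT_GROUPS or self.class_a == PATIENTS
        b_pat = self.class_b in PATIENT_GROUPS or self.class_b == PATIENTS
        if a_pat and not b_pat:
            return self.class_a
        return self.class_b

    def members(self, label: str) -> tuple[str, ...]:
        """Concrete group labels covered by one side of the pair."""
        return PATIENT_GROUPS if label == PATIENTS else (label,)


@dataclass
class ConnectivityDataset:
    """A cohort of subjects sharing one ROI parcellation.

    Attributes
    ----------
    matrices : ndarray, shape (n_subjects, R, R)
        Fisher-Z connectivity matrices, symmetric, finite off the diagonal.
    subject_ids : list of str
    groups : list of str
    roi_labels : list of str, length R
    targets : ndarray of {0,1} or None
        Binary class targets, present only after :func:`select_pair`.
    """

    matrices: np.ndarray
    subject_ids: list[str]
    groups: list[str]
    roi_labels: list[str] = field(default_factory=list)
    targets: np.ndarray | None = None

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError(
                f"matrices must have shape (n_subjects, R, R), got "
                f"{self.matrices.shape}"
            )
        if self.n_rois < 2:
            raise ValueError("a connectivity dataset needs at least 2 ROIs")
        n = len(self.subject_ids)
        if len(self.groups) != n or self.matrices.shape[0] != n:
            raise ValueError("subject_ids, groups and matrices disagree in length")
        if not self.roi_labels:
            self.roi_labels = [f"ROI{i:03d}" for i in range(self.n_rois)]
        if len(self.roi_labels) != self.n_rois:
            raise ValueError("roi_labels length must equal n_rois")
        offdiag = self.matrices[
            :, ~np.eye(self.n_rois, dtype=bool)
        ]
        if not np.all(np.isfinite(offdiag)):
            raise ValueError("off-diagonal entries must be finite")
        asym = np.abs(self.matrices - self.matrices.transpose(0, 2, 1)).max()
        if asym > SYMMETRY_TOL:
            logger.warning(
                "matrices asymmetric up to %.3g; symmetrizing as (M + M.T)/2",
                asym,
            )
            self.matrices = 0.5 * (self.matrices + self.matrices.transpose(0, 2, 1))
        if self.targets is not None:
            self.targets = np.asarray(self.targets, dtype=int)
            if self.targets.shape != (n,):
                raise ValueError("targets must be one value per subject")

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_rois(self) -> int:
        return self.matrices.shape[1]

    def subset(self, indices) -> "ConnectivityDataset":
        indices = np.asarray(indices, dtype=int)
        return ConnectivityDataset(
            matrices=self.matrices[indices].copy(),
            subject_ids=[self.subject_ids[i] for i in indices],
            groups=[self.groups[i] for i in indices],
            roi_labels=list(self.roi_labels),
            targets=None if self.targets is None else self.targets[indices].copy(),
        )


def concatenate(datasets: list[ConnectivityDataset]) -> ConnectivityDataset:
    """Stack cohorts that share the same ROI labels."""
    first = datasets[0]
    for d in datasets[1:]:
        if d.roi_labels != first.roi_labels:
            raise ValueError("cannot concatenate datasets with different ROI labels")
    return ConnectivityDataset(
        matrices=np.concatenate([d.matrices for d in datasets]),
        subject_ids=sum((d.subject_ids for d in datasets), []),
        groups=sum((d.groups for d in datasets), []),
        roi_labels=list(first.roi_labels),
    )


def select_pair(dataset: ConnectivityDataset, pair: GroupPair) -> ConnectivityDataset:
    """Restrict a cohort to the two classes of a comparison, with 0/1 targets.

    Subjects outside both classes are dropped.  The virtual label
    ``"patients"`` expands to MCS union UWS.  Each retained class must hold at
    least 2 subjects (otherwise no train/test split exists).
    """
    groups_a = pair.members(pair.class_a)
    groups_b = pair.members(pair.class_b)
    if set(groups_a) & set(groups_b):
        raise ValueError(f"pair sides overlap: {groups_a} vs {groups_b}")
    in_a = np.array([g in groups_a for g in dataset.groups])
    in_b = np.array([g in groups_b for g in dataset.groups])
    for label, m in ((pair.class_a, in_a), (pair.class_b, in_b)):
        if m.sum() < 2:
            raise ValueError(
                f"class {label!r} has {int(m.sum())} subject(s); "
                "at least 2 are required for a train/test split"
            )
    keep = np.flatnonzero(in_a | in_b)
    sub = dataset.subset(keep)
    positive = pair.resolved_positive()
    pos_groups = pair.members(positive)
    sub.targets = np.array([1 if g in pos_groups else 0 for g in sub.groups], dtype=int)
    return sub


# ---------------------------------------------------------------------------
# Text I/O: delimited matrix files and a CSV manifest.

def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_matrix(path) -> tuple[np.ndarray, list[str] | None]:
    """Read a square delimited-text matrix; returns (matrix, labels or None).

    Accepts comma- or tab-separated values, scientific notation, and an
    optional single header row of ROI labels.
    """
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    tokens = [t.strip() for t in first.strip().split(delim)]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(t) for t in tokens if t)
    labels = tokens if has_header else None
    mat = np.loadtxt(path, delimiter=delim, skiprows=1 if has_header else 0, ndmin=2)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(
            f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]}, expected square"
        )
    return mat, labels


def write_matrix(path, matrix: np.ndarray, labels: list[str] | None = None) -> None:
    """Write a matrix as comma-separated text at full double precision."""
    with open(path, "w") as fh:
        if labels is not None:
            fh.write(",".join(labels) + "\n")
        np.savetxt(fh, np.asarray(matrix, float), delimiter=",", fmt="%.17g")


def load_manifest(manifest_path, allowed_groups: set[str] | None = None) -> ConnectivityDataset:
    """Build a dataset from a manifest CSV (subject_id, group, matrix_path).

    Relative matrix paths are resolved against the manifest's directory.
    """
    manifest_path = os.fspath(manifest_path)
    table = pd.read_csv(manifest_path, dtype=str)
    required = {"subject_id", "group", "matrix_path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(manifest_path))
    files = [
        (row.subject_id, row.group,
         row.matrix_path if os.path.isabs(row.matrix_path)
         else os.path.join(base, row.matrix_path))
        for row in table.itertuples()
    ]
    return matrices_to_dataset(files, allowed_groups=allowed_groups)


def matrices_to_dataset(
    files: list[tuple[str, str, str]],
    roi_labels: list[str] | None = None,
    allowed_groups: set[str] | None = None,
) -> ConnectivityDataset:
    """Assemble (subject_id, group, matrix-file path) triples into a dataset.

    All matrices must be square and of identical dimension; labels read from
    file headers must agree with ``roi_labels`` when both are given.
    """
    if not files:
        raise ValueError("no matrix files given")
    mats, ids, groups = [], [], []
    for subject_id, group, path in files:
        if allowed_groups is not None and group not in allowed_groups:
            raise ValueError(
                f"subject {subject_id!r}: group {group!r} not in "
                f"{sorted(allowed_groups)}"
            )
        mat, labels = read_matrix(path)
        if roi_labels is None and labels is not None:
            roi_labels = labels
        if mats and mat.shape != mats[0].shape:
            raise ValueError(
                f"subject {subject_id!r}: matrix is {mat.shape[0]}x{mat.shape[1]} "
                f"but earlier subjects are {mats[0].shape[0]}x{mats[0].shape[0]}"
            )
        mats.append(mat)
        ids.append(subject_id)
        groups.append(group)
    return ConnectivityDataset(
        matrices=np.stack(mats),
        subject_ids=ids,
        groups=groups,
        roi_labels=roi_labels or [],
    )


def save_dataset(dataset: ConnectivityDataset, out_dir) -> str:
    """Write one matrix file per subject plus a manifest CSV; returns its path."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, (sid, group) in enumerate(zip(dataset.subject_ids, dataset.groups)):
        fname = f"{sid}.csv"
        write_matrix(os.path.join(out_dir, fname), dataset.matrices[i],
                     labels=dataset.roi_labels)
        rows.append({"subject_id": sid, "group": group, "matrix_path": fname})
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
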