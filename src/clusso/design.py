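"""Per-subject cluster-averaged, proportion-weighted design matrices.

Given cluster labels for every tubule, each subject's objects are averaged
within clusters (rows of ``X_star``), the cluster membership proportions
``w`` are recorded, and the final design matrix is the weighted
``X_dstar = diag(w) @ X_star``. Subjects lacking at least one object in every
cluster have an undefined cluster average and are dropped (and reported).

The design cells entering the structured lasso are z-scored per (cluster,
feature) cell across subjects, and the outcome is centered; the stored
transform is re-applied to test-set designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusterAssignment
from .data_io import DataError, OutcomeVector, TubuleTable

__all__ = [
    "ClusterAveragedDesign",
    "DroppedSubjectReport",
    "StandardizationTransform",
    "build_design",
    "build_full_info_design",
    "stack_designs",
    "standardize",
]


@dataclass
class ClusterAveragedDesign:
    """One subject's (X_star, w, X_dstar) triple."""

    subject_id: object
    X_star: np.ndarray  # (G, q) within-cluster feature means
    w: np.ndarray  # (G,) cluster proportions, summing to 1
    X_dstar: np.ndarray = field(init=False)  # diag(w) @ X_star

    def __post_init__(self) -> None:
        self.X_star = np.asarray(self.X_star, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.X_star.ndim != 2 or self.w.shape != (self.X_star.shape[0],):
            raise DataError("X_star must be (G, q) with w of length G")
        if abs(self.w.sum() - 1.0) > 1e-12:
            raise DataError(f"weights for subject {self.subject_id!r} do not sum to 1")
        self.X_dstar = self.w[:, None] * self.X_star


@dataclass
class DroppedSubjectReport:
    """Subjects excluded for lacking an object in at least one cluster."""

    subject_ids: list
    missing_clusters: dict  # subject_id -> sorted list of empty cluster labels

    @property
    def n_dropped(self) -> int:
        return len(self.subject_ids)


def build_design(
    tubules: TubuleTable, labels, G: int
) -> tuple[list[ClusterAveragedDesign], DroppedSubjectReport]:
    """Cluster-average each subject's objects and weight by cluster proportions.

    Row ``k`` of a subject's ``X_star`` is the mean feature vector of their
    objects labeled ``k``; ``w`` holds the per-subject label proportions.
    Subjects with an empty cluster are dropped and reported. Invariant to the
    object row order within a subject.
    """
    lab = labels.labels if isinstance(labels, ClusterAssignment) else np.asarray(labels, int)
    if lab.shape != (tubules.n_objects,):
        raise DataError("labels must align with tubule rows")
    if lab.size and (lab.min() < 1 or lab.max() > G):
        raise DataError("labels must lie in 1..G")
    designs: list[ClusterAveragedDesign] = []
    dropped: list = []
    missing: dict = {}
    for subject, rows in tubules.subject_row_indices().items():
        sub_lab = lab[rows]
        counts = np.bincount(sub_lab - 1, minlength=G)
        if np.any(counts == 0):
            dropped.append(subject)
            missing[subject] = (np.flatnonzero(counts == 0) + 1).tolist()
            continue
        X_star = np.empty((G, tubules.q))
        for k in range(G):
            X_star[k] = tubules.features[rows[sub_lab == k + 1]].mean(axis=0)
        w = counts / counts.sum()
        designs.append(ClusterAveragedDesign(subject, X_star, w))
    if not designs:
        raise DataError(
            "every subject lacks at least one object in some cluster; "
            "the tubules may come from a single latent subgroup -- "
            "consider the naive averaging method instead"
        )
    return designs, DroppedSubjectReport(dropped, missing)


def build_full_info_design(truth) -> list[ClusterAveragedDesign]:
    """Oracle designs from true cluster means and proportions (no drops)."""
    designs = []
    for subject, X_star, w in zip(truth.subject_ids, truth.X_star, truth.w):
        w = np.asarray(w, dtype=float)
        if np.any(w <= 0) or np.any(w > 1):
            raise DataError(f"true weight outside (0, 1] for subject {subject!r}")
        designs.append(ClusterAveragedDesign(subject, X_star, w))
    return designs


def stack_designs(designs: list[ClusterAveragedDesign]) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-subject X_dstar matrices into (subject_ids, (n, G, q) array)."""
    ids = np.asarray([d.subject_id for d in designs])
    X = np.stack([d.X_dstar for d in designs], axis=0)
    return ids, X


@dataclass
class StandardizationTransform:
    """Per-cell z-scoring of the (G, q) design entries, plus outcome centering."""

    mean: np.ndarray  # (G, q)
    scale: np.ndarray  # (G, q), all > 0
    y_mean: float

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    def invert(self, X_std: np.ndarray) -> np.ndarray:
        return np.asarray(X_std, dtype=float) * self.scale + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean, "scale": self.scale, "y_mean": float(self.y_mean)}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationTransform":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            y_mean=float(d["y_mean"]),
        )


def standardize(
    designs: list[ClusterAveragedDesign], y
) -> tuple[np.ndarray, np.ndarray, StandardizationTransform]:
    """Z-score design cells across subjects and center the outcome.

    Returns the standardized (n, G, q) design stack, the centered outcome
    aligned to the design subject order, and the invertible transform. The
    outcome model has no intercept, so centering y stands in for one;
    predictions add the training y-mean back.
    """
    ids, X = stack_designs(designs)
    if X.shape[0] < 2:
        raise DataError("standardization requires at least 2 retained subjects")
    if isinstance(y, OutcomeVector):
        yv = y.select(ids)
    else:
        yv = np.asarray(y, dtype=float)
        if yv.shape != (X.shape[0],):
            raise DataError("y must align with the retained subjects")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    if np.any(scale == 0):
        k, j = np.argwhere(scale == 0)[0]
        raise DataError(f"zero variance in design cell (cluster {k + 1}, feature {j})")
    tr = StandardizationTransform(mean=mean, scale=scale, y_mean=float(yv.mean()))
    return tr.apply(X), yv - tr.y_mean, tr
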