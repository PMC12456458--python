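"""Unsupervised clustering of pooled tubules into latent subgroups.

All tubules from all subjects are pooled into one matrix and classified into
``G`` subgroups with either a Gaussian mixture model (EM, full covariances)
or K-means. The fitted cluster model is a plain-parameter object so it can be
serialized into a model archive and re-applied to test-set tubules without
refitting.

Clustering accuracy against known labels is scored by the single global label
permutation that maximizes overall agreement (Hungarian assignment on the
pooled confusion matrix), then averaged per subject and across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .data_io import TubuleTable

__all__ = [
    "ClusteringError",
    "ClusterModel",
    "ClusterAssignment",
    "cluster_pooled",
    "assign_new",
    "clustering_accuracy",
]

_ALGORITHMS = ("gmm", "kmeans")


class ClusteringError(RuntimeError):
    """Raised when clustering cannot be fit or applied."""


@dataclass
class ClusterModel:
    """Frozen parameters of a fitted clustering model.

    ``params`` holds ``weights``/``means``/``covariances`` for a GMM or
    ``centers`` for K-means; features are optionally column-standardized with
    the stored pooled mean/scale before scoring.
    """

    algorithm: str
    G: int
    standardize: bool
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    params: dict
    seed: int | None = None

    def _transform(self, features: np.ndarray) -> np.ndarray:
        if not self.standardize:
            return np.asarray(features, dtype=float)
        return (features - self.feature_mean) / self.feature_scale

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Labels in 1..G for raw (unstandardized) feature rows."""
        X = self._transform(np.asarray(features, dtype=float))
        if X.shape[1] != len(self.feature_mean):
            raise ClusteringError(
                f"feature count {X.shape[1]} does not match training "
                f"q={len(self.feature_mean)}"
            )
        if self.algorithm == "gmm":
            scores = self._gmm_log_posterior(X)
            # argmax returns the lowest index on exact ties
            return np.argmax(scores, axis=1) + 1
        centers = self.params["centers"]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1) + 1

    def _gmm_log_posterior(self, X: np.ndarray) -> np.ndarray:
        weights = self.params["weights"]
        means = self.params["means"]
        covs = self.params["covariances"]
        n, q = X.shape
        logp = np.empty((n, self.G))
        for k in range(self.G):
            chol = linalg.cholesky(covs[k], lower=True)
            dev = linalg.solve_triangular(chol, (X - means[k]).T, lower=True)
            maha = np.sum(dev**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            logp[:, k] = (
                np.log(weights[k])
                - 0.5 * (q * np.log(2.0 * np.pi) + logdet + maha)
            )
        return logp

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "G": int(self.G),
            "standardize": bool(self.standardize),
            "feature_mean": self.feature_mean,
            "feature_scale": self.feature_scale,
            "params": dict(self.params),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        return cls(
            algorithm=d["algorithm"],
            G=int(d["G"]),
            standardize=bool(d["standardize"]),
            feature_mean=np.asarray(d["feature_mean"], dtype=float),
            feature_scale=np.asarray(d["feature_scale"], dtype=float),
            params={k: np.asarray(v, dtype=float) for k, v in d["params"].items()},
            seed=d.get("seed"),
        )


@dataclass
class ClusterAssignment:
    """Per-object labels (1..G) aligned to a TubuleTable, plus the model."""

    labels: np.ndarray
    G: int
    algorithm: str
    model: ClusterModel
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.G):
            raise ClusteringError("labels must lie in 1..G")


def cluster_pooled(
    tubules: TubuleTable,
    G: int,
    algorithm: str = "gmm",
    seed: int = 0,
    standardize_features: bool = True,
    n_init: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ClusterAssignment:
    """Cluster the pooled tubule matrix into G subgroups.

    GMM uses full covariance matrices with ``n_init`` EM restarts; labels are
    the argmax posterior responsibilities. K-means labels are nearest-centroid
    with ties broken toward the lowest cluster index. Deterministic given
    ``seed``.
    """
    if algorithm not in _ALGORITHMS:
        raise ClusteringError(f"unknown clustering algorithm {algorithm!r}")
    if G < 1:
        raise ClusteringError("G must be >= 1")
    X = tubules.features
    if X.shape[0] < G:
        raise ClusteringError(
            f"pooled object count {X.shape[0]} is smaller than G={G}"
        )
    if standardize_features:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)  # constant columns pass through
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Z = (X - mean) / scale

    seed = int(seed) % (2**31)
    if algorithm == "gmm":
        gm = GaussianMixture(
            n_components=G,
            covariance_type="full",
            n_init=n_init,
            tol=tol,
            max_iter=max_iter,
            random_state=seed,
        )
        gm.fit(Z)
        if not gm.converged_:
            raise ClusteringError(
                f"EM did not converge within {max_iter} iterations "
                f"(last lower bound {gm.lower_bound_:.6g})"
            )
        params = {
            "weights": gm.weights_,
            "means": gm.means_,
            "covariances": gm.covariances_,
        }
    else:
        km = KMeans(n_clusters=G, n_init=n_init, random_state=seed)
        km.fit(Z)
        params = {"centers": km.cluster_centers_}

    model = ClusterModel(
        algorithm=algorithm,
        G=G,
        standardize=standardize_features,
        feature_mean=mean,
        feature_scale=scale,
        params=params,
        seed=seed,
    )
    # score through the frozen model so training and test labeling share one path
    labels = model.predict(X)
    return ClusterAssignment(labels=labels, G=G, algorithm=algorithm, model=model, seed=seed)


def assign_new(model, tubules: TubuleTable) -> ClusterAssignment:
    """Label new tubules with a trained cluster model (no refit)."""
    if isinstance(model, ClusterAssignment):
        model = model.model
    labels = model.predict(tubules.features)
    return ClusterAssignment(
        labels=labels,
        G=model.G,
        algorithm=model.algorithm,
        model=model,
        seed=model.seed,
    )


def clustering_accuracy(estimated, truth, subject_ids) -> float:
    """Best-permutation clustering accuracy, averaged across subjects.

    A single global permutation of the estimated labels (the one maximizing
    total agreement with ``truth``, found by Hungarian assignment on the
    pooled confusion matrix) is applied; each subject's proportion of
    agreeing objects is computed and the mean across subjects returned.
    Invariant to relabeling either argument.
    """
    est = estimated.labels if isinstance(estimated, ClusterAssignment) else np.asarray(estimated, int)
    tru = np.asarray(truth, dtype=int)
    subject_ids = np.asarray(subject_ids)
    if est.shape != tru.shape or est.shape != subject_ids.shape:
        raise ValueError("estimated, truth and subject_ids must be aligned")
    G = int(max(est.max(initial=1), tru.max(initial=1)))
    if est.min(initial=1) < 1 or tru.min(initial=1) < 1:
        raise ValueError("labels must lie in 1..G")
    conf = np.zeros((G, G), dtype=int)
    np.add.at(conf, (est - 1, tru - 1), 1)
    rows, cols = linear_sum_assignment(-conf)
    mapping = np.empty(G, dtype=int)
    mapping[rows] = cols
    mapped = mapping[est - 1] + 1
    agree = (mapped == tru).astype(float)
    _, inv = np.unique(subject_ids, return_inverse=True)
    per_subject = np.bincount(inv, weights=agree) / np.bincount(inv)
    return float(per_subject.mean())
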