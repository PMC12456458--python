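"""End-to-end fitting strategies: CLUSSO, Full Information oracle, naive lasso.

``fit_clusso`` runs the full pipeline on observed tubules: pool-and-cluster,
cluster-average and weight per subject, standardize, cross-validate lambda,
solve the structured lasso from multiple starts, and threshold the
L1-normalized coefficients. ``fit_full_info`` does the same from the true
cluster means and proportions (simulation oracle). ``fit_naive`` averages all
of a subject's tubules into one feature vector and runs an ordinary lasso
with a glmnet-style log-spaced regularization path.

For applying a fitted CLUSSO model to an independent test set, the mapping
between training and test cluster labels is unidentified;
``predict_with_correspondence`` evaluates every permutation of cluster rows
and, when test outcomes are available, flags the one with the smallest MSE.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .clustering import ClusterModel, assign_new, cluster_pooled
from .data_io import DataError, ModelArchive, OutcomeVector, TubuleTable
from .design import (
    DroppedSubjectReport,
    StandardizationTransform,
    build_design,
    build_full_info_design,
    stack_designs,
    standardize,
)
from .structured_lasso import cv_lambda, normalize_threshold, solve_multi_init

__all__ = [
    "FitConfig",
    "CorrespondenceResult",
    "fit_clusso",
    "fit_full_info",
    "fit_naive",
    "naive_lambda_grid",
    "predict_with_correspondence",
    "predict_naive",
]

DEFAULT_LAMBDA_GRID = tuple(np.arange(0.5, 5.01, 0.5))


@dataclass
class FitConfig:
    """Settings shared by the three fitting strategies."""

    G: int = 2
    cluster_algorithm: str = "gmm"
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    n_folds: int = 5
    n_inits: int = 5
    threshold: float = 0.001
    seed: int = 0
    standardize_features: bool = True
    tol: float = 1e-6
    max_iter: int = 200

    def __post_init__(self) -> None:
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.size == 0 or np.any(np.diff(grid) < 0):
            raise ValueError("lambda_grid must be non-empty and ascending")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _archive_metadata(config: FitConfig, n_used: int, dropped: DroppedSubjectReport | None,
                      cv_table, extra: dict | None = None) -> dict:
    meta = {
        "n_subjects": int(n_used),
        "dropped_subjects": [str(s) for s in dropped.subject_ids] if dropped else [],
        "missing_clusters": {str(k): v for k, v in dropped.missing_clusters.items()}
        if dropped
        else {},
        "cv_table": {k: np.asarray(v, dtype=float) for k, v in cv_table.items()}
        if cv_table is not None
        else None,
        "seed": int(config.seed),
        "threshold": float(config.threshold),
    }
    if extra:
        meta.update(extra)
    return meta


def fit_clusso(
    tubules: TubuleTable, outcomes: OutcomeVector, config: FitConfig | None = None
) -> ModelArchive:
    """Fit CLUSSO on observed tubules and subject outcomes."""
    config = config or FitConfig()
    cv_seed, solve_seed = (int(s) for s in _seeds(config.seed, 2))
    assignment = cluster_pooled(
        tubules,
        config.G,
        algorithm=config.cluster_algorithm,
        seed=config.seed,
        standardize_features=config.standardize_features,
    )
    designs, dropped = build_design(tubules, assignment, config.G)
    n_total = len(tubules.subjects)
    if dropped.n_dropped > 0.5 * n_total:
        warnings.warn(
            f"{dropped.n_dropped}/{n_total} subjects dropped for an empty cluster; "
            "the tubules may come from a single latent subgroup, where the naive "
            "averaging approach may be sufficient",
            stacklevel=2,
        )
    X, y_c, transform = standardize(designs, outcomes)
    lam, cv_table = cv_lambda(
        X,
        y_c,
        np.asarray(config.lambda_grid, dtype=float),
        n_folds=config.n_folds,
        seed=cv_seed,
        n_inits=config.n_inits,
        tol=config.tol,
        max_iter=config.max_iter,
    )
    sol = solve_multi_init(
        X, y_c, lam, n_inits=config.n_inits, seed=solve_seed,
        tol=config.tol, max_iter=config.max_iter,
    )
    return ModelArchive(
        method="clusso",
        feature_names=list(tubules.feature_names),
        G=config.G,
        alpha=sol.alpha,
        beta=sol.beta,
        beta_normalized=normalize_threshold(sol.beta, config.threshold),
        lam=lam,
        design_mean=transform.mean,
        design_scale=transform.scale,
        y_mean=transform.y_mean,
        cluster_model=assignment.model.to_dict(),
        metadata=_archive_metadata(
            config, X.shape[0], dropped, cv_table.to_dict(orient="list"),
            {"objective": sol.objective, "converged": bool(sol.converged)},
        ),
    )


def fit_full_info(truth, outcomes=None, config: FitConfig | None = None) -> ModelArchive:
    """Oracle fit from the true cluster means and proportions (simulation only)."""
    config = config or FitConfig(G=len(truth.alpha_star))
    cv_seed, solve_seed = (int(s) for s in _seeds(config.seed, 2))
    designs = build_full_info_design(truth)
    y = outcomes if outcomes is not None else OutcomeVector(truth.subject_ids, truth.y)
    X, y_c, transform = standardize(designs, y)
    lam, cv_table = cv_lambda(
        X,
        y_c,
        np.asarray(config.lambda_grid, dtype=float),
        n_folds=config.n_folds,
        seed=cv_seed,
        n_inits=config.n_inits,
        tol=config.tol,
        max_iter=config.max_iter,
    )
    sol = solve_multi_init(
        X, y_c, lam, n_inits=config.n_inits, seed=solve_seed,
        tol=config.tol, max_iter=config.max_iter,
    )
    return ModelArchive(
        method="full_info",
        feature_names=[f"feature_{j}" for j in range(X.shape[2])],
        G=X.shape[1],
        alpha=sol.alpha,
        beta=sol.beta,
        beta_normalized=normalize_threshold(sol.beta, config.threshold),
        lam=lam,
        design_mean=transform.mean,
        design_scale=transform.scale,
        y_mean=transform.y_mean,
        cluster_model=None,
        metadata=_archive_metadata(
            config, X.shape[0], None, cv_table.to_dict(orient="list"),
            {"objective": sol.objective, "converged": bool(sol.converged)},
        ),
    )


def naive_lambda_grid(Xbar_std: np.ndarray, y_centered: np.ndarray, n_values: int = 100,
                      ratio: float = 1e-4) -> np.ndarray:
    """glmnet-style log-spaced path, descending from lambda_max.

    Under the objective (1/n)||y - X b||^2 + lambda ||b||_1, the smallest
    lambda with an all-zero solution is lambda_max = (2/n) max_j |<x_j, y>|.
    """
    n = len(y_centered)
    lam_max = 2.0 / n * np.max(np.abs(Xbar_std.T @ y_centered))
    return np.geomspace(lam_max, lam_max * ratio, n_values)


def _naive_lasso(Xbar_std, y_centered, lam):
    # sklearn minimizes (1/2n)||y - Xb||^2 + a||b||_1, so a = lam / 2
    model = Lasso(alpha=lam / 2.0, fit_intercept=False, max_iter=50_000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xbar_std, y_centered)
    return model.coef_.copy()


def fit_naive(
    tubules: TubuleTable, outcomes: OutcomeVector, config: FitConfig | None = None
) -> ModelArchive:
    """Average each subject's tubules and fit an ordinary lasso.

    The lambda path has 100 log-spaced values from lambda_max down to
    lambda_max * 1e-4; lambda is chosen by K-fold cross-validated MSE with
    ties going to the smaller lambda.
    """
    config = config or FitConfig()
    subjects = tubules.subjects
    Xbar = np.stack(
        [tubules.features[rows].mean(axis=0) for rows in tubules.subject_row_indices().values()]
    )
    y = outcomes.select(subjects)
    mean = Xbar.mean(axis=0)
    scale = Xbar.std(axis=0)
    if np.any(scale == 0):
        j = int(np.flatnonzero(scale == 0)[0])
        raise DataError(
            f"zero variance in averaged feature column '{tubules.feature_names[j]}'"
        )
    Xs = (Xbar - mean) / scale
    y_mean = float(y.mean())
    y_c = y - y_mean
    grid = naive_lambda_grid(Xs, y_c)

    cv_seed = int(_seeds(config.seed, 1)[0])
    kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=cv_seed)
    errs = np.empty((grid.size, config.n_folds))
    for f, (tr, ho) in enumerate(kf.split(Xs)):
        # descend the path with warm starts, as the reference lasso path does
        model = Lasso(alpha=grid[0] / 2.0, fit_intercept=False, max_iter=50_000,
                      tol=1e-8, warm_start=True)
        for li, lam in enumerate(grid):
            model.alpha = lam / 2.0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Xs[tr], y_c[tr])
            errs[li, f] = np.mean((y_c[ho] - Xs[ho] @ model.coef_) ** 2)
    mean_err = errs.mean(axis=1)
    ties = np.flatnonzero(mean_err == mean_err.min())
    lam_best = float(grid[ties].min())  # ties -> smaller lambda
    beta = _naive_lasso(Xs, y_c, lam_best)
    cv_table = {
        "lambda": grid,
        "fold_mse_mean": mean_err,
        "fold_mse_sd": errs.std(axis=1, ddof=1),
    }
    return ModelArchive(
        method="naive",
        feature_names=list(tubules.feature_names),
        G=None,
        alpha=None,
        beta=beta,
        beta_normalized=normalize_threshold(beta, config.threshold),
        lam=lam_best,
        design_mean=mean,
        design_scale=scale,
        y_mean=y_mean,
        cluster_model=None,
        metadata=_archive_metadata(
            config, len(subjects), None, cv_table, {"lambda_max": float(grid[0])}
        ),
    )


def predict_naive(model: ModelArchive, tubules: TubuleTable) -> tuple[np.ndarray, np.ndarray]:
    """(subject_ids, predictions) for a fitted naive model on new tubules."""
    if model.method != "naive":
        raise DataError("predict_naive requires a naive model archive")
    if len(model.feature_names) != tubules.q:
        raise DataError("feature count mismatch between model and tubules")
    subjects = tubules.subjects
    Xbar = np.stack(
        [tubules.features[rows].mean(axis=0) for rows in tubules.subject_row_indices().values()]
    )
    Xs = (Xbar - model.design_mean) / model.design_scale
    return subjects, Xs @ model.beta + model.y_mean


@dataclass
class CorrespondenceResult:
    """Predictions under every training-to-test cluster correspondence.

    ``permutations[p][k]`` is the test cluster row placed in training cluster
    row ``k`` (0-based); with test outcomes available ``chosen`` is the
    permutation with the smallest test MSE.
    """

    subject_ids: np.ndarray
    permutations: list[tuple]
    predictions: dict
    mses: dict | None
    chosen: tuple | None
    dropped: DroppedSubjectReport
    labels: np.ndarray = field(default=None)


def predict_with_correspondence(
    model: ModelArchive,
    test_tubules: TubuleTable,
    test_outcomes: OutcomeVector | None = None,
    recluster: bool = False,
    seed: int | None = None,
) -> CorrespondenceResult:
    """Apply a fitted CLUSSO model to test tubules under all G! correspondences.

    Test tubules are labeled with the trained cluster model by default, or
    independently re-clustered with ``recluster=True``; designs are built and
    standardized with the *training* transform after each row permutation.
    """
    if model.method not in ("clusso", "full_info"):
        raise DataError("correspondence prediction requires a clusso/full_info model")
    if model.cluster_model is None:
        raise DataError("model archive carries no cluster model to label test tubules")
    if len(model.feature_names) != test_tubules.q:
        raise DataError("feature count mismatch between model and test tubules")
    cluster_model = ClusterModel.from_dict(model.cluster_model)
    if recluster:
        assignment = cluster_pooled(
            test_tubules,
            model.G,
            algorithm=cluster_model.algorithm,
            seed=cluster_model.seed if seed is None else seed,
            standardize_features=cluster_model.standardize,
        )
    else:
        assignment = assign_new(cluster_model, test_tubules)
    designs, dropped = build_design(test_tubules, assignment, model.G)
    ids, Xd = stack_designs(designs)
    transform = StandardizationTransform(
        mean=model.design_mean, scale=model.design_scale, y_mean=model.y_mean
    )
    y = test_outcomes.select(ids) if test_outcomes is not None else None

    predictions: dict = {}
    mses: dict | None = {} if y is not None else None
    for perm in itertools.permutations(range(model.G)):
        Xp = transform.apply(Xd[:, perm, :])
        pred = np.einsum("igq,g,q->i", Xp, model.alpha, model.beta) + model.y_mean
        predictions[perm] = pred
        if y is not None:
            mses[perm] = float(np.mean((y - pred) ** 2))
    chosen = min(mses, key=mses.get) if mses is not None else None
    return CorrespondenceResult(
        subject_ids=ids,
        permutations=list(predictions.keys()),
        predictions=predictions,
        mses=mses,
        chosen=chosen,
        dropped=dropped,
        labels=assignment.labels,
    )
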