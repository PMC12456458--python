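"""Synthetic data generation and the simulation/evaluation harness.

The generator emulates a digital-pathology cohort: each subject carries a
latent (G, q) matrix of cluster-mean tubular features, a cluster-proportion
vector, and a scalar outcome from the bilinear model
``y = alpha*' diag(w) X* beta* + eps``. Observed tubules are resampled rows
of the latent matrix (row k picked with probability w_k) plus additive
Gaussian measurement error with variance ``sigma2_R``.

Scenarios:

* ``two_cluster`` — rows drawn i.i.d. from N(2, 1) and N(5, 3); w1 uniform on
  {0.2, 0.3, ..., 0.8}. The reference setting.
* ``correlated`` — matrix-normal rows with row covariance
  [[1, sqrt(3)/2], [sqrt(3)/2, 3]] (tubule-tubule correlation 0.5) and
  identity column covariance.
* ``three_cluster`` — three latent subgroups N(2,1), N(5,3), N(7,3); probes
  misspecification when clustering into two groups.
* ``one_cluster`` — a single latent row with entries N(2, 3); clustering into
  two groups drops most subjects.

Throughout, "N(a, b)" is mean a and *variance* b. Tubule counts are discrete
uniform over H integers centered at ``mu_M``, with H the largest odd integer
<= sqrt(12*sigma2_M + 1) so the count variance approximates ``sigma2_M``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterModel, assign_new, clustering_accuracy
from .data_io import OutcomeVector, TubuleTable
from .estimators import FitConfig, fit_clusso, fit_full_info, fit_naive, predict_naive
from .structured_lasso import predict as sl_predict

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SCENARIOS",
    "sample_tubule_counts",
    "generate_truth",
    "generate_dataset",
    "selection_metrics",
    "simulate_replicate",
    "run_simulation",
    "ROW_CORRELATION",
]

SIGMA_R_ROW_COV = np.array([[1.0, np.sqrt(3.0) / 2.0], [np.sqrt(3.0) / 2.0, 3.0]])
#: tubule-tubule correlation implied by the matrix-normal row covariance
ROW_CORRELATION = float(
    SIGMA_R_ROW_COV[0, 1] / np.sqrt(SIGMA_R_ROW_COV[0, 0] * SIGMA_R_ROW_COV[1, 1])
)

SCENARIOS = {
    "two_cluster": 2,
    "correlated": 2,
    "three_cluster": 3,
    "one_cluster": 1,
}

_W1_SET = np.round(np.arange(2, 9) / 10.0, 1)  # {0.2, ..., 0.8}


@dataclass
class SimulationConfig:
    """One simulation setting; defaults match the reference conditions."""

    n: int = 500
    q: int = 10
    s_beta: float = 0.8
    sigma2_eps: float = 1.0
    sigma2_R: float = 1.0
    mu_M: float = 40.0
    sigma2_M: float = 5.0
    scenario: str = "two_cluster"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n < 1 or self.q < 1:
            raise ValueError("n and q must be >= 1")
        if not 0.0 <= self.s_beta <= 1.0:
            raise ValueError("s_beta must lie in [0, 1]")
        for name in ("sigma2_eps", "sigma2_R", "sigma2_M"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def G_true(self) -> int:
        return SCENARIOS[self.scenario]


@dataclass
class SimulationTruth:
    """Ground truth behind one generated dataset (oracle inputs)."""

    alpha_star: np.ndarray
    beta_star: np.ndarray
    subject_ids: np.ndarray
    w: np.ndarray  # (n, G_true)
    X_star: np.ndarray  # (n, G_true, q)
    X_dstar: np.ndarray  # (n, G_true, q) = diag(w) X_star
    y: np.ndarray
    epsilon: np.ndarray


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_tubule_counts(n: int, mu_M: float = 40.0, sigma2_M: float = 5.0, seed=0) -> np.ndarray:
    """Draw per-subject tubule counts from a discrete uniform on H integers.

    H is the largest odd integer <= sqrt(12*sigma2_M + 1); the support is
    {mu_M - (H-1)/2, ..., mu_M + (H-1)/2}, so E(p) = mu_M and
    Var(p) = (H^2 - 1)/12 approximates sigma2_M.
    """
    H = int(np.floor(np.sqrt(12.0 * sigma2_M + 1.0)))
    if H % 2 == 0:
        H -= 1
    H = max(H, 1)
    a = int(round(mu_M - (H - 1) / 2))
    b = int(round(mu_M + (H - 1) / 2))
    if a < 1:
        raise ValueError(f"count support lower bound {a} < 1; increase mu_M")
    return _rng(seed).integers(a, b + 1, size=n)


def generate_truth(q: int, s_beta: float, G_true: int = 2, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Draw (alpha*, beta*) once, shared across settings and repetitions.

    Entries are uniform on {1, 2, 3, 4}; exactly round(s_beta * q) components
    of beta* are then zeroed (chosen without replacement). Deterministic given
    the seed.
    """
    rng = _rng(seed)
    alpha = rng.integers(1, 5, size=G_true).astype(float)
    beta = rng.integers(1, 5, size=q).astype(float)
    n_zero = int(round(s_beta * q))
    if n_zero:
        beta[rng.choice(q, size=n_zero, replace=False)] = 0.0
    return alpha, beta


def _draw_latents(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-subject latent cluster-mean matrices, (n, G_true, q)."""
    n, q = config.n, config.q
    if config.scenario == "two_cluster":
        X = np.empty((n, 2, q))
        X[:, 0, :] = rng.normal(2.0, 1.0, size=(n, q))
        X[:, 1, :] = rng.normal(5.0, np.sqrt(3.0), size=(n, q))
    elif config.scenario == "correlated":
        L = np.linalg.cholesky(SIGMA_R_ROW_COV)
        Z = rng.standard_normal(size=(n, 2, q))
        X = np.array([[2.0], [5.0]]) + np.einsum("rs,nsq->nrq", L, Z)
    elif config.scenario == "three_cluster":
        X = np.empty((n, 3, q))
        X[:, 0, :] = rng.normal(2.0, 1.0, size=(n, q))
        X[:, 1, :] = rng.normal(5.0, np.sqrt(3.0), size=(n, q))
        X[:, 2, :] = rng.normal(7.0, np.sqrt(3.0), size=(n, q))
    else:  # one_cluster
        X = rng.normal(2.0, np.sqrt(3.0), size=(n, 1, q))
    return X


def _draw_weights(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n
    if config.scenario in ("two_cluster", "correlated"):
        w1 = rng.choice(_W1_SET, size=n)
        return np.round(np.stack([w1, 1.0 - w1], axis=1), 10)
    if config.scenario == "three_cluster":
        w = np.empty((n, 3))
        for i in range(n):
            w1 = rng.choice(np.round(np.arange(2, 7) / 10.0, 1))
            w2_set = np.round(np.arange(2, int(round((0.8 - w1) * 10)) + 1) / 10.0, 1)
            w2 = rng.choice(w2_set)
            w[i] = (w1, w2, round(1.0 - w1 - w2, 10))
        return w
    return np.ones((n, 1))


def generate_dataset(
    config: SimulationConfig, truth: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[TubuleTable, OutcomeVector, SimulationTruth, np.ndarray]:
    """Generate one synthetic cohort.

    Returns the observed tubule table, subject outcomes, the ground truth
    (for oracle fits and metrics), and the true per-tubule cluster labels
    (1-based, aligned to the tubule table rows). All randomness flows from
    ``config.seed``.
    """
    rng = _rng(config.seed)
    G = config.G_true
    if truth is None:
        truth = generate_truth(config.q, config.s_beta, G, seed=config.seed)
    alpha_star, beta_star = (np.asarray(v, dtype=float) for v in truth)
    if alpha_star.shape != (G,):
        raise ValueError(
            f"alpha* has length {len(alpha_star)} but scenario "
            f"{config.scenario!r} has {G} latent subgroups"
        )
    if beta_star.shape != (config.q,):
        raise ValueError("beta* length must equal q")

    X_star = _draw_latents(config, rng)
    w = _draw_weights(config, rng)
    X_dstar = w[:, :, None] * X_star
    eps = rng.normal(0.0, np.sqrt(config.sigma2_eps), size=config.n)
    y = np.einsum("g,ngq,q->n", alpha_star, X_dstar, beta_star) + eps
    counts = sample_tubule_counts(config.n, config.mu_M, config.sigma2_M, seed=rng)

    subject_ids = np.array([f"S{i + 1:05d}" for i in range(config.n)])
    sd_R = np.sqrt(config.sigma2_R)
    sub_col, obj_col, feat_blocks, label_blocks = [], [], [], []
    for i in range(config.n):
        p = int(counts[i])
        ks = rng.choice(G, size=p, p=w[i])
        T = X_star[i, ks, :] + rng.normal(0.0, sd_R, size=(p, config.q))
        sub_col.append(np.repeat(subject_ids[i], p))
        obj_col.append(np.arange(1, p + 1))
        feat_blocks.append(T)
        label_blocks.append(ks + 1)

    tubules = TubuleTable(
        np.concatenate(sub_col),
        np.concatenate(obj_col),
        np.vstack(feat_blocks),
        [f"feature_{j}" for j in range(config.q)],
    )
    outcomes = OutcomeVector(subject_ids, y)
    truth_obj = SimulationTruth(
        alpha_star=alpha_star,
        beta_star=beta_star,
        subject_ids=subject_ids,
        w=w,
        X_star=X_star,
        X_dstar=X_dstar,
        y=y,
        epsilon=eps,
    )
    return tubules, outcomes, truth_obj, np.concatenate(label_blocks)


def selection_metrics(beta_hat_thresholded, beta_star) -> tuple[float, float, float]:
    """(TPR, FPR, L1 bias) of a thresholded coefficient vector against truth.

    TPR is the fraction of truly nonzero components recovered; FPR the
    fraction of truly zero components selected. The bias is the L1 distance
    between the component-wise *magnitudes* of both vectors after
    L1-normalizing each (signs are not identifiable). Undefined rates
    (no nonzero or no zero truth entries) come back as NaN, not 0.
    """
    bh = np.asarray(beta_hat_thresholded, dtype=float)
    bs = np.asarray(beta_star, dtype=float)
    if bh.shape != bs.shape:
        raise ValueError("coefficient vectors must have equal length")
    nz = bs != 0
    tpr = float((bh[nz] != 0).mean()) if nz.any() else float("nan")
    fpr = float((bh[~nz] != 0).mean()) if (~nz).any() else float("nan")
    bh_n = np.abs(bh) / np.abs(bh).sum() if np.abs(bh).sum() > 0 else np.zeros_like(bh)
    bs_n = np.abs(bs) / np.abs(bs).sum() if np.abs(bs).sum() > 0 else np.zeros_like(bs)
    bias = float(np.abs(bh_n - bs_n).sum())
    return tpr, fpr, bias


def _in_sample_mse_structured(archive, X_std, y) -> float:
    pred = sl_predict((archive.alpha, archive.beta), X_std, archive.y_mean)
    return float(np.mean((y - pred) ** 2))


def simulate_replicate(
    config: SimulationConfig,
    methods=("clusso", "naive", "full_info"),
    fit_config: FitConfig | None = None,
) -> dict:
    """Generate one dataset and score each method on it.

    Returns ``{method: {"tpr", "fpr", "bias", "mse", "accuracy"}}`` (accuracy
    only for clusso). The fit seed is derived from the data seed so a
    replicate is fully reproducible from ``config.seed``.
    """
    base = fit_config or FitConfig()
    fit_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
    tubules, outcomes, truth, true_labels = generate_dataset(config)
    out: dict = {}
    for method in methods:
        fc = FitConfig(
            G=base.G if method != "full_info" else config.G_true,
            cluster_algorithm=base.cluster_algorithm,
            lambda_grid=base.lambda_grid,
            n_folds=base.n_folds,
            n_inits=base.n_inits,
            threshold=base.threshold,
            seed=fit_seed,
            standardize_features=base.standardize_features,
            tol=base.tol,
            max_iter=base.max_iter,
        )
        if method == "clusso":
            archive = fit_clusso(tubules, outcomes, fc)
            labels = assign_new(
                ClusterModel.from_dict(archive.cluster_model), tubules
            ).labels
            accuracy = clustering_accuracy(labels, true_labels, tubules.subject_ids)
            kept = [
                s
                for s in tubules.subjects.tolist()
                if s not in set(archive.metadata["dropped_subjects"])
            ]
            from .design import build_design, StandardizationTransform

            designs, _ = build_design(tubules, labels, fc.G)
            tr = StandardizationTransform(
                archive.design_mean, archive.design_scale, archive.y_mean
            )
            X_std = tr.apply(np.stack([d.X_dstar for d in designs]))
            y_kept = outcomes.select([d.subject_id for d in designs])
            mse = _in_sample_mse_structured(archive, X_std, y_kept)
        elif method == "full_info":
            archive = fit_full_info(truth, outcomes, fc)
            tr_mean, tr_scale = archive.design_mean, archive.design_scale
            X_std = (truth.X_dstar - tr_mean) / tr_scale
            mse = _in_sample_mse_structured(archive, X_std, truth.y)
            accuracy = float("nan")
        else:
            archive = fit_naive(tubules, outcomes, fc)
            _, pred = predict_naive(archive, tubules)
            mse = float(np.mean((outcomes.select(tubules.subjects) - pred) ** 2))
            accuracy = float("nan")
        tpr, fpr, bias = selection_metrics(archive.beta_normalized, truth.beta_star)
        out[method] = {
            "tpr": tpr,
            "fpr": fpr,
            "bias": bias,
            "mse": mse,
            "accuracy": accuracy,
        }
    return out


def _cache_key(config: SimulationConfig, methods, rep: int, master_seed: int) -> str:
    payload = json.dumps(
        {"config": asdict(config), "methods": list(methods), "rep": rep, "seed": master_seed},
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def run_simulation(
    configs,
    methods=("clusso", "naive", "full_info"),
    reps: int = 50,
    seed: int = 0,
    fit_config: FitConfig | None = None,
    cache_dir=None,
    verbose: bool = False,
) -> pd.DataFrame:
    """Replicate each setting and summarize method performance.

    Per (setting, method): the median of TPR/FPR/bias/MSE across repetitions,
    and for clustering accuracy the mean of per-replicate means. Per-rep seeds
    are spawned from the master seed with a (setting, rep) counter key, so
    each setting is independently reproducible; failed replicates are counted
    and excluded rather than silently dropped. With ``cache_dir`` set,
    per-replicate results are cached to disk and runs are resumable.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if isinstance(configs, SimulationConfig):
        configs = [configs]
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    rows = []
    for si, config in enumerate(configs):
        per_method: dict = {m: {k: [] for k in ("tpr", "fpr", "bias", "mse", "accuracy")} for m in methods}
        failures = 0
        for r in range(reps):
            rep_seed = int(
                np.random.SeedSequence(seed, spawn_key=(si, r)).generate_state(1)[0]
                % (2**31)
            )
            rep_config = SimulationConfig(**{**asdict(config), "seed": rep_seed})
            result = None
            cache_file = (
                cache / f"{_cache_key(config, methods, r, seed)}.json"
                if cache is not None
                else None
            )
            if cache_file is not None and cache_file.exists():
                result = json.loads(cache_file.read_text())
            if result is None:
                try:
                    result = simulate_replicate(rep_config, methods, fit_config)
                except Exception as exc:
                    failures += 1
                    if verbose:
                        print(f"setting {si} rep {r} failed: {exc}")
                    continue
                if cache_file is not None:
                    cache_file.write_text(json.dumps(result))
            for m in methods:
                for k, v in result[m].items():
                    per_method[m][k].append(v)
        for m in methods:
            vals = per_method[m]
            for metric in ("tpr", "fpr", "bias", "mse"):
                arr = np.asarray(vals[metric], dtype=float)
                value = float(np.nanmedian(arr)) if arr.size and not np.all(np.isnan(arr)) else float("nan")
                rows.append(
                    dict(
                        setting=si,
                        scenario=config.scenario,
                        n=config.n,
                        q=config.q,
                        s_beta=config.s_beta,
                        sigma2_R=config.sigma2_R,
                        method=m,
                        metric=metric,
                        value=value,
                        reps_used=int(np.sum(~np.isnan(arr))),
                        failures=failures,
                    )
                )
            acc = np.asarray(vals["accuracy"], dtype=float)
            acc_val = float(np.nanmean(acc)) if acc.size and not np.all(np.isnan(acc)) else float("nan")
            rows.append(
                dict(
                    setting=si,
                    scenario=config.scenario,
                    n=config.n,
                    q=config.q,
                    s_beta=config.s_beta,
                    sigma2_R=config.sigma2_R,
                    method=m,
                    metric="accuracy",
                    value=acc_val,
                    reps_used=int(np.sum(~np.isnan(acc))),
                    failures=failures,
                )
            )
    return pd.DataFrame(rows)
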