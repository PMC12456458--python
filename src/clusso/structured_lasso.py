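"""Constrained bilinear ("structured") lasso for scalar-on-matrix regression.

The model is ``y_i = alpha' X_i beta + eps_i`` with ``X_i`` a standardized
(G, q) design matrix per subject. The estimator minimizes

    (1/n) sum_i (y_i - alpha' X_i beta)^2 + lambda * ||beta||_1

over the identifiability set {||alpha||_1 = 1, sign of the largest-magnitude
beta component = +1}; the row effects alpha are not penalized. The problem is
biconvex and solved by alternating minimization:

* beta-step: with alpha fixed, ``z_i = X_i' alpha`` turns the problem into an
  ordinary lasso in beta, solved by cyclic coordinate descent with
  soft-thresholding;
* alpha-step: with beta fixed, ``v_i = X_i beta`` gives a least-squares
  problem in alpha. The row effects carry no penalty of their own, but the
  constraint ``||alpha||_1 = 1`` couples alpha's scale to beta's: rescaling
  ``(alpha, beta) <- (alpha/||alpha||_1, beta*||alpha||_1)`` leaves every
  fitted value unchanged while the penalty becomes
  ``lambda * ||beta||_1 * ||alpha||_1``. The alpha-step therefore minimizes
  ``(1/n)||y - V a||^2 + lambda*||beta||_1*||a||_1`` (a lasso with the
  constraint-induced weight) before rescaling back onto the constraint set;
  at lambda = 0 this reduces to plain least squares.

Each step is then a genuine descent step, so the objective is non-increasing
across iterations; the solver stops on a relative objective change below
``tol``.
Because alternating minimization reaches a stationary point rather than the
global minimum, ``solve_multi_init`` restarts from several random
initializations and keeps the best objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

__all__ = [
    "StructuredLassoError",
    "StructuredLassoSolution",
    "BoundInputs",
    "solve_single",
    "solve_multi_init",
    "cv_lambda",
    "normalize_threshold",
    "predict",
    "theoretical_bound",
]


class StructuredLassoError(RuntimeError):
    """Raised for degenerate solver states (rank-deficient alpha-step, ...)."""


@dataclass
class StructuredLassoSolution:
    """A fitted (alpha, beta) pair with solver diagnostics.

    ``trace`` records the objective after every alternating iteration and is
    non-increasing up to floating-point noise.
    """

    alpha: np.ndarray
    beta: np.ndarray
    lam: float
    objective: float
    n_iter: int
    converged: bool
    init_seed: int | None = None
    trace: np.ndarray | None = None


def _coerce_designs(designs) -> np.ndarray:
    """Accept an (n, G, q) array or a list of per-subject designs."""
    if isinstance(designs, np.ndarray):
        X = designs
    else:
        X = np.stack(
            [d.X_dstar if hasattr(d, "X_dstar") else np.asarray(d) for d in designs]
        )
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("designs must stack to an (n, G, q) array")
    return X


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _beta_step(
    Z: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float, max_sweeps: int = 10
) -> np.ndarray:
    """Cyclic coordinate descent for (1/n)||y - Z b||^2 + lam ||b||_1."""
    n, q = Z.shape
    beta = beta.copy()
    z2 = np.einsum("ij,ij->j", Z, Z)
    r = y - Z @ beta
    thresh = 0.5 * n * lam
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(q):
            bj = beta[j]
            if bj != 0.0:
                r += Z[:, j] * bj
            if z2[j] <= 0.0:
                beta[j] = 0.0
                continue
            rho = Z[:, j] @ r
            bj_new = _soft(rho, thresh) / z2[j]
            if bj_new != 0.0:
                r -= Z[:, j] * bj_new
            beta[j] = bj_new
            max_delta = max(max_delta, abs(bj_new - bj))
        if max_delta < 1e-10:
            break
    return beta


def _objective(X: np.ndarray, y: np.ndarray, alpha: np.ndarray, beta: np.ndarray, lam: float) -> float:
    fitted = np.einsum("igq,g,q->i", X, alpha, beta)
    return float(np.mean((y - fitted) ** 2) + lam * np.abs(beta).sum())


def _canonicalize_sign(alpha: np.ndarray, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip both vectors if the largest-|.| beta component (lowest index on
    ties) is negative; fitted values are unchanged."""
    if np.any(beta != 0):
        j = int(np.argmax(np.abs(beta)))
        if beta[j] < 0:
            return -alpha, -beta
    return alpha, beta


def solve_single(
    designs,
    y,
    lam: float,
    init: tuple[np.ndarray, np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 200,
) -> StructuredLassoSolution:
    """Alternating minimization from a single (alpha0, beta0) start."""
    X = _coerce_designs(designs)
    y = np.asarray(y, dtype=float)
    n, G, q = X.shape
    if y.shape != (n,):
        raise ValueError("y must have one entry per design")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    alpha = np.asarray(init[0], dtype=float).copy()
    beta = np.asarray(init[1], dtype=float).copy()
    if alpha.shape != (G,) or beta.shape != (q,):
        raise ValueError("init shapes must be (G,) and (q,)")
    a_norm = np.abs(alpha).sum()
    if a_norm == 0:
        raise StructuredLassoError("initial alpha has zero L1 norm")
    alpha /= a_norm

    obj = _objective(X, y, alpha, beta, lam)
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # beta-step: lasso in beta at fixed alpha
        Z = np.einsum("igq,g->iq", X, alpha)
        beta = _beta_step(Z, y, beta, lam)
        if not np.any(beta != 0):
            # alpha is unidentified at beta = 0; the objective is flat
            obj_new = float(np.mean(y**2))
            trace.append(obj_new)
            converged = True
            obj = obj_new
            break
        # alpha-step at fixed beta: lasso with the constraint-induced weight
        V = np.einsum("igq,q->ig", X, beta)
        lam_eff = lam * np.abs(beta).sum()
        if lam_eff == 0.0:
            VtV = V.T @ V
            if np.linalg.matrix_rank(VtV) < G:
                raise StructuredLassoError(
                    "alpha-step normal matrix is rank deficient; try another start"
                )
            alpha = np.linalg.solve(VtV, V.T @ y)
        else:
            alpha = _beta_step(V, y, alpha, lam_eff, max_sweeps=50)
        a_norm = np.abs(alpha).sum()
        if a_norm == 0:
            # the penalty shrank the whole bilinear term away
            beta = np.zeros_like(beta)
            obj = float(np.mean(y**2))
            trace.append(obj)
            converged = True
            break
        # rescale onto the constraint set; alpha' X beta is unchanged
        alpha /= a_norm
        beta *= a_norm
        obj_new = _objective(X, y, alpha, beta, lam)
        trace.append(obj_new)
        if abs(obj - obj_new) < tol * max(1.0, abs(obj)):
            obj = obj_new
            converged = True
            break
        obj = obj_new

    alpha, beta = _canonicalize_sign(alpha, beta)
    return StructuredLassoSolution(
        alpha=alpha,
        beta=beta,
        lam=float(lam),
        objective=obj,
        n_iter=it,
        converged=converged,
        trace=np.asarray(trace),
    )


def random_init(rng: np.random.Generator, G: int, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal start; alpha is L1-normalized."""
    while True:
        a0 = rng.standard_normal(G)
        if np.abs(a0).sum() > 0:
            break
    return a0 / np.abs(a0).sum(), rng.standard_normal(q)


def solve_multi_init(
    designs,
    y,
    lam: float,
    n_inits: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    extra_inits=None,
) -> StructuredLassoSolution:
    """Best-objective solution over ``n_inits`` random starts.

    ``extra_inits`` may carry additional (alpha0, beta0) candidate starts
    (e.g., warm starts from a neighboring lambda); they only ever lower the
    returned objective. Deterministic given ``seed``.
    """
    if n_inits < 1:
        raise ValueError("n_inits must be >= 1")
    X = _coerce_designs(designs)
    _, G, q = X.shape
    rng = np.random.default_rng(seed)
    inits = [random_init(rng, G, q) for _ in range(n_inits)]
    if extra_inits:
        inits.extend(extra_inits)
    best: StructuredLassoSolution | None = None
    last_err: Exception | None = None
    for a0, b0 in inits:
        try:
            sol = solve_single(X, y, lam, (a0, b0), tol=tol, max_iter=max_iter)
        except StructuredLassoError as exc:
            last_err = exc
            continue
        if best is None or sol.objective < best.objective:
            best = sol
    if best is None:
        raise last_err if last_err is not None else StructuredLassoError("no start succeeded")
    best.init_seed = int(seed)
    return best


def cv_lambda(
    designs,
    y,
    lambda_grid,
    n_folds: int = 5,
    seed: int = 0,
    n_inits: int = 5,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[float, pd.DataFrame]:
    """Pick lambda by K-fold cross-validated held-out MSE.

    Subjects are shuffled into folds with the given seed; for every lambda
    (ascending) each fold's model is fit with ``n_inits`` random starts plus a
    warm start from the previous lambda, and the mean held-out squared error
    decides. Ties go to the smaller lambda.
    """
    X = _coerce_designs(designs)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("lambda grid must be ascending")
    n = len(y)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n < n_folds:
        raise ValueError("fewer subjects than folds")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**31))
    fold_seeds = np.random.SeedSequence(seed).generate_state(n_folds) % (2**31)
    errs = np.full((grid.size, n_folds), np.nan)
    for f, (tr, ho) in enumerate(kf.split(np.arange(n))):
        if len(tr) < 2:
            raise ValueError("fold with fewer than 2 training subjects")
        warm = None
        for li, lam in enumerate(grid):
            sol = solve_multi_init(
                X[tr],
                y[tr],
                lam,
                n_inits=n_inits,
                seed=int(fold_seeds[f]),
                tol=tol,
                max_iter=max_iter,
                extra_inits=[warm] if warm is not None else None,
            )
            warm = (sol.alpha, sol.beta)
            pred = np.einsum("igq,g,q->i", X[ho], sol.alpha, sol.beta)
            errs[li, f] = np.mean((y[ho] - pred) ** 2)
    mean = errs.mean(axis=1)
    best = int(np.argmin(mean))  # first minimum -> smaller lambda on ties
    table = pd.DataFrame(
        {
            "lambda": grid,
            "fold_mse_mean": mean,
            "fold_mse_sd": errs.std(axis=1, ddof=1),
        }
    )
    return float(grid[best]), table


def normalize_threshold(beta: np.ndarray, threshold: float = 0.001) -> np.ndarray:
    """L1-normalize beta, then zero components below ``threshold`` in magnitude.

    The result is *not* renormalized after zeroing; a zero vector passes
    through unchanged.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    beta = np.asarray(beta, dtype=float).copy()
    l1 = np.abs(beta).sum()
    if l1 > 0:
        beta = beta / l1
    beta[np.abs(beta) < threshold] = 0.0
    return beta


def predict(solution, designs, y_train_mean: float = 0.0) -> np.ndarray:
    """Fitted values ``alpha' X_i beta + y_train_mean`` on standardized designs."""
    if isinstance(solution, StructuredLassoSolution):
        alpha, beta = solution.alpha, solution.beta
    else:
        alpha, beta = solution
    X = _coerce_designs(designs)
    if X.shape[1] != len(alpha) or X.shape[2] != len(beta):
        raise ValueError("design dimensions do not match (alpha, beta)")
    return np.einsum("igq,g,q->i", X, alpha, beta) + y_train_mean


@dataclass
class BoundInputs:
    """Inputs to the theoretical L1 estimation-error bound.

    ``kappa2`` is the structured restricted-eigenvalue constant
    kappa^2(s0, 3); ``s0`` is the support size of theta = beta* (x) alpha*.
    """

    delta0: float
    a: float
    sigma: float
    G: int
    q: int
    n: int
    kappa2: float
    s0: int
    beta_star: np.ndarray

    def __post_init__(self) -> None:
        self.beta_star = np.asarray(self.beta_star, dtype=float)
        for name in ("delta0", "a", "sigma", "kappa2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.G < 1 or self.q < 1 or self.n < 1:
            raise ValueError("G, q, n must be >= 1")
        if not 0 <= self.s0 <= self.G * self.q:
            raise ValueError("s0 must lie in [0, G*q]")


def theoretical_bound(inputs: BoundInputs) -> tuple[float, float]:
    """Oracle regularization level and L1 error bound for the full-information fit.

    lambda_n = (1 + delta0) * sigma * sqrt(2 (1 + a) log(G q) / n), and the
    bound is 4 kappa^2 * lambda_n * s0 * (1 + 2 ||beta*||_1 / beta*_(1)),
    where beta*_(1) is the largest-magnitude component of beta* (assumed
    positive under the sign canonicalization).
    """
    b = inputs.beta_star
    if not np.any(b != 0):
        raise ValueError("beta_star must not be identically zero")
    beta_top = b[int(np.argmax(np.abs(b)))]
    lambda_n = (1.0 + inputs.delta0) * inputs.sigma * np.sqrt(
        2.0 * (1.0 + inputs.a) * np.log(inputs.G * inputs.q) / inputs.n
    )
    B0 = 4.0 * inputs.kappa2
    bound = B0 * lambda_n * inputs.s0 * (1.0 + 2.0 * np.abs(b).sum() / beta_top)
    return float(lambda_n), float(bound)
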