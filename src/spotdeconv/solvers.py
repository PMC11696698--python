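"""Weight estimators for the linear mixing model Y = M X + E.

Y (spots x genes) holds spatial counts, X (cells x genes) the reference
prototype profiles, and M (spots x cells) the unknown per-spot prototype
weights. Two estimators are provided:

* :func:`ols_estimate` — the closed form  M = Y X^T (X X^T)^{-1}  (entries
  may be negative; rank-deficient X falls back to the minimum-norm
  pseudo-inverse solution, recorded on the result);
* :func:`nnls_estimate` — ridge-penalized non-negative least squares

      argmin_{M >= 0}  1/2 ||Y - M X||_F^2 + lambda/2 ||M||_F^2

  solved by projected gradient descent with a fixed step size: gradient
  step on the smooth objective, then elementwise clamp at zero. The
  objective is convex, so the iteration converges to the global minimum
  for step sizes below 2 / (sigma_max(X)^2 + lambda).

The ridge parameter can be selected by :func:`cross_validate_lambda`,
which splits *genes* (columns) into folds, fits on the training columns
and scores reconstruction of the held-out columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import CVReport, PrototypeWeights

__all__ = [
    "SolverConfig",
    "DEFAULT_LAMBDA_GRID",
    "ols_estimate",
    "nnls_objective",
    "nnls_estimate",
    "cross_validate_lambda",
]

#: Grid used when cross-validating the ridge parameter: 0, 0.02, ..., 0.2.
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0, 0.21, 0.02), 2))


@dataclass
class SolverConfig:
    """Settings for the projected-gradient solver and ridge selection.

    ``ridge_lambda`` may be a scalar (used directly) or a sequence of
    candidate values (selected by gene-split cross-validation).
    """

    learning_rate: float = 0.1
    num_epochs: int = 1000
    ridge_lambda: float | Sequence[float] = 0.1
    n_fold: int = 5
    warm_start: bool = True
    seed: int = 0
    device: str = "cpu"  # opaque hint; results are backend-independent

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.num_epochs < 1:
            raise ValueError("num_epochs must be >= 1")
        grid = np.atleast_1d(np.asarray(self.ridge_lambda, dtype=float))
        if np.any(grid < 0):
            raise ValueError("ridge penalty values must be non-negative")
        if self.n_fold < 1:
            raise ValueError("n_fold must be >= 1")

    @property
    def lambda_grid(self) -> np.ndarray:
        return np.sort(np.atleast_1d(np.asarray(self.ridge_lambda, dtype=float)))


def _check_shapes(Y: np.ndarray, X: np.ndarray) -> None:
    if Y.ndim != 2 or X.ndim != 2:
        raise ValueError("Y and X must be 2-dimensional")
    if Y.shape[1] != X.shape[1]:
        raise ValueError(
            f"gene dimensions differ: Y has {Y.shape[1]}, X has {X.shape[1]}"
        )


def ols_estimate(Y: np.ndarray, X: np.ndarray) -> PrototypeWeights:
    """Closed-form least squares M = Y X^T (X X^T)^{-1}.

    When X X^T is singular (rank-deficient X), the minimum-norm solution via
    the pseudo-inverse is returned and ``pinv_fallback`` is set.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_shapes(Y, X)
    G = X @ X.T
    fallback = np.linalg.matrix_rank(X) < X.shape[0]
    if fallback:
        # min ||Y - M X||_F over M: solve X^T M^T = Y^T in the least-squares
        # sense; lstsq returns the minimum-norm M, i.e. the pseudo-inverse route
        M = np.linalg.lstsq(X.T, Y.T, rcond=None)[0].T
    else:
        M = np.linalg.solve(G, X @ Y.T).T
    return PrototypeWeights(weights=M, estimator="OLS", pinv_fallback=fallback)


def nnls_objective(M: np.ndarray, Y: np.ndarray, X: np.ndarray, lam: float = 0.0) -> float:
    """Ridge-penalized least-squares objective 1/2||Y - MX||_F^2 + lam/2||M||_F^2."""
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_shapes(Y, X)
    if M.shape != (Y.shape[0], X.shape[0]):
        raise ValueError(f"M shape {M.shape} incompatible with ({Y.shape[0]}, {X.shape[0]})")
    resid = Y - M @ X
    return 0.5 * float(np.sum(resid * resid)) + 0.5 * lam * float(np.sum(M * M))


def nnls_estimate(
    Y: np.ndarray,
    X: np.ndarray,
    cfg: SolverConfig | None = None,
    lam: float | None = None,
    record_objective: bool = False,
) -> PrototypeWeights:
    """Non-negative ridge regression by projected gradient descent.

    Runs exactly ``cfg.num_epochs`` iterations of

        M <- max(M - lr * ((M X - Y) X^T + lam * M), 0)

    starting from the elementwise-clamped OLS solution (``warm_start``) or
    from zero. Convergence is not monitored inside the loop; optimality is a
    property of the returned iterate (see the KKT tests).

    Raises
    ------
    FloatingPointError
        If the iterates leave the representable range, which for this fixed
        step scheme indicates a too-large ``learning_rate``.
    """
    cfg = cfg or SolverConfig()
    if lam is None:
        grid = cfg.lambda_grid
        if grid.size != 1:
            raise ValueError("scalar ridge penalty required; pass lam or use cross_validate_lambda")
        lam = float(grid[0])
    if lam < 0:
        raise ValueError("ridge penalty must be non-negative")
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_shapes(Y, X)
    if cfg.warm_start:
        M = np.maximum(ols_estimate(Y, X).weights, 0.0)
    else:
        M = np.zeros((Y.shape[0], X.shape[0]))
    Xt = X.T
    lr = cfg.learning_rate
    trace = [] if record_objective else None
    every = max(1, cfg.num_epochs // 20)
    with np.errstate(over="ignore", invalid="ignore"):  # divergence is raised, not warned
        for epoch in range(cfg.num_epochs):
            grad = (M @ X - Y) @ Xt + lam * M
            M = np.maximum(M - lr * grad, 0.0)
            if not np.all(np.isfinite(M)):
                raise FloatingPointError(
                    "projected gradient descent diverged (non-finite weights); "
                    "reduce learning_rate"
                )
            if trace is not None and (epoch + 1) % every == 0:
                trace.append(nnls_objective(M, Y, X, lam))
    return PrototypeWeights(
        weights=M,
        estimator="NNLS",
        lambda_used=lam,
        objective_trace=np.asarray(trace) if trace is not None else None,
    )


def cross_validate_lambda(
    Y: np.ndarray, X: np.ndarray, cfg: SolverConfig | None = None
) -> CVReport:
    """Select the ridge penalty by splitting genes (columns) into folds.

    Genes are shuffled once with ``cfg.seed`` and split into ``n_fold``
    contiguous blocks. For each candidate lambda and each fold, the model is
    fit on the training columns and scored on the held-out columns by

        MMSE(lambda) = 1 / (2 n_test) * ||Y_test - M_train X_test||_F^2 .

    The grid value with the smallest mean across folds wins; ties break
    toward the smaller lambda.
    """
    cfg = cfg or SolverConfig(ridge_lambda=DEFAULT_LAMBDA_GRID)
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_shapes(Y, X)
    grid = cfg.lambda_grid
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    n_genes = X.shape[1]
    if n_genes < cfg.n_fold:
        raise ValueError(f"{n_genes} genes cannot be split into {cfg.n_fold} folds")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n_genes)
    folds = np.array_split(perm, cfg.n_fold)
    fold_mse = np.empty((grid.size, cfg.n_fold))
    for j, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        Xtr, Xte = X[:, train_idx], X[:, test_idx]
        Ytr, Yte = Y[:, train_idx], Y[:, test_idx]
        for i, lam in enumerate(grid):
            M = nnls_estimate(Ytr, Xtr, cfg, lam=float(lam)).weights
            resid = Yte - M @ Xte
            fold_mse[i, j] = 0.5 / test_idx.size * float(np.sum(resid * resid))
    mean_mse = fold_mse.mean(axis=1)
    selected = float(grid[int(np.argmin(mean_mse))])  # first min = smallest lambda
    return CVReport(
        lambda_grid=grid, fold_mse=fold_mse, mean_mse=mean_mse, selected_lambda=selected
    )
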