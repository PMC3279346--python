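"""Penalty selection: per-gene lambda_max, kappa schedules, LOOCV.

Every gene's useful penalty range is ``[0, lambda_max_j]``: at 0 the fit is
ordinary least squares, at ``lambda_max_j`` the optimum coefficient vector is
identically zero.  Rather than tuning one penalty per gene (prone to
overfitting), a single fraction ``kappa`` in (0, 1] is shared by all genes and
two schedules are offered:

* global: ``lambda_j = kappa * Lambda`` with one ``Lambda = max_j
  lambda_max_j`` for every gene, making per-gene scores comparable;
* local:  ``lambda_j = kappa * lambda_max_j`` per gene.

``kappa`` is chosen by leave-one-out cross-validation over a fixed grid
{1/10000, 1/100, 1/50, 1/20, 1/10, 1/5, 1/3, 1/2}: each sample is held out
in turn, penalties are recomputed on the remaining samples (so the held-out
sample never leaks into the schedule), every gene is refit, and the squared
prediction error on the held-out sample is accumulated.  The selected kappa
minimizes the mean squared error over all (gene, sample) terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .data_io import ExpressionMatrix
from .solver import active_rows, solve_gene

#: The kappa grid used for LOOCV selection.
DEFAULT_KAPPA_GRID: tuple[float, ...] = (
    1 / 10000, 1 / 100, 1 / 50, 1 / 20, 1 / 10, 1 / 5, 1 / 3, 1 / 2)


@dataclass
class PenaltyConfig:
    """A per-gene penalty schedule ``lambda_j = kappa * Lambda_j``."""

    method: str                 # "global" or "local"
    kappa: float
    Lambda: np.ndarray          # per-gene ceiling Lambda_j
    lambdas: np.ndarray         # per-gene penalty lambda_j = kappa * Lambda_j


@dataclass
class CVResult:
    """LOOCV error per kappa and the selected value."""

    mse_by_kappa: dict[float, float]
    selected_kappa: float


def lambda_max(x: np.ndarray, Z: np.ndarray) -> float:
    """Smallest penalty for which beta = 0 is optimal for one gene.

    From the stationarity condition on the non-positive orthant with the
    plain-RSS loss: beta = 0 is optimal iff ``lam >= -2 * z_k.(x - mean(x))``
    for every regulator k, so the ceiling is the largest of these (clamped at
    0).  Zero-variance rows of Z are ignored, exactly as in the solver.
    """
    x = np.asarray(x, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] == 0:
        return 0.0
    act = active_rows(Z)
    if not act.any() or x.max() == x.min():
        return 0.0
    # identical float expressions to the solver's first sweep (exact boundary)
    zx = Z @ x
    s = Z.sum(axis=1)
    x0 = x.sum() / x.shape[0]
    d = zx - x0 * s
    m = float((-2.0 * d[act]).max())
    return m if m > 0.0 else 0.0


def lambda_max_all(X: ExpressionMatrix, Z: ExpressionMatrix,
                   C: sparse.spmatrix) -> np.ndarray:
    """Per-gene lambda_max for every row of X given the mask C."""
    C = sparse.csr_matrix(C)
    out = np.zeros(X.n_features)
    for j in range(X.n_features):
        idx = C.indices[C.indptr[j]:C.indptr[j + 1]]
        if idx.size:
            out[j] = lambda_max(X.values[j], Z.values[idx])
    return out


def penalty_schedule(lmax: np.ndarray, kappa: float,
                     method: str = "global") -> PenaltyConfig:
    """Build per-gene penalties from the per-gene ceilings and a fraction."""
    lmax = np.asarray(lmax, dtype=float)
    if (lmax < 0).any():
        raise ValueError("lambda_max values must be non-negative")
    if not 0 < kappa <= 1:
        raise ValueError("kappa must lie in (0, 1]")
    if method == "global":
        Lambda = np.full_like(lmax, lmax.max() if lmax.size else 0.0)
    elif method == "local":
        Lambda = lmax.copy()
    else:
        raise ValueError(f"unknown method {method!r}")
    if lmax.size and lmax.max() == 0.0:
        warnings.warn("all lambda_max are zero: no negative-regulation signal",
                      stacklevel=2)
    return PenaltyConfig(method, float(kappa), Lambda, kappa * Lambda)


def loocv_select(X: ExpressionMatrix, Z: ExpressionMatrix,
                 C: sparse.spmatrix,
                 grid: tuple[float, ...] = DEFAULT_KAPPA_GRID,
                 method: str = "global", *, tol: float = 1e-8,
                 max_iter: int = 10_000,
                 nonpositive: bool = True) -> CVResult:
    """Select kappa by leave-one-out cross-validation.

    For each held-out sample the per-gene ceilings (and the global Lambda)
    are recomputed on the training samples.  Within a fold, kappas are
    visited from largest to smallest with warm-started coefficients, which
    does not change the (deterministic) result, only the runtime.  The MSE
    denominator is the number of prediction terms, J * I.
    """
    grid = tuple(float(k) for k in grid)
    if not grid:
        raise ValueError("kappa grid is empty")
    if any(not 0 < k <= 1 for k in grid):
        raise ValueError("kappa grid values must lie in (0, 1]")
    I = X.n_samples
    if I < 3:
        raise ValueError("LOOCV requires at least 3 samples "
                         "(a 1-sample training set cannot be centered)")
    C = sparse.csr_matrix(C)
    J = X.n_features
    active = [C.indices[C.indptr[j]:C.indptr[j + 1]] for j in range(J)]
    desc = sorted(set(grid), reverse=True)

    sse = {k: 0.0 for k in desc}
    for i in range(I):
        tr = np.ones(I, dtype=bool)
        tr[i] = False
        Xtr = X.values[:, tr]
        Ztr = Z.values[:, tr]
        lmax = np.zeros(J)
        for j in range(J):
            if active[j].size:
                lmax[j] = lambda_max(Xtr[j], Ztr[active[j]])
        Lam = lmax.max() if method == "global" else None

        warm: list[np.ndarray | None] = [None] * J
        for kappa in desc:
            for j in range(J):
                idx = active[j]
                if idx.size == 0:
                    pred = Xtr[j].mean()
                else:
                    lam_j = kappa * (Lam if method == "global" else lmax[j])
                    sol = solve_gene(Xtr[j], Ztr[idx], lam_j, tol=tol,
                                     max_iter=max_iter,
                                     nonpositive=nonpositive,
                                     beta0=warm[j])
                    warm[j] = sol.beta
                    pred = sol.intercept + sol.beta @ Z.values[idx, i]
                err = X.values[j, i] - pred
                sse[kappa] += err * err

    denom = J * I
    mse = {k: float(sse[k] / denom) for k in grid}
    best = grid[0]
    for k in grid:
        if mse[k] < mse[best]:
            best = k
    return CVResult(mse_by_kappa=mse, selected_kappa=best)
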