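"""Per-gene L1-penalized least squares with non-positive coefficients.

For one mRNA with centered log-expression ``x`` (length I) and the expression
rows ``Z`` of its K_j putative miRNA regulators, the fitted model is

    minimize  || x - x0*1 - sum_k beta_k z_k ||^2  +  lam * sum_k |beta_k|
    subject to  beta_k <= 0  for all k,

with an unpenalized intercept ``x0``.  Because every beta_k is non-positive,
the L1 penalty equals ``-lam * sum_k beta_k`` and the problem is a smooth
convex quadratic over the non-positive orthant: any local minimum is global.

The solver is cyclic coordinate descent.  Each coordinate has the closed-form
update ``beta_k = min(0, (2 z_k.r_{-k} + lam) / (2 ||z_k||^2))`` where
``r_{-k}`` is the residual excluding beta_k's own contribution; the intercept
is reset to the mean residual at the start of every sweep.  Rows of Z with
zero variance carry no information beyond the intercept and are frozen at 0.

The plain residual-sum-of-squares convention (no 1/2 or 1/I factor) is used
throughout, so that the per-gene penalty ceiling lambda_max computed in
:mod:`talasso.tuning` is exactly the smallest ``lam`` yielding beta = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .data_io import ExpressionMatrix


@dataclass
class PerGeneSolution:
    """Solution of the penalized problem for a single mRNA."""

    beta: np.ndarray          # length K_j, all entries <= 0 (constrained mode)
    intercept: float          # unpenalized x0
    objective: float          # attained value of the penalized objective
    iterations: int           # coordinate-descent sweeps used
    converged: bool


@dataclass
class FitResult:
    """Fits for all mRNAs: sparse coefficient matrix plus diagnostics."""

    mrna_ids: list[str]
    mirna_ids: list[str]
    beta: sparse.csr_matrix        # J x K, nonzeros only where C = 1
    intercepts: np.ndarray         # length J
    objectives: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray          # bool per gene
    lambdas: np.ndarray


def active_rows(Z: np.ndarray) -> np.ndarray:
    """Boolean mask of Z rows with nonzero variance (informative regressors).

    Constant rows (including all-zero) are collinear with the intercept and
    are excluded from coordinate updates; the same mask is applied when
    computing lambda_max so the two stay consistent.
    """
    Z = np.atleast_2d(Z)
    return (Z.max(axis=1) - Z.min(axis=1)) > 0


def objective_value(x: np.ndarray, Z: np.ndarray, beta: np.ndarray,
                    intercept: float, lam: float) -> float:
    """Penalized objective  ||x - x0 - Z'beta||^2 + lam*||beta||_1."""
    r = x - intercept - beta @ Z
    return float(r @ r + lam * np.abs(beta).sum())


def solve_gene(x: np.ndarray, Z: np.ndarray, lam: float, *,
               tol: float = 1e-8, max_iter: int = 10_000,
               nonpositive: bool = True,
               beta0: np.ndarray | None = None) -> PerGeneSolution:
    """Solve the penalized regression for one mRNA.

    Parameters
    ----------
    x : array of shape (I,)
        The mRNA's (centered) log-expression across samples.
    Z : array of shape (K_j, I)
        Log-expression of the putative regulators, one row per miRNA.
    lam : float
        Non-negative L1 penalty.
    tol : float
        Convergence: largest absolute coefficient change in a sweep.
    nonpositive : bool
        If True (default), constrain beta <= 0.  ``False`` gives ordinary
        unconstrained LASSO (used only for method comparison).
    beta0 : array, optional
        Warm-start coefficients (clipped to feasibility).
    """
    x = np.asarray(x, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    K, I = Z.shape
    if x.shape[0] != I:
        raise ValueError(f"x has {x.shape[0]} samples but Z has {I}")
    if I < 2:
        raise ValueError("at least 2 samples are required")
    if not np.isfinite(x).all() or not np.isfinite(Z).all():
        raise ValueError("NaN or infinite values in solver inputs")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if tol <= 0:
        raise ValueError("tol must be positive")

    act = np.flatnonzero(active_rows(Z))
    sx = float(x.sum())
    if act.size == 0:
        x0 = sx / I
        return PerGeneSolution(np.zeros(K), x0,
                               objective_value(x, Z, np.zeros(K), x0, lam),
                               0, True)

    G = Z @ Z.T                     # gram matrix, K x K
    zx = Z @ x
    s = Z.sum(axis=1)
    diag = np.diag(G)

    beta = np.zeros(K)
    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float).copy()
        if nonpositive:
            beta = np.minimum(beta, 0.0)
        beta[~np.isin(np.arange(K), act)] = 0.0
    Gb = G @ beta

    x0 = (sx - s @ beta) / I
    prev_obj = objective_value(x, Z, beta, x0, lam)
    converged = False
    sweeps = 0
    for sweeps in range(1, max_iter + 1):
        x0 = (sx - s @ beta) / I
        max_delta = 0.0
        for k in act:
            rho = zx[k] - x0 * s[k] - Gb[k] + diag[k] * beta[k]
            if nonpositive:
                new = (2.0 * rho + lam) / (2.0 * diag[k])
                if new > 0.0:
                    new = 0.0
            else:
                a = 2.0 * rho
                if a > lam:
                    new = (a - lam) / (2.0 * diag[k])
                elif a < -lam:
                    new = (a + lam) / (2.0 * diag[k])
                else:
                    new = 0.0
            delta = new - beta[k]
            if delta != 0.0:
                Gb += delta * G[:, k]
                beta[k] = new
                ad = abs(delta)
                if ad > max_delta:
                    max_delta = ad
        obj = objective_value(x, Z, beta, x0, lam)
        if max_delta < tol or abs(prev_obj - obj) <= 1e-10 * max(1.0, abs(prev_obj)):
            converged = True
            break
        prev_obj = obj

    x0 = (sx - s @ beta) / I
    obj = objective_value(x, Z, beta, x0, lam)
    if not converged:
        warnings.warn(f"coordinate descent did not converge in {max_iter} "
                      "sweeps", stacklevel=2)
    return PerGeneSolution(beta, float(x0), obj, sweeps, converged)


def fit_all(X: ExpressionMatrix, Z: ExpressionMatrix, C: sparse.spmatrix,
            lambdas: np.ndarray | float, *, tol: float = 1e-8,
            max_iter: int = 10_000, nonpositive: bool = True) -> FitResult:
    """Fit every mRNA against its putative regulators.

    ``C`` is the J x K binary indicator from :func:`talasso.data_io.align`;
    ``lambdas`` is a per-gene penalty vector (or a scalar broadcast to all
    genes).  Genes with no putative regulator get an empty beta row and an
    intercept equal to their mean expression.
    """
    C = sparse.csr_matrix(C)
    J, K = C.shape
    if X.n_features != J or Z.n_features != K:
        raise ValueError("C shape inconsistent with expression matrices")
    if X.n_samples != Z.n_samples:
        raise ValueError("sample counts differ between X and Z")
    lambdas = np.broadcast_to(np.asarray(lambdas, dtype=float), (J,)).copy()

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    intercepts = np.empty(J)
    objectives = np.empty(J)
    iterations = np.zeros(J, dtype=int)
    converged = np.ones(J, dtype=bool)
    Zv = Z.values
    for j in range(J):
        idx = C.indices[C.indptr[j]:C.indptr[j + 1]]
        xj = X.values[j]
        if idx.size == 0:
            intercepts[j] = xj.mean()
            objectives[j] = float(((xj - intercepts[j]) ** 2).sum())
            continue
        try:
            sol = solve_gene(xj, Zv[idx], float(lambdas[j]), tol=tol,
                             max_iter=max_iter, nonpositive=nonpositive)
        except ValueError as exc:
            raise ValueError(f"gene {X.feature_ids[j]!r}: {exc}") from exc
        nz = np.flatnonzero(sol.beta)
        if nz.size:
            rows.append(np.full(nz.size, j))
            cols.append(idx[nz])
            vals.append(sol.beta[nz])
        intercepts[j] = sol.intercept
        objectives[j] = sol.objective
        iterations[j] = sol.iterations
        converged[j] = sol.converged

    if rows:
        beta = sparse.csr_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))), shape=(J, K))
    else:
        beta = sparse.csr_matrix((J, K))
    return FitResult(list(X.feature_ids), list(Z.feature_ids), beta,
                     intercepts, objectives, iterations, converged, lambdas)
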