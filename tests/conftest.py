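"""Shared test helpers: an independent exact QP oracle and problem makers."""

from itertools import combinations

import numpy as np
import pytest

import talasso as tl


def oracle_objective(x: np.ndarray, Z: np.ndarray, lam: float) -> float:
    """Exact global optimum of the non-positive penalized problem.

    Independent of the package's coordinate descent: enumerate every support
    set, solve the stationarity system of the smooth problem restricted to
    that support, clip to the feasible orthant, re-optimize the intercept and
    evaluate the objective.  The true optimum's support appears among the
    enumerated sets with an interior (uncut) solution, so the minimum over
    all candidates is the exact optimum.  Exponential in K: use for K <= 10.
    """
    x = np.asarray(x, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    K, I = Z.shape
    act = np.flatnonzero((Z.max(axis=1) - Z.min(axis=1)) > 0)
    best = np.inf
    for r in range(len(act) + 1):
        for S in combinations(act, r):
            S = list(S)
            D = np.column_stack([np.ones(I)] + [Z[k] for k in S])
            rhs = D.T @ x
            rhs[1:] += lam / 2.0          # gradient of -lam*sum(beta)
            theta, *_ = np.linalg.lstsq(D.T @ D, rhs, rcond=None)
            beta = np.zeros(K)
            beta[S] = np.minimum(theta[1:], 0.0)
            x0 = float(np.mean(x - beta @ Z))
            resid = x - x0 - beta @ Z
            best = min(best, float(resid @ resid + lam * np.abs(beta).sum()))
    return best


def random_problem(rng, I_range=(3, 10), K_range=(1, 8), lam_scale=5.0):
    """A random per-gene instance (x, Z, lam)."""
    I = int(rng.integers(I_range[0], I_range[1] + 1))
    K = int(rng.integers(K_range[0], K_range[1] + 1))
    x = rng.standard_normal(I) * rng.uniform(0.5, 3.0)
    Z = rng.standard_normal((K, I))
    lam = float(rng.uniform(0.0, lam_scale))
    return x, Z, lam


def pipeline_align(truth):
    """median-center both matrices of a SyntheticTruth and align with its mask."""
    X = tl.median_center(truth.mrna)
    Z = tl.median_center(truth.mirna)
    return tl.align(X, Z, truth.mask)


@pytest.fixture
def tmp_truth(tmp_path):
    """A small synthetic dataset written to disk as the standard TSV files."""
    truth = tl.generate(12, 6, 10, putative_per_gene=3, true_per_gene=1,
                        noise_sd=0.2, seed=5)
    paths = truth.write(tmp_path / "fixture")
    return truth, paths
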