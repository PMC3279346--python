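"""Ranked interaction lists and post-selection coefficient statistics.

Rankings are plain pandas DataFrames with columns
``mRNA_id, miRNA_id, score, rank, method`` — most strongly down-regulating
first.  Two scores are provided: the fitted coefficient beta (the method's
own score) and the signed Pearson correlation baseline (most negative r
first; the signed form outperforms |r|, which cannot distinguish up- from
down-regulation).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .data_io import ExpressionMatrix
from .solver import FitResult

RANK_COLUMNS = ["mRNA_id", "miRNA_id", "score", "rank", "method"]


def _finalize(entries: list[tuple[str, str, float]], method: str) -> pd.DataFrame:
    """Sort ascending by score with lexicographic (mRNA, miRNA) tie-break."""
    entries.sort(key=lambda e: (e[2], e[0], e[1]))
    df = pd.DataFrame(entries, columns=["mRNA_id", "miRNA_id", "score"])
    df["rank"] = np.arange(1, len(df) + 1)
    df["method"] = method
    return df


def rank_talasso(fit: FitResult, method_label: str = "talasso") -> pd.DataFrame:
    """Rank fitted interactions by coefficient, most negative beta first.

    Only strictly negative coefficients appear (beta = 0 means the penalty
    removed the interaction).
    """
    coo = sparse.coo_matrix(fit.beta)
    entries = [
        (fit.mrna_ids[j], fit.mirna_ids[k], float(v))
        for j, k, v in zip(coo.row, coo.col, coo.data) if v < 0
    ]
    return _finalize(entries, method_label)


def rank_correlation(X: ExpressionMatrix, Z: ExpressionMatrix,
                     C: sparse.spmatrix, *, spearman: bool = False
                     ) -> pd.DataFrame:
    """Correlation baseline: score each putative pair by Pearson r.

    Pairs are ranked ascending (most negative correlation first).  Pairs
    involving a zero-variance feature have undefined correlation and are
    excluded with a warning.  ``spearman=True`` ranks by Spearman rho
    instead (a monotone proxy for mutual information under normality).
    """
    if X.n_samples < 3:
        raise ValueError("correlation ranking requires at least 3 samples")
    C = sparse.coo_matrix(C)
    Xv = X.values
    Zv = Z.values
    if spearman:
        Xv = np.apply_along_axis(stats.rankdata, 1, Xv)
        Zv = np.apply_along_axis(stats.rankdata, 1, Zv)
    Xc = Xv - Xv.mean(axis=1, keepdims=True)
    Zc = Zv - Zv.mean(axis=1, keepdims=True)
    xn = np.sqrt((Xc * Xc).sum(axis=1))
    zn = np.sqrt((Zc * Zc).sum(axis=1))

    entries = []
    n_skipped = 0
    for j, k in zip(C.row, C.col):
        if xn[j] == 0 or zn[k] == 0:
            n_skipped += 1
            continue
        r = float(Xc[j] @ Zc[k] / (xn[j] * zn[k]))
        entries.append((X.feature_ids[j], Z.feature_ids[k], r))
    if n_skipped:
        warnings.warn(f"excluded {n_skipped} pair(s) with a zero-variance "
                      "feature (correlation undefined)", stacklevel=2)
    return _finalize(entries, "spearman" if spearman else "correlation")


def annotate_validated(ranked: pd.DataFrame, validated) -> pd.DataFrame:
    """Add an ``in_validated_set`` 0/1 column to a ranking."""
    vs = validated.pairs if hasattr(validated, "pairs") else set(validated)
    out = ranked.copy()
    out["in_validated_set"] = [
        int((g, m) in vs) for g, m in zip(out["mRNA_id"], out["miRNA_id"])]
    return out


def significance_beta(fit: FitResult, X: ExpressionMatrix,
                      Z: ExpressionMatrix) -> pd.DataFrame:
    """OLS-refit t-statistics for the selected coefficients of each gene.

    For gene j with support S_j (the miRNAs with nonzero fitted beta), an
    ordinary unconstrained least-squares regression of x_j on an intercept
    plus the selected miRNAs is refit, and each coefficient gets a two-sided
    t-test with I - (|S_j| + 1) degrees of freedom.  These p-values are
    conditional on the selection step and should be read as descriptive, not
    as calibrated unconditional error rates.

    Returns a DataFrame with columns ``mRNA_id, miRNA_id, estimate, stderr,
    t, p_value, flag`` (flag is '' normally, 'insufficient_df',
    'degenerate_fit' for an exact fit, or 'singular' for a collinear
    design).
    """
    I = X.n_samples
    beta = sparse.csr_matrix(fit.beta)
    rows = []
    gidx = {g: i for i, g in enumerate(X.feature_ids)}
    midx = {m: i for i, m in enumerate(Z.feature_ids)}
    for jf, gene in enumerate(fit.mrna_ids):
        sel = beta.indices[beta.indptr[jf]:beta.indptr[jf + 1]]
        if sel.size == 0:
            continue
        x = X.values[gidx[gene]]
        Zi = Z.values[[midx[fit.mirna_ids[k]] for k in sel]]
        s = sel.size
        D = np.column_stack([np.ones(I), Zi.T])
        df_resid = I - (s + 1)
        if df_resid <= 0:
            for k in sel:
                rows.append((gene, fit.mirna_ids[k], np.nan, np.nan, np.nan,
                             np.nan, "insufficient_df"))
            continue
        DtD = D.T @ D
        if np.linalg.matrix_rank(DtD) < s + 1:
            warnings.warn(f"gene {gene!r}: collinear selected miRNAs; "
                          "p-values undefined", stacklevel=2)
            for k in sel:
                rows.append((gene, fit.mirna_ids[k], np.nan, np.nan, np.nan,
                             np.nan, "singular"))
            continue
        coef, *_ = np.linalg.lstsq(D, x, rcond=None)
        resid = x - D @ coef
        rss = float(resid @ resid)
        cov_unscaled = np.linalg.inv(DtD)
        scale = rss / df_resid
        if scale <= np.finfo(float).eps * max(1.0, float(x @ x)):
            # exact fit: t is infinite, p numerically zero
            for pos, k in enumerate(sel, start=1):
                rows.append((gene, fit.mirna_ids[k], float(coef[pos]), 0.0,
                             np.inf, 0.0, "degenerate_fit"))
            continue
        se = np.sqrt(scale * np.diag(cov_unscaled))
        for pos, k in enumerate(sel, start=1):
            t = coef[pos] / se[pos]
            p = 2.0 * stats.t.sf(abs(t), df_resid)
            rows.append((gene, fit.mirna_ids[k], float(coef[pos]),
                         float(se[pos]), float(t), float(p), ""))
    return pd.DataFrame(
        rows, columns=["mRNA_id", "miRNA_id", "estimate", "stderr", "t",
                       "p_value", "flag"])
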