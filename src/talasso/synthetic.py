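"""Synthetic miRNA-mRNA data with known ground truth.

Data are generated under the same linear model the fitting assumes: for each
mRNA j, log-expression is an intercept plus a non-positive linear combination
of the log-expression of its true regulators plus Gaussian noise,

    x_j = x_j0 * 1 + sum_k beta_jk z_k + eps_j,   beta_jk <= 0.

miRNA expression is i.i.d. standard normal on the log scale by default.  Two
departures used in method-comparison experiments are available:

* a two-condition block design (``two_condition=True``): each miRNA is
  elevated in one half of the samples only, emulating condition-specific
  regulators.  A gene regulated by one miRNA from each block is poorly
  captured by marginal correlation, while a joint linear fit explains it;
* decoy regressors (:func:`generate_decoys`): per gene, extra putative
  miRNAs whose expression is positively correlated with the gene (tracking
  its regulated signal), which an unconstrained fit can chase with positive
  coefficients.

Intercepts are drawn uniform in [4, 12] arbitrary log-units; they are
irrelevant once the pipeline median-centers each feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, InteractionMask, write_interactions


@dataclass
class SyntheticTruth:
    """A generated dataset together with its generating parameters."""

    mrna: ExpressionMatrix          # X, J x I
    mirna: ExpressionMatrix         # Z, K x I
    mask: InteractionMask           # putative pairs (supset of true pairs)
    beta_true: dict[tuple[str, str], float]   # true pair -> coefficient (< 0)
    intercepts: np.ndarray          # per-gene x_j0
    noise_sd: float
    seed: int

    def true_pairs(self) -> set[tuple[str, str]]:
        return set(self.beta_true)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the standard TSV fixture files; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mrna": outdir / "mrna.tsv",
            "mirna": outdir / "mirna.tsv",
            "putative": outdir / "putative.tsv",
            "truth": outdir / "truth.tsv",
        }
        self.mrna.write(paths["mrna"])
        self.mirna.write(paths["mirna"])
        write_interactions(self.mask.pairs, paths["putative"])
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            fh.write("mRNA_id\tmiRNA_id\tbeta_true\n")
            for (g, m) in self.mask.pairs:
                if (g, m) in self.beta_true:
                    fh.write(f"{g}\t{m}\t{self.beta_true[(g, m)]:.12g}\n")
        return paths


def _ids(prefix: str, n: int, width: int) -> list[str]:
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate(J: int, K: int, I: int, *, putative_per_gene: int,
             true_per_gene: int, beta_range: tuple[float, float] = (-2.0, -0.5),
             noise_sd: float = 0.3, seed: int = 0,
             intercept_range: tuple[float, float] = (4.0, 12.0),
             two_condition: bool = False,
             condition_shift: float = 3.0) -> SyntheticTruth:
    """Generate a ground-truth network and matched expression matrices.

    Per gene, ``putative_per_gene`` miRNAs are sampled without replacement
    into the putative mask; ``true_per_gene`` of them get a coefficient drawn
    uniform in ``beta_range`` (both ends <= 0).  With ``two_condition`` the
    miRNAs are split into two blocks, each elevated by ``condition_shift`` in
    one half of the samples, and (for ``true_per_gene == 2``) each gene's
    true regulators are one miRNA from each block.
    """
    if J < 1 or K < 1 or I < 2:
        raise ValueError("need J >= 1, K >= 1, I >= 2")
    if not 0 <= true_per_gene <= putative_per_gene <= K:
        raise ValueError("need 0 <= true_per_gene <= putative_per_gene <= K")
    lo, hi = beta_range
    if not lo <= hi <= 0:
        raise ValueError("beta_range must satisfy lo <= hi <= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if two_condition and (K < 2 or true_per_gene not in (0, 2)):
        raise ValueError("two_condition requires K >= 2 and true_per_gene "
                         "in {0, 2}")

    rng = np.random.default_rng(seed)
    gene_ids = _ids("G", J, 4)
    mir_ids = _ids("miR-", K, 3)

    Z = rng.standard_normal((K, I))
    half_k = K // 2
    half_i = I // 2
    if two_condition:
        # block A miRNAs elevated in the first half of samples, block B in
        # the second half: condition-specific expression
        Z[:half_k, :half_i] += condition_shift
        Z[half_k:, half_i:] += condition_shift

    intercepts = rng.uniform(*intercept_range, size=J)
    X = np.tile(intercepts[:, None], (1, I))
    pairs: list[tuple[str, str]] = []
    beta_true: dict[tuple[str, str], float] = {}
    for j in range(J):
        if two_condition and true_per_gene == 2:
            trues = np.array([rng.integers(0, half_k),
                              rng.integers(half_k, K)])
        else:
            trues = rng.choice(K, size=true_per_gene, replace=False)
        rest = np.setdiff1d(np.arange(K), trues)
        decoys = rng.choice(rest, size=putative_per_gene - trues.size,
                            replace=False)
        chosen = np.concatenate([trues, decoys])
        for k in chosen:
            pairs.append((gene_ids[j], mir_ids[int(k)]))
        betas = rng.uniform(lo, hi, size=trues.size)
        for k, b in zip(trues, betas):
            beta_true[(gene_ids[j], mir_ids[int(k)])] = float(b)
            X[j] += b * Z[int(k)]
    if noise_sd > 0:
        X += rng.normal(0.0, noise_sd, size=(J, I))

    sample_ids = _ids("S", I, 3)
    return SyntheticTruth(
        mrna=ExpressionMatrix(gene_ids, sample_ids, X),
        mirna=ExpressionMatrix(mir_ids, sample_ids, Z),
        mask=InteractionMask.from_pairs(pairs),
        beta_true=beta_true, intercepts=intercepts,
        noise_sd=float(noise_sd), seed=int(seed))


def generate_decoys(J: int, K: int, I: int, *, true_per_gene: int = 2,
                    decoys_per_gene: int = 2, extra_putative: int = 2,
                    beta_range: tuple[float, float] = (-2.0, -0.5),
                    noise_sd: float = 0.3, decoy_noise_sd: float = 0.5,
                    seed: int = 0) -> SyntheticTruth:
    """True negative regulators plus gene-specific positively-correlated decoys.

    Each gene gets ``true_per_gene`` regulators from a shared pool of K
    miRNAs, ``decoys_per_gene`` dedicated decoy miRNAs whose expression
    tracks the gene's regulated signal (hence correlates *positively* with
    the gene), and ``extra_putative`` random uninformative pool miRNAs.  A
    sign-unconstrained fit can assign decoys positive coefficients and
    distort the true negative ones; the constrained fit cannot.
    """
    if true_per_gene > K:
        raise ValueError("true_per_gene must be <= K")
    rng = np.random.default_rng(seed)
    K_total = K + J * decoys_per_gene
    gene_ids = _ids("G", J, 4)
    mir_ids = _ids("miR-", K, 3) + [
        f"miR-D{j + 1:03d}.{d + 1}" for j in range(J)
        for d in range(decoys_per_gene)]

    Z = np.zeros((K_total, I))
    Z[:K] = rng.standard_normal((K, I))
    intercepts = rng.uniform(4.0, 12.0, size=J)
    X = np.tile(intercepts[:, None], (1, I))
    pairs: list[tuple[str, str]] = []
    beta_true: dict[tuple[str, str], float] = {}
    lo, hi = beta_range
    for j in range(J):
        trues = rng.choice(K, size=true_per_gene, replace=False)
        betas = rng.uniform(lo, hi, size=true_per_gene)
        signal = np.zeros(I)
        for k, b in zip(trues, betas):
            signal += b * Z[int(k)]
            beta_true[(gene_ids[j], mir_ids[int(k)])] = float(b)
            pairs.append((gene_ids[j], mir_ids[int(k)]))
        X[j] += signal
        sd = signal.std()
        unit = signal / sd if sd > 0 else np.zeros(I)
        for d in range(decoys_per_gene):
            kd = K + j * decoys_per_gene + d
            # decoy rises and falls with the gene's regulated signal
            Z[kd] = unit + rng.normal(0.0, decoy_noise_sd, size=I)
            pairs.append((gene_ids[j], mir_ids[kd]))
        rest = np.setdiff1d(np.arange(K), trues)
        for k in rng.choice(rest, size=min(extra_putative, rest.size),
                            replace=False):
            pairs.append((gene_ids[j], mir_ids[int(k)]))
    if noise_sd > 0:
        X += rng.normal(0.0, noise_sd, size=(J, I))

    sample_ids = _ids("S", I, 3)
    return SyntheticTruth(
        mrna=ExpressionMatrix(gene_ids, sample_ids, X),
        mirna=ExpressionMatrix(mir_ids, sample_ids, Z),
        mask=InteractionMask.from_pairs(pairs),
        beta_true=beta_true, intercepts=intercepts,
        noise_sd=float(noise_sd), seed=int(seed))


def evaluate_recovery(truth: SyntheticTruth, ranked: pd.DataFrame,
                      top_n: int) -> dict:
    """Precision / recall / F1 of true edges among the top-n ranked pairs.

    ``sign_ok`` reports whether every ranked true pair carries a negative
    score (recovered down-regulation has the right sign).  An empty ranking
    yields zero precision with ``empty_ranking=True``.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    true = truth.true_pairs()
    pairs = list(zip(ranked["mRNA_id"], ranked["miRNA_id"]))
    if not pairs:
        return {"precision": 0.0, "recall": 0.0, "f1": 0.0,
                "sign_ok": True, "empty_ranking": True}
    top = pairs[:top_n]
    tp = sum(1 for p in top if p in true)
    precision = tp / len(top)
    recall = tp / len(true) if true else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    scores = dict(zip(pairs, ranked["score"]))
    sign_ok = all(scores[p] < 0 for p in pairs if p in true)
    return {"precision": precision, "recall": recall, "f1": f1,
            "sign_ok": sign_ok, "empty_ranking": False}
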