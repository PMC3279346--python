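"""Hypergeometric enrichment of ranked interaction lists.

Given a ranking of the N putative interactions and a set of K_val validated
ones, the curve evaluates at every cutoff n the probability of drawing at
least the observed number of validated pairs when n interactions are sampled
without replacement from the universe of N.  Smaller p at a cutoff means the
top of the list is more enriched in validated interactions.

By default (as in the original protocol) the universe is restricted to
interactions whose mRNA has at least one validated miRNA target, so genes
that can never contribute a success do not dilute the test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import InteractionMask, ValidatedSet


def hypergeom_tail(n: int, p_obs: int, K_val: int, N: int) -> float:
    """Upper tail P(X >= p_obs), X ~ Hypergeometric(N, K_val, n).

    ``N`` is the universe size, ``K_val`` the validated pairs in it and ``n``
    the number of top-ranked interactions drawn.  The tail includes the
    observed count, so ``p_obs = 0`` gives 1.
    """
    if not (0 <= p_obs <= n <= N):
        raise ValueError(f"need 0 <= p_obs <= n <= N, got p_obs={p_obs}, "
                         f"n={n}, N={N}")
    if not (0 <= K_val <= N):
        raise ValueError(f"need 0 <= K_val <= N, got K_val={K_val}, N={N}")
    return float(stats.hypergeom.sf(p_obs - 1, N, K_val, n))


@dataclass
class EnrichmentCurve:
    """Cumulative validated counts and tail p-values along a ranking."""

    N: int                      # universe size after restriction
    K_val: int                  # validated pairs in the universe
    table: pd.DataFrame         # columns: n, N_E, p
    p_min: float
    N_T_at_min: int             # cutoff n at the minimum p (first attained)
    N_E_at_min: int
    N_E_500: int                # validated pairs within the top 500 (clamped)

    def summary(self) -> dict:
        return {"N": self.N, "K_val": self.K_val, "p_min": self.p_min,
                "N_T_at_min": self.N_T_at_min, "N_E_at_min": self.N_E_at_min,
                "N_E_500": self.N_E_500}

    def write(self, curve_path: str | Path, summary_path: str | Path | None
              = None) -> None:
        self.table.to_csv(curve_path, sep="\t", index=False,
                          float_format="%.6g")
        if summary_path is not None:
            Path(summary_path).write_text(
                json.dumps(self.summary(), indent=2) + "\n")


def enrichment_curve(ranked: pd.DataFrame, validated: ValidatedSet,
                     universe: InteractionMask, *,
                     restrict_universe: bool = True,
                     stride: int = 1) -> EnrichmentCurve:
    """Hypergeometric enrichment of a ranking against validated pairs.

    Parameters
    ----------
    ranked : DataFrame with columns mRNA_id, miRNA_id in rank order.
    validated : the reference set; intersected with the universe first.
    universe : the putative interactions tested (the finite population).
    restrict_universe : keep only interactions whose mRNA has at least one
        validated target (both N and K_val are recomputed after this).
    stride : evaluate p only at multiples of this cutoff (the cumulative
        counts, the minimum-p summary and N_E_500 always use stride 1 on the
        evaluated grid; the final cutoff is always included).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    uni = universe.pair_set() if hasattr(universe, "pair_set") else set(universe)
    val = (validated.pairs if hasattr(validated, "pairs")
           else frozenset(validated)) & uni
    if restrict_universe:
        genes_with_val = {g for g, _ in val}
        uni = {p for p in uni if p[0] in genes_with_val}
    K_val = len(val)
    if K_val == 0:
        raise ValueError("no validated interactions in universe")
    N = len(uni)

    pairs = [(g, m) for g, m in zip(ranked["mRNA_id"], ranked["miRNA_id"])]
    kept = [p for p in pairs if p in uni]
    L = len(kept)
    if L == 0:
        raise ValueError("ranking has no interactions inside the universe")
    hits = np.fromiter(((p in val) for p in kept), dtype=int, count=L)
    cum = np.cumsum(hits)

    ns = np.arange(stride, L + 1, stride)
    if ns.size == 0 or ns[-1] != L:
        ns = np.append(ns, L)
    p = stats.hypergeom.sf(cum[ns - 1] - 1, N, K_val, ns)
    table = pd.DataFrame({"n": ns, "N_E": cum[ns - 1], "p": p})

    imin = int(np.argmin(p))          # first cutoff attaining the minimum
    n500 = min(500, L)
    if L < 500:
        warnings.warn(f"ranking has only {L} interactions; N_E_500 computed "
                      f"at n={L}", stacklevel=2)
    return EnrichmentCurve(
        N=N, K_val=K_val, table=table,
        p_min=float(p[imin]), N_T_at_min=int(ns[imin]),
        N_E_at_min=int(cum[ns[imin] - 1]), N_E_500=int(cum[n500 - 1]))


def set_report(masks: dict[str, InteractionMask | set]) -> pd.DataFrame:
    """Overlap table for named interaction sets.

    Returns one row per individual set, per unordered pair of sets, plus the
    intersection and union of all sets, with cardinalities.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 named sets")
    sets = {name: (m.pair_set() if hasattr(m, "pair_set") else set(m))
            for name, m in masks.items()}
    names = list(sets)
    rows = [(name, len(sets[name])) for name in names]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rows.append((f"{a} & {b}", len(sets[a] & sets[b])))
    if len(names) > 2:   # for two sets the pairwise row already covers this
        rows.append((" & ".join(names), len(set.intersection(*sets.values()))))
    rows.append((" | ".join(names), len(set.union(*sets.values()))))
    return pd.DataFrame(rows, columns=["sets", "size"])
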