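"""Reading, writing and aligning expression matrices and interaction lists.

Expression data are tab-separated text: a header row ``ID\t<sample1>\t...``
followed by one feature (mRNA or miRNA) per row.  Values are assumed to be on
a log scale already (the regression model is linear in log-expression); an
optional ``log2(x+1)`` pre-transform is available for raw intensities, and
ΔΔCt miRNA data are handled by sign negation so that larger always means more
expressed.

Interaction lists (putative targets, validated targets) are two-column TSV
files ``mRNA_id\tmiRNA_id`` with optional header and ``#`` comment lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """A features × samples matrix of log-scale expression values.

    Parameters
    ----------
    feature_ids : sequence of str
        Unique feature (mRNA or miRNA) identifiers, one per row.
    sample_ids : sequence of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_features, n_samples)
        Finite log-scale expression values.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D array")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise DataError("duplicate feature IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample IDs")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row_index(self) -> dict[str, int]:
        """Map feature ID -> row number."""
        return {f: i for i, f in enumerate(self.feature_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.feature_ids, name="ID"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))

    def write(self, path: str | Path) -> None:
        """Write as TSV with 12 significant digits (round-trip safe)."""
        self.to_frame().to_csv(path, sep="\t", float_format="%.12g")

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(list(self.feature_ids), list(self.sample_ids),
                                self.values.copy())


@dataclass(frozen=True)
class InteractionMask:
    """An ordered, de-duplicated collection of putative (mRNA, miRNA) pairs."""

    pairs: tuple[tuple[str, str], ...]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "InteractionMask":
        seen: dict[tuple[str, str], None] = {}
        for g, m in pairs:
            seen[(str(g).strip(), str(m).strip())] = None
        return cls(tuple(seen))

    def pair_set(self) -> set[tuple[str, str]]:
        return set(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ValidatedSet:
    """Experimentally validated (mRNA, miRNA) pairs with a source label."""

    pairs: frozenset[tuple[str, str]]
    source_label: str = "validated"

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   source_label: str = "validated") -> "ValidatedSet":
        return cls(frozenset((str(g).strip(), str(m).strip()) for g, m in pairs),
                   source_label)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AlignReport:
    """Bookkeeping from aligning two expression matrices with a mask."""

    n_pairs_kept: int = 0
    dropped_pairs: int = 0
    dropped_mrnas: int = 0
    dropped_mirnas: int = 0
    sample_order: list[str] = field(default_factory=list)


def read_expression(path: str | Path, is_ddct: bool = False,
                    log2_transform: bool = False) -> ExpressionMatrix:
    """Read an expression TSV into an :class:`ExpressionMatrix`.

    Duplicate feature IDs are collapsed by their arithmetic mean (as when
    several probes map to one gene).  Rows containing missing or empty cells
    are dropped with a warning.  With ``is_ddct`` the values are negated,
    since Ct counts decrease with abundance.  With ``log2_transform`` a
    ``log2(x+1)`` transform is applied first (for raw, non-log intensities).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=0, dtype=str,
                          index_col=0, comment=None, skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"{path}: cannot parse header line: {exc}") from exc
    if raw.index.name is None or raw.shape[1] == 0:
        raise DataError(f"{path}: malformed header at line 1 "
                        "(expected 'ID<TAB>sample1<TAB>...')")
    if raw.shape[1] < 2:
        raise DataError(f"{path}: fewer than 2 samples; leave-one-out "
                        "cross-validation is impossible")
    sample_ids = [str(c).strip() for c in raw.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise DataError(f"{path}: duplicate sample names in header")

    feature_ids = [str(i).strip() for i in raw.index]
    values = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy()
    for i in range(arr.shape[0]):
        for jcol in range(arr.shape[1]):
            cell = arr[i, jcol]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or str(cell).strip() == "":
                values[i, jcol] = np.nan
                continue
            try:
                values[i, jcol] = float(cell)
            except ValueError as exc:
                raise DataError(
                    f"{path}: non-numeric cell {cell!r} at feature "
                    f"{feature_ids[i]!r} (row {i + 2}), sample "
                    f"{sample_ids[jcol]!r} (column {jcol + 2})") from exc

    missing = np.isnan(values).any(axis=1)
    if missing.any():
        warnings.warn(f"{path}: dropped {int(missing.sum())} feature row(s) "
                      "with missing values", stacklevel=2)
        keep = ~missing
        values = values[keep]
        feature_ids = [f for f, k in zip(feature_ids, keep) if k]
    if len(feature_ids) == 0:
        raise DataError(f"{path}: no complete feature rows")

    df = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    if df.index.has_duplicates:
        # probes mapping to one feature: aggregate by mean, keep first-seen order
        order = list(dict.fromkeys(feature_ids))
        df = df.groupby(level=0, sort=False).mean().loc[order]

    vals = df.to_numpy(dtype=float)
    if log2_transform:
        if (vals < 0).any():
            raise DataError(f"{path}: negative values; log2(x+1) transform "
                            "requires non-negative intensities")
        vals = np.log2(vals + 1.0)
    if is_ddct:
        vals = -vals
    return ExpressionMatrix(list(df.index), sample_ids, vals)


def read_interactions(path: str | Path) -> InteractionMask:
    """Read a two-column (mRNA_id, miRNA_id) TSV; ``#`` lines are comments.

    A first line whose fields are non-numeric labels containing 'mrna'/'mirna'
    or 'id' is treated as a header and skipped.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise DataError(f"{path}: line {lineno}: expected two "
                                f"tab-separated identifiers, got {line!r}")
            low = (fields[0].lower(), fields[1].lower())
            if not pairs and lineno == 1 and (
                    "mrna" in low[0] or "id" == low[0] or "gene" in low[0]):
                continue  # header row
            pairs.append((fields[0], fields[1]))
    return InteractionMask.from_pairs(pairs)


def write_interactions(pairs: Iterable[tuple[str, str]], path: str | Path,
                       header: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("mRNA_id\tmiRNA_id\n")
        for g, m in pairs:
            fh.write(f"{g}\t{m}\n")


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each feature's median across samples (row-wise centering)."""
    med = np.median(m.values, axis=1, keepdims=True)
    return ExpressionMatrix(list(m.feature_ids), list(m.sample_ids),
                            m.values - med)


def align(mrna: ExpressionMatrix, mirna: ExpressionMatrix,
          mask: InteractionMask
          ) -> tuple[ExpressionMatrix, ExpressionMatrix, sparse.csr_matrix,
                     AlignReport]:
    """Intersect expression matrices with the putative-interaction mask.

    Samples of the two matrices must agree as sets; the miRNA matrix is
    reordered to the mRNA sample order.  Features are restricted to those
    occurring in at least one mask pair whose partner is also measured;
    original row order is preserved, making the operation idempotent.

    Returns the restricted matrices, the binary indicator matrix ``C``
    (kept mRNAs × kept miRNAs, CSR), and an :class:`AlignReport`.
    """
    s1, s2 = set(mrna.sample_ids), set(mirna.sample_ids)
    if s1 != s2:
        diff = sorted(s1.symmetric_difference(s2))
        raise DataError(f"sample sets differ between mRNA and miRNA matrices; "
                        f"symmetric difference: {diff}")
    order = [mirna.sample_ids.index(s) for s in mrna.sample_ids]
    z_vals = mirna.values[:, order]

    gidx = mrna.row_index()
    midx = mirna.row_index()
    resolvable = [(g, m) for g, m in mask.pairs if g in gidx and m in midx]
    dropped_pairs = len(mask.pairs) - len(resolvable)
    if not resolvable:
        raise DataError("no putative pair has both its mRNA and miRNA measured")

    kept_g = {g for g, _ in resolvable}
    kept_m = {m for _, m in resolvable}
    g_order = [g for g in mrna.feature_ids if g in kept_g]
    m_order = [m for m in mirna.feature_ids if m in kept_m]
    g_new = {g: i for i, g in enumerate(g_order)}
    m_new = {m: i for i, m in enumerate(m_order)}

    rows = [g_new[g] for g, m in resolvable]
    cols = [m_new[m] for g, m in resolvable]
    C = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(g_order), len(m_order)))
    C.data[:] = 1.0  # duplicate pairs collapse to a single indicator
    C.sum_duplicates()
    C.data[:] = 1.0

    out_mrna = ExpressionMatrix(
        g_order, list(mrna.sample_ids),
        mrna.values[[gidx[g] for g in g_order], :])
    out_mirna = ExpressionMatrix(
        m_order, list(mrna.sample_ids),
        z_vals[[midx[m] for m in m_order], :])
    report = AlignReport(
        n_pairs_kept=int(C.nnz),
        dropped_pairs=dropped_pairs,
        dropped_mrnas=mrna.n_features - len(g_order),
        dropped_mirnas=mirna.n_features - len(m_order),
        sample_order=list(mrna.sample_ids),
    )
    return out_mrna, out_mirna, C, report
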