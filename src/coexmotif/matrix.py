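"""Expression-matrix ingestion and normalization.

The compendium is a genes x arrays real matrix. Ingestion drops rows with
missing or non-numeric cells (never imputes), and normalization is quantile
normalization on the log2 scale so that per-array quantile ranks and Pearson
correlations are comparable across hybridizations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Gene x array expression matrix with a scale tag.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene id, columns by array id, float values.
    scale_tag : {"linear", "log2"}
        Intensity scale of ``data``.
    """

    data: pd.DataFrame
    scale_tag: str = "linear"

    def __post_init__(self):
        if self.scale_tag not in ("linear", "log2"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate array id: {dup!r}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("empty expression matrix")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("non-numeric values in expression matrix")
        if not np.isfinite(vals).all():
            raise ValueError("non-finite values in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def read_expression_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a TSV/CSV matrix (header row = array ids, first column = gene ids).

    Rows containing missing or non-numeric cells are dropped with a logged
    count; duplicated ids or an empty body are hard errors.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no array columns found (malformed header?)")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate array id {dup!r}")
    probe = df.apply(pd.to_numeric, errors="coerce")
    bad = probe.isna().any(axis=1)
    if bad.any():
        logger.warning("dropped %d row(s) with missing/non-numeric cells: %s",
                       int(bad.sum()), list(df.index[bad])[:10])
    # astype goes through Python's exact float parser, so written values
    # round-trip bit for bit (pandas' fast to_numeric path can be 1 ulp off)
    num = df.loc[~bad].astype(float)
    if num.shape[0] == 0:
        raise ValueError(f"{path}: no valid data rows")
    return ExpressionMatrix(num)


def write_expression_matrix(m: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    # pandas writes shortest round-trip repr for float64, so read-back is exact
    m.data.to_csv(path, sep=delimiter, lineterminator="\n")


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(value + offset); requires a linear-scale matrix and positivity."""
    if m.scale_tag != "linear":
        raise ValueError("log2_transform requires a linear-scale matrix")
    vals = m.values + offset
    if (vals <= 0).any():
        raise ValueError("log2_transform: value + offset must be positive everywhere")
    return ExpressionMatrix(pd.DataFrame(np.log2(vals), index=m.data.index,
                                         columns=m.data.columns), scale_tag="log2")


def _quantile_map(vals: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map each column of ``vals`` onto ``reference`` by rank; ties within a
    column receive the mean of the reference values their span covers."""
    out = np.empty_like(vals, dtype=float)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        sorter = np.argsort(col, kind="stable")
        s = col[sorter]
        # group consecutive equal values (tie groups in rank space)
        grp = np.concatenate([[0], np.cumsum(s[1:] != s[:-1])])
        sums = np.bincount(grp, weights=reference)
        counts = np.bincount(grp)
        out[sorter, j] = (sums / counts)[grp]
    return out


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every array to the across-array mean of sorted columns.

    Within-column ranks are preserved; ties get the mean of the reference
    quantiles they span (deterministic, order-independent). A single-column
    matrix is returned unchanged with a warning.
    """
    if m.shape[1] < 2:
        warnings.warn("quantile_normalize: single array, returning input unchanged")
        return replace(m, data=m.data.copy())
    vals = m.values.astype(float)
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = _quantile_map(vals, reference)
    return replace(m, data=pd.DataFrame(out, index=m.data.index, columns=m.data.columns))


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalization over array columns (genes are rows).

    ``fit`` learns the reference distribution (the across-column mean of
    sorted columns); ``transform`` maps each column onto it by rank, with
    ties assigned the mean of the spanned reference values.

    Attributes
    ----------
    reference_ : ndarray of shape (n_genes,)
        Sorted reference distribution learned from the fit data.
    """

    def fit(self, X, y=None):
        X = self._as_frame(X)
        vals = X.to_numpy(dtype=float)
        if vals.shape[0] < 2:
            raise ValueError("need at least 2 genes")
        self.n_genes_ = vals.shape[0]
        self.reference_ = np.sort(vals, axis=0).mean(axis=1)
        return self

    def transform(self, X):
        X = self._as_frame(X)
        if X.shape[0] != self.n_genes_:
            raise ValueError("transform input must have the same number of genes as fit data")
        out = _quantile_map(X.to_numpy(dtype=float), self.reference_)
        return pd.DataFrame(out, index=X.index, columns=X.columns)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, ExpressionMatrix):
            return X.data
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float))
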