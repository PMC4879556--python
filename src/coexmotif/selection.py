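"""Discriminative array selection.

Each array is scored by the fraction of a positive gene list (genes with a
validated role in the process of interest) that falls into the array's
extreme expression quantiles — the top q or bottom q of all genes on the
array. Arrays whose score strictly exceeds f are kept; with the shipped
defaults (q=0.25, f=0.70) an array is selected when more than 70% of the
list genes sit among the 25% highest or lowest signals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PositiveGeneList:
    gene_ids: frozenset
    name: str = "positive"

    def __post_init__(self):
        if not self.gene_ids:
            raise ValueError("positive gene list is empty")

    def __len__(self):
        return len(self.gene_ids)


def read_gene_list(path, name: str | None = None) -> PositiveGeneList:
    """Plain text, one gene id per line, '#' starts a comment."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    return PositiveGeneList(frozenset(ids), name or str(path))


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


@dataclass(frozen=True)
class SelectionParams:
    """q: extreme-quantile fraction per tail; f: minimum list fraction (strict)."""

    q: float = 0.25
    f: float = 0.70

    def __post_init__(self):
        if not (0 < self.q <= 0.5):
            raise ValueError(f"q must be in (0, 0.5], got {self.q}")
        if not (0 < self.f <= 1):
            raise ValueError(f"f must be in (0, 1], got {self.f}")


@dataclass
class ArraySelection:
    """Per-array scores and selected status, sorted by score descending."""

    table: pd.DataFrame  # index: array_id; columns: score, selected
    params: SelectionParams

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())

    @property
    def selected_arrays(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "array_id", out.index)
        out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def extreme_quantile_membership(column: pd.Series, q: float) -> set:
    """Genes in the k highest or k lowest values, k = floor(q*n) per tail.

    Boundary ties are broken deterministically by lexicographic gene id:
    genes are ordered by (value, gene id) and the two ends of that order
    are taken.
    """
    n = len(column)
    if n < 2:
        raise ValueError("need at least 2 genes")
    k = int(np.floor(q * n))
    if k < 1:
        raise ValueError(f"quantile too small for n (q={q}, n={n})")
    ids = column.index.to_numpy(dtype=object)
    order = np.lexsort((ids, column.to_numpy()))
    return set(ids[order[:k]]) | set(ids[order[-k:]])


def score_array(m: ExpressionMatrix, array_id: str, gene_list: PositiveGeneList,
                q: float = 0.25) -> float:
    """Fraction of list genes (present in the matrix) in the array's extremes."""
    present = gene_list.gene_ids & set(m.gene_ids)
    if not present:
        raise ValueError("no positive-list gene is present in the matrix")
    extremes = extreme_quantile_membership(m.data[array_id], q)
    return len(present & extremes) / len(present)


def select_discriminative_arrays(m: ExpressionMatrix, gene_list: PositiveGeneList,
                                 params: SelectionParams = SelectionParams()) -> ArraySelection:
    """Score every array; selected iff score > f (strict inequality)."""
    present = gene_list.gene_ids & set(m.gene_ids)
    if not present:
        raise ValueError("no positive-list gene is present in the matrix")
    missing = gene_list.gene_ids - present
    if missing:
        logger.info("%d positive-list gene(s) absent from matrix, excluded from scoring",
                    len(missing))
    n = m.shape[0]
    k = int(np.floor(params.q * n))
    if k < 1:
        raise ValueError(f"quantile too small for n (q={params.q}, n={n})")
    vals = m.values
    ids = np.asarray(m.gene_ids, dtype=object)
    present_mask = np.isin(ids, list(present))
    scores = np.empty(m.shape[1])
    for j in range(m.shape[1]):
        order = np.lexsort((ids, vals[:, j]))
        extreme = np.zeros(n, dtype=bool)
        extreme[order[:k]] = True
        extreme[order[-k:]] = True
        scores[j] = (extreme & present_mask).sum() / present_mask.sum()
    tab = pd.DataFrame({"score": scores, "selected": scores > params.f},
                       index=pd.Index(m.array_ids, name="array_id"))
    tab = tab.sort_values(["score", "array_id"], ascending=[False, True],
                          kind="stable")
    if not tab["selected"].any():
        warnings.warn("no array passed the discriminative-selection threshold")
    return ArraySelection(tab, params)


class DiscriminativeArraySelector(BaseEstimator):
    """Select expression arrays in which a positive gene list is extreme.

    Parameters
    ----------
    positive_genes : collection of str
        The positive gene list.
    q : float, default 0.25
        Extreme-quantile fraction per tail.
    f : float, default 0.70
        Minimum fraction of list genes in the extremes (strict inequality).

    Attributes
    ----------
    scores_ : pandas.Series, array id -> score.
    selected_ : list of selected array ids.
    selection_ : ArraySelection with the full sorted table.
    """

    def __init__(self, positive_genes=(), q: float = 0.25, f: float = 0.70):
        self.positive_genes = positive_genes
        self.q = q
        self.f = f

    def fit(self, X, y=None):
        m = X if isinstance(X, ExpressionMatrix) else ExpressionMatrix(pd.DataFrame(X), scale_tag="log2")
        genes = (self.positive_genes if isinstance(self.positive_genes, PositiveGeneList)
                 else PositiveGeneList(frozenset(self.positive_genes)))
        self.selection_ = select_discriminative_arrays(
            m, genes, SelectionParams(q=self.q, f=self.f))
        self.scores_ = self.selection_.table["score"]
        self.selected_ = self.selection_.selected_arrays
        return self

    def transform(self, X):
        """Restrict the matrix to the selected arrays."""
        df = X.data if isinstance(X, ExpressionMatrix) else X
        return df[self.selected_]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
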