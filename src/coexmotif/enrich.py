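"""GO-term enrichment: right-sided hypergeometric test per term, Holm
(Bonferroni step-down) correction across the terms tested for a cluster.

For a cluster with n genes in the annotation universe of size N, a term
annotating K universe genes and k cluster genes gets
p = P(X >= k), X ~ Hypergeometric(N, K, n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GOAnnotation:
    """gene -> terms mapping, its inverse, and the annotation universe."""

    gene_to_terms: dict
    term_to_genes: dict = field(default=None)
    universe: frozenset = field(default=None)

    def __post_init__(self):
        if self.term_to_genes is None:
            inv: dict[str, set] = {}
            for g, terms in self.gene_to_terms.items():
                for t in terms:
                    inv.setdefault(t, set()).add(g)
            self.term_to_genes = {t: frozenset(gs) for t, gs in inv.items()}
        if self.universe is None:
            self.universe = frozenset(self.gene_to_terms)

    def restrict(self, genes) -> "GOAnnotation":
        """Universe restricted to ``genes`` (e.g. genes in the matrix)."""
        keep = self.universe & frozenset(genes)
        g2t = {g: set(ts) for g, ts in self.gene_to_terms.items() if g in keep}
        return GOAnnotation(g2t)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for g in sorted(self.gene_to_terms):
                for t in sorted(self.gene_to_terms[g]):
                    fh.write(f"{g}\t{t}\n")


def read_go_annotation(path) -> GOAnnotation:
    """Two-column TSV (gene_id, term_id) or GAF 2.x (columns 2 and 5)."""
    g2t: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 15:  # GAF
                gene, term = parts[1], parts[4]
            elif len(parts) >= 2:
                gene, term = parts[0], parts[1]
            else:
                continue
            g2t.setdefault(gene, set()).add(term)
    if not g2t:
        raise ValueError(f"{path}: no annotations parsed")
    return GOAnnotation(g2t)


def hypergeometric_pvalue_right(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N and k >= 0):
        raise ValueError(f"invalid hypergeometric arguments k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def enrich_cluster(cluster, annot: GOAnnotation) -> pd.DataFrame:
    """One right-sided test per term with k >= 1; Holm correction across the
    tested terms. Cluster genes outside the universe are logged and excluded.

    Returns a DataFrame (term, k, n, K, N, p_raw, p_adj) sorted by p_adj
    then p_raw then term.
    """
    members = set(getattr(cluster, "members", cluster))
    inside = members & annot.universe
    outside = members - annot.universe
    if outside:
        logger.info("%d cluster gene(s) outside annotation universe, excluded",
                    len(outside))
    if not inside:
        raise ValueError("cluster has no gene in the annotation universe")
    N = len(annot.universe)
    n = len(inside)
    rows = []
    for term in sorted(annot.term_to_genes):
        tg = annot.term_to_genes[term]
        k = len(inside & tg)
        if k < 1:
            continue
        rows.append((term, k, n, len(tg), N,
                     hypergeometric_pvalue_right(k, len(tg), n, N)))
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p_raw"])
    df["p_adj"] = holm_adjust(df["p_raw"].to_numpy()) if len(df) else []
    return df.sort_values(["p_adj", "p_raw", "term"], kind="stable").reset_index(drop=True)
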