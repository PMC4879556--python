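"""Pearson-thresholded co-expression network and cluster extraction.

An edge joins two candidate genes when their sample Pearson correlation
across the selected arrays is >= r0 (signed, inclusive; 0.90 by default).
Gene clusters are the connected components of the thresholded graph with at
least ``min_cluster_size`` members, labelled C0, C1, ... by decreasing size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkParams:
    r0: float = 0.90
    min_cluster_size: int = 5

    def __post_init__(self):
        if not (-1 < self.r0 <= 1):
            raise ValueError(f"r0 must be in (-1, 1], got {self.r0}")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class CoexpressionNetwork:
    graph: nx.Graph
    params: NetworkParams
    excluded_genes: list = field(default_factory=list)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    members: frozenset

    def __len__(self):
        return len(self.members)


@dataclass
class ClusterResult:
    """Ordered clusters plus the remainder (nodes in components below the
    size cutoff); together they partition the network's node set."""

    clusters: list
    remainder: frozenset

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self):
        return len(self.clusters)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("cluster_id\tgene_id\n")
            for c in self.clusters:
                for g in sorted(c.members):
                    fh.write(f"{c.cluster_id}\t{g}\n")
            for g in sorted(self.remainder):
                fh.write(f"remainder\t{g}\n")


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation; requires length >= 3 and nonzero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def build_network(m: ExpressionMatrix, candidates, arrays,
                  params: NetworkParams = NetworkParams()) -> CoexpressionNetwork:
    """All-pairs Pearson over the selected arrays; edge iff r >= r0.

    Zero-variance genes are excluded (logged); nodes are the candidate genes
    present in the matrix and not excluded.
    """
    arrays = list(arrays)
    if len(arrays) < 3:
        raise ValueError("need at least 3 selected arrays for correlation")
    present = [g for g in m.gene_ids if g in set(candidates)]
    if len(present) < 2:
        raise ValueError("need at least 2 candidate genes present in the matrix")
    sub = m.data.loc[present, arrays]
    vals = sub.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    excluded = [g for g, s in zip(present, sd) if s == 0]
    if excluded:
        logger.info("excluded %d zero-variance gene(s) from network", len(excluded))
    keep = sd > 0
    genes = [g for g, k in zip(present, keep) if k]
    vals = vals[keep]
    g = nx.Graph()
    g.add_nodes_from(genes)
    if len(genes) >= 2:
        corr = np.corrcoef(vals)
        iu, ju = np.where(np.triu(corr >= params.r0, k=1))
        for i, j in zip(iu, ju):
            g.add_edge(genes[i], genes[j], weight=float(corr[i, j]))
    return CoexpressionNetwork(g, params, excluded)


def extract_clusters(net: CoexpressionNetwork,
                     min_cluster_size: int | None = None) -> ClusterResult:
    """Connected components of size >= min_cluster_size, labelled C0, C1, ...
    in decreasing size; size ties broken by lexicographically smallest member."""
    mcs = net.params.min_cluster_size if min_cluster_size is None else min_cluster_size
    comps = [frozenset(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    clusters, remainder = [], set()
    for c in comps:
        if len(c) >= mcs:
            clusters.append(GeneCluster(f"C{len(clusters)}", c))
        else:
            remainder |= c
    return ClusterResult(clusters, frozenset(remainder))


def write_network(net: CoexpressionNetwork, path, format: str = "edge-list") -> None:
    """Write as sorted edge-list TSV (gene_a < gene_b) or GraphML."""
    if format == "edge-list":
        rows = []
        for a, b, d in net.graph.edges(data=True):
            a, b = sorted((a, b))
            rows.append((a, b, d["weight"]))
        rows.sort()
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tr\n")
            for a, b, r in rows:
                fh.write(f"{a}\t{b}\t{r!r}\n")
    elif format == "graphml":
        # rebuild with sorted insertion so output is deterministic
        g = nx.Graph()
        g.add_nodes_from(sorted(net.graph.nodes))
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            g.add_edge(a, b, weight=net.graph[a][b]["weight"])
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, params: NetworkParams = NetworkParams(),
                 nodes=None) -> CoexpressionNetwork:
    """Read an edge-list TSV written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for a, b, r in df.itertuples(index=False):
        g.add_edge(a, b, weight=float(r))
    return CoexpressionNetwork(g, params)


class CoexpressionClusterer(ClusterMixin, BaseEstimator):
    """Cluster genes by thresholded Pearson co-expression.

    Rows of X are genes (samples in the sklearn sense), columns are the
    selected arrays. Components of the r >= r0 graph with at least
    ``min_cluster_size`` genes become clusters 0, 1, ... by decreasing size;
    remainder genes get label -1.

    Attributes
    ----------
    network_ : CoexpressionNetwork
    clusters_ : ClusterResult
    labels_ : ndarray of int, aligned with the rows of X.
    """

    def __init__(self, r0: float = 0.90, min_cluster_size: int = 5):
        self.r0 = r0
        self.min_cluster_size = min_cluster_size

    def fit(self, X, y=None):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        m = ExpressionMatrix(df, scale_tag="log2")
        params = NetworkParams(r0=self.r0, min_cluster_size=self.min_cluster_size)
        self.network_ = build_network(m, set(df.index), df.columns, params)
        self.clusters_ = extract_clusters(self.network_)
        lbl = {}
        for i, c in enumerate(self.clusters_.clusters):
            for gid in c.members:
                lbl[gid] = i
        self.labels_ = np.array([lbl.get(gid, -1) for gid in df.index])
        return self
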