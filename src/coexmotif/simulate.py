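"""Synthetic inputs with ground truth for every pipeline stage.

The generator emulates, at desk scale, the statistical structure the
analysis assumes: an expression compendium in which a minority of
"discriminative" arrays place the positive-list genes in extreme quantiles;
planted co-expressed modules among candidate genes; promoters drawn from an
order-3 Markov background with planted motif instances; and a GO annotation
with planted enriched terms. Every stage of the pipeline can therefore be
scored against recorded truth without any external download.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._util import IUPAC
from .background import MarkovBackground
from .enrich import GOAnnotation
from .matrix import ExpressionMatrix
from .promoters import Promoter, PromoterParams, PromoterSet
from .selection import PositiveGeneList


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset; fields unused by a given
    generator are left None."""

    seed: int
    params: dict = field(default_factory=dict)
    discriminative_arrays: list | None = None
    module_assignments: dict | None = None  # gene -> module index
    positive_genes: list | None = None
    shift_signs: dict | None = None
    planted_consensus: str | None = None
    planted_sites: dict | None = None  # gene -> (offset, instance)
    planted_terms: list | None = None  # (term, module genes planted)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=list)
            fh.write("\n")


def simulate_expression(n_genes: int = 200, n_arrays: int = 100,
                        n_discriminative: int = 10, positive_list_size: int = 20,
                        modules=((20, 0.95), (15, 0.95), (10, 0.95)),
                        shift: float = 4.0, noise_sd: float = 1.0,
                        seed: int = 1):
    """Synthetic compendium with planted discriminative arrays and modules.

    Background entries are iid N(0, 1) on the normalized (log-like) scale.
    A module gene is sqrt(rho) * latent factor + sqrt(1-rho) * noise_sd * eps,
    so at noise_sd=1 the expected within-module Pearson correlation is
    exactly rho. In discriminative arrays every positive-list gene is
    shifted by +-``shift`` (sign fixed per gene).

    Returns (ExpressionMatrix, PositiveGeneList, candidate gene set, truth).
    """
    modules = [tuple(m) for m in modules]
    if sum(s for s, _ in modules) + positive_list_size > n_genes:
        raise ValueError("module sizes plus positive list exceed n_genes")
    if n_discriminative > n_arrays:
        raise ValueError("n_discriminative exceeds n_arrays")
    for s, rho in modules:
        if not (0 <= rho < 1):
            raise ValueError(f"infeasible module correlation {rho}")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    arrays = [f"a{j + 1:03d}" for j in range(n_arrays)]
    vals = rng.standard_normal((n_genes, n_arrays))

    module_of: dict[str, int] = {}
    pos = 0
    for mi, (size, rho) in enumerate(modules):
        factor = rng.standard_normal(n_arrays)
        block = (np.sqrt(rho) * factor
                 + np.sqrt(1.0 - rho) * noise_sd * rng.standard_normal((size, n_arrays)))
        vals[pos:pos + size] = block
        for g in genes[pos:pos + size]:
            module_of[g] = mi
        pos += size
    positive = genes[pos:pos + positive_list_size]
    pos += positive_list_size

    disc = sorted(rng.choice(arrays, size=n_discriminative, replace=False))
    disc_idx = [arrays.index(a) for a in disc]
    signs = {g: int(s) for g, s in zip(positive, rng.choice([-1, 1], size=len(positive)))}
    for g in positive:
        gi = genes.index(g)
        vals[gi, disc_idx] += signs[g] * shift

    candidates = frozenset(module_of) | frozenset(genes[pos:])
    m = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=arrays),
                         scale_tag="log2")
    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_genes=n_genes, n_arrays=n_arrays,
                    n_discriminative=n_discriminative,
                    positive_list_size=positive_list_size,
                    modules=list(modules), shift=shift, noise_sd=noise_sd),
        discriminative_arrays=list(disc),
        module_assignments=module_of,
        positive_genes=list(positive),
        shift_signs=signs,
    )
    return m, PositiveGeneList(frozenset(positive)), candidates, truth


def _resolve_iupac(pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in pattern)


def simulate_promoters(n_seqs: int = 30, length: int = 500,
                       background_order: int = 3,
                       background_source_seed: int | None = None,
                       planted_consensus: str = "GACGTGGC",
                       n_carriers: int = 20, seed: int = 11,
                       gene_ids=None):
    """Promoters from a random order-k Markov chain with planted motif
    instances in the first ``n_carriers`` sequences.

    Degenerate positions of the planted consensus are resolved uniformly at
    each insertion, so every planted instance matches the consensus by
    construction. Returns (PromoterSet, truth).
    """
    if n_carriers > n_seqs:
        raise ValueError("n_carriers exceeds n_seqs")
    if len(planted_consensus) > length:
        raise ValueError("planted consensus longer than sequences")
    rng = np.random.default_rng(seed)
    bg_rng = np.random.default_rng(
        seed if background_source_seed is None else background_source_seed)
    bg = MarkovBackground.random(background_order, bg_rng)
    ids = list(gene_ids) if gene_ids is not None else [f"p{i + 1:03d}" for i in range(n_seqs)]
    if len(ids) != n_seqs:
        raise ValueError("gene_ids length must equal n_seqs")
    w = len(planted_consensus)
    proms = {}
    sites = {}
    for i, gid in enumerate(ids):
        s = bg.sample(length, rng)
        if i < n_carriers:
            off = int(rng.integers(0, length - w + 1))
            inst = _resolve_iupac(planted_consensus, rng)
            s = s[:off] + inst + s[off + w:]
            sites[gid] = (off, inst)
        proms[gid] = Promoter(gid, "synthetic", "+", 1, length, s)
    pset = PromoterSet(proms, PromoterParams(max_length=max(length, 1000),
                                             min_length=min(length, 50)))
    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_seqs=n_seqs, length=length, background_order=background_order,
                    background_source_seed=background_source_seed,
                    planted_consensus=planted_consensus, n_carriers=n_carriers),
        planted_consensus=planted_consensus,
        planted_sites=sites,
    )
    return pset, truth


def simulate_go_annotation(universe, n_terms: int = 50,
                           term_size_range=(5, 40), planted=(),
                           seed: int = 5):
    """GO-like annotation: decoy terms sample universe genes uniformly;
    each planted (genes, fraction) pair becomes a term containing that
    fraction of the given gene set plus uniform fill.

    Returns (GOAnnotation, truth).
    """
    universe = sorted(universe)
    lo, hi = term_size_range
    if hi > len(universe):
        raise ValueError("term sizes exceed universe")
    rng = np.random.default_rng(seed)
    g2t: dict[str, set] = {g: set() for g in universe}
    planted_records = []
    for i, (genes, frac) in enumerate(planted):
        genes = sorted(set(genes) & set(universe))
        term = f"GO:9{i:06d}"
        n_core = int(round(frac * len(genes)))
        core = sorted(rng.choice(genes, size=n_core, replace=False))
        size = int(rng.integers(lo, hi + 1))
        pool = [g for g in universe if g not in set(core)]
        fill = sorted(rng.choice(pool, size=max(0, size - n_core), replace=False))
        for g in core + fill:
            g2t[g].add(term)
        planted_records.append((term, core))
    for i in range(n_terms):
        term = f"GO:{i:07d}"
        size = int(rng.integers(lo, hi + 1))
        for g in rng.choice(universe, size=size, replace=False):
            g2t[g].add(term)
    annot = GOAnnotation({g: ts for g, ts in g2t.items() if ts})
    truth = SyntheticTruth(
        seed=seed,
        params=dict(n_terms=n_terms, term_size_range=list(term_size_range),
                    n_planted=len(planted_records), universe_size=len(universe)),
        planted_terms=planted_records,
    )
    return annot, truth
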