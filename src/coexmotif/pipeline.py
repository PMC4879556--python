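"""End-to-end pipeline: normalize -> select arrays -> network -> clusters ->
per-cluster motif discovery/annotation -> GO enrichment.

All stage outputs are plain-text files under the configured output
directory, a machine-readable ``report.json`` summarises counts per stage,
and every source of randomness derives from the single master seed, so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from ._util import derive_seed
from .annotate import (ConsensusPattern, comparisons_to_tsv,
                       compare_motif_to_library, filter_motifs_by_gene_support,
                       scan_consensus)
from .background import train_markov_background
from .discovery import MotifParams, discover_motifs_zoops
from .enrich import enrich_cluster, read_go_annotation
from .matrix import (ExpressionMatrix, log2_transform, quantile_normalize,
                     read_expression_matrix, write_expression_matrix)
from .memeio import read_meme_library, write_meme
from .network import (NetworkParams, build_network, extract_clusters,
                      write_network)
from .promoters import (PromoterParams, extract_promoters, read_fasta,
                        read_gff3, read_promoter_fasta, write_promoter_fasta)
from .selection import (SelectionParams, read_gene_list,
                        select_discriminative_arrays)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration; the shipped defaults are the published
    analysis settings (q=0.25, f=0.70, r0=0.90, promoters 50-1000 bp,
    10 motifs of width 6-12 over an order-3 background, support >= 4)."""

    expression: str = ""
    positive_list: str = ""
    candidate_list: str = ""
    promoter_fasta: str | None = None
    genome_fasta: str | None = None
    gff3: str | None = None
    tfbs_library: str | None = None
    go_annotation: str | None = None
    out_dir: str = "results"

    log2: bool = False
    log2_offset: float = 1.0
    quantile_normalize: bool = True

    q: float = 0.25
    f: float = 0.70
    r0: float = 0.90
    min_cluster_size: int = 5

    promoter_max_length: int = 1000
    promoter_min_length: int = 50

    n_motifs: int = 10
    w_min: int = 6
    w_max: int = 12
    background_order: int = 3
    max_seeds: int = 1000
    min_gene_support: int = 4

    consensus_patterns: dict = field(default_factory=dict)
    n_shuffles: int = 1000
    seed: int = 1

    def __post_init__(self):
        # triggers the owning modules' invariant checks before any computation
        SelectionParams(q=self.q, f=self.f)
        NetworkParams(r0=self.r0, min_cluster_size=self.min_cluster_size)
        MotifParams(n_motifs=self.n_motifs, w_min=self.w_min, w_max=self.w_max,
                    background_order=self.background_order)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _load_promoters(config: PipelineConfig):
    pp = PromoterParams(max_length=config.promoter_max_length,
                        min_length=config.promoter_min_length)
    if config.promoter_fasta:
        return read_promoter_fasta(config.promoter_fasta, pp)
    if config.genome_fasta and config.gff3:
        genome = read_fasta(config.genome_fasta)
        genes = read_gff3(config.gff3)
        return extract_promoters(genes, genome, pp)
    return None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.content_hash(), "seed": config.seed,
                    "version": __version__, "stages": {}}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("normalize")
        m = read_expression_matrix(config.expression)
        if config.log2:
            m = log2_transform(m, config.log2_offset)
        if config.quantile_normalize and m.shape[1] >= 2:
            m = quantile_normalize(m)
        write_expression_matrix(m, out / "normalized_matrix.tsv")
        report["stages"]["normalize"] = {"n_genes": m.shape[0], "n_arrays": m.shape[1]}
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'normalize' failed on "
                           f"{config.expression}: {e}") from e

    try:
        stage("select-arrays")
        positive = read_gene_list(config.positive_list)
        sel = select_discriminative_arrays(m, positive,
                                           SelectionParams(q=config.q, f=config.f))
        sel.to_tsv(out / "array_selection.tsv")
        report["stages"]["selection"] = {"n_arrays_selected": sel.n_selected}
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'select-arrays' failed on "
                           f"{config.positive_list}: {e}") from e

    try:
        stage("network")
        candidates = read_gene_list(config.candidate_list).gene_ids
        nparams = NetworkParams(r0=config.r0, min_cluster_size=config.min_cluster_size)
        arrays = sel.selected_arrays
        if len(arrays) < 3:
            warnings.warn("fewer than 3 arrays selected: network stage emits "
                          "an empty network")
            import networkx as nx
            from .network import CoexpressionNetwork
            net = CoexpressionNetwork(nx.Graph(), nparams)
        else:
            net = build_network(m, candidates, arrays, nparams)
        clusters = extract_clusters(net)
        write_network(net, out / "network_edges.tsv", format="edge-list")
        write_network(net, out / "network.graphml", format="graphml")
        clusters.to_tsv(out / "clusters.tsv")
        report["stages"]["network"] = {
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.n_edges,
            "cluster_sizes": {c.cluster_id: len(c) for c in clusters},
            "n_remainder": len(clusters.remainder),
        }
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'network' failed on "
                           f"{config.candidate_list}: {e}") from e

    promoters = _load_promoters(config)
    library = read_meme_library(config.tfbs_library) if config.tfbs_library else None
    motif_report: dict = {}
    if promoters is not None:
        if config.genome_fasta:
            write_promoter_fasta(promoters, out / "promoters.fa")
        for cluster in clusters:
            try:
                cdir = out / cluster.cluster_id
                cdir.mkdir(exist_ok=True)
                sub = promoters.subset(cluster.members)
                crep: dict = {"n_promoters": len(sub)}
                if len(sub) >= 2:
                    mparams = MotifParams(
                        n_motifs=config.n_motifs, w_min=config.w_min,
                        w_max=config.w_max, background_order=config.background_order,
                        max_seeds=config.max_seeds,
                        seed=derive_seed(config.seed, "motifs", cluster.cluster_id))
                    bg = train_markov_background(sub, k=config.background_order)
                    found = discover_motifs_zoops(sub, mparams, bg)
                    kept = filter_motifs_by_gene_support(
                        found, sub, min_genes=config.min_gene_support)
                    write_meme(found, cdir / "motifs.meme")
                    write_meme(kept, cdir / "motifs_supported.meme")
                    with open(cdir / "motif_sites.tsv", "w") as fh:
                        fh.write("motif\tgene_id\tstart\tstrand\tsequence\n")
                        for mo in found:
                            for s in mo.sites:
                                fh.write(f"{mo.name}\t{s.gene_id}\t{s.start}"
                                         f"\t{s.strand}\t{s.sequence}\n")
                    crep["n_motifs_found"] = len(found)
                    crep["n_motifs_supported"] = len(kept)
                    if library is not None and kept:
                        comps = []
                        for mo in kept:
                            comps.extend(compare_motif_to_library(
                                mo, library, n_shuffles=config.n_shuffles,
                                seed=derive_seed(config.seed, "tomtom",
                                                 cluster.cluster_id, mo.name)))
                        comparisons_to_tsv(comps, cdir / "tfbs_comparisons.tsv")
                        crep["n_library_comparisons"] = len(comps)
                scans: dict = {}
                for name, pat in sorted(config.consensus_patterns.items()):
                    res = scan_consensus(sub, ConsensusPattern(pat, name))
                    res.to_tsv(cdir / f"scan_{name}.tsv")
                    scans[name] = {"n_occurrences": len(res.occurrences),
                                   "n_genes_with_hit": res.n_genes_with_hit()}
                if scans:
                    crep["consensus_scans"] = scans
                motif_report[cluster.cluster_id] = crep
            except Exception as e:
                raise RuntimeError(f"pipeline stage 'motifs' failed on cluster "
                                   f"{cluster.cluster_id}: {e}") from e
    report["stages"]["motifs"] = motif_report

    if config.go_annotation:
        try:
            stage("enrich")
            annot = read_go_annotation(config.go_annotation).restrict(m.gene_ids)
            enr_rep = {}
            frames = []
            for cluster in clusters:
                if not (cluster.members & annot.universe):
                    continue
                df = enrich_cluster(cluster, annot)
                df.insert(0, "cluster", cluster.cluster_id)
                frames.append(df)
                enr_rep[cluster.cluster_id] = {
                    "n_terms_tested": int(len(df)),
                    "n_significant": int((df["p_adj"] < 0.05).sum()),
                }
            if frames:
                import pandas as pd
                pd.concat(frames).to_csv(out / "enrichment.tsv", sep="\t",
                                         index=False, lineterminator="\n")
            report["stages"]["enrichment"] = enr_rep
        except Exception as e:
            raise RuntimeError(f"pipeline stage 'enrich' failed on "
                               f"{config.go_annotation}: {e}") from e

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    config.to_yaml(out / "config_used.yaml")
    return report


def make_fixture(outdir, seed: int = 1, n_motifs: int = 3,
                 promoter_length: int = 300, n_shuffles: int = 200) -> PipelineConfig:
    """Write a coherent synthetic dataset plus a matching configuration.

    The motif stage is scaled down (fewer motifs, shorter promoters) so the
    end-to-end run stays fast; the statistical structure is unchanged.
    """
    from .memeio import write_meme
    from .selection import write_gene_list
    from .simulate import (simulate_expression, simulate_go_annotation,
                           simulate_promoters)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m, positive, candidates, etruth = simulate_expression(seed=derive_seed(seed, "expr"))
    write_expression_matrix(m, outdir / "expression.tsv")
    write_gene_list(positive.gene_ids, outdir / "positive_list.txt")
    write_gene_list(candidates, outdir / "candidate_list.txt")
    etruth.to_json(outdir / "truth_expression.json")

    module_genes = sorted(etruth.module_assignments)
    pset, ptruth = simulate_promoters(
        n_seqs=len(module_genes), length=promoter_length,
        n_carriers=sum(1 for g, mi in etruth.module_assignments.items() if mi == 0),
        seed=derive_seed(seed, "prom"),
        gene_ids=sorted([g for g, mi in etruth.module_assignments.items() if mi == 0])
        + sorted([g for g, mi in etruth.module_assignments.items() if mi != 0]))
    write_promoter_fasta(pset, outdir / "promoters.fa")
    ptruth.to_json(outdir / "truth_promoters.json")

    module0 = [g for g, mi in etruth.module_assignments.items() if mi == 0]
    module1 = [g for g, mi in etruth.module_assignments.items() if mi == 1]
    annot, gtruth = simulate_go_annotation(
        sorted(candidates), planted=[(module0, 0.9), (module1, 0.9)],
        seed=derive_seed(seed, "go"))
    annot.to_tsv(outdir / "go_annotation.tsv")
    gtruth.to_json(outdir / "truth_go.json")

    # a small known-TFBS library containing the planted motif's PPM
    import numpy as np

    from ._util import BASE_INDEX, IUPAC
    rng = np.random.default_rng(derive_seed(seed, "lib"))
    planted = ptruth.planted_consensus
    mat = np.empty((len(planted), 4))
    for i, c in enumerate(planted):
        row = np.full(4, 0.04)
        hits = [BASE_INDEX[b] for b in IUPAC[c]]
        row[hits] = (1.0 - 0.04 * (4 - len(hits))) / len(hits)
        mat[i] = row
    decoys = [(f"decoy_{i}", rng.dirichlet([0.5] * 4, size=8)) for i in range(4)]
    write_meme([("planted_element", mat)] + decoys, outdir / "tfbs_library.meme")

    cfg = PipelineConfig(
        expression=str(outdir / "expression.tsv"),
        positive_list=str(outdir / "positive_list.txt"),
        candidate_list=str(outdir / "candidate_list.txt"),
        promoter_fasta=str(outdir / "promoters.fa"),
        tfbs_library=str(outdir / "tfbs_library.meme"),
        go_annotation=str(outdir / "go_annotation.tsv"),
        out_dir=str(outdir / "results"),
        quantile_normalize=False,  # generator emits the normalized scale
        n_motifs=n_motifs,
        n_shuffles=n_shuffles,
        consensus_patterns={"planted": planted},
        seed=seed,
    )
    cfg.to_yaml(outdir / "config.yaml")
    return cfg
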