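"""Genome/annotation IO and core-promoter extraction.

Promoters are the up-to-``max_length`` bases immediately 5' of a gene's
5' end (the gene-model start on + genes, the end on - genes), truncated at
the nearest annotated gene body on either strand, and dropped when shorter
than ``min_length``. Sequences are reported 5'->3' with respect to the
gene's strand; lowercase (repeat-masked) positions are retained but treated
as unusable by downstream motif steps.

Internally coordinates are 0-based half-open; GFF3's 1-based inclusive
coordinates are converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

from ._util import revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """A gene feature; start/end are 1-based inclusive as in GFF3."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    @property
    def start0(self) -> int:  # 0-based half-open start
        return self.start - 1

    @property
    def end0(self) -> int:  # 0-based half-open end
        return self.end


@dataclass(frozen=True)
class PromoterParams:
    max_length: int = 1000
    min_length: int = 50
    stop_at_neighbour: bool = True
    use_repeat_mask: bool = True


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    chromosome: str
    strand: str
    start: int  # 1-based inclusive, genomic, for the header
    end: int
    seq: str

    def __len__(self):
        return len(self.seq)


@dataclass
class PromoterSet:
    """Mapping gene id -> Promoter, plus the extraction parameters."""

    promoters: dict
    params: PromoterParams = field(default_factory=PromoterParams)

    def __getitem__(self, gene_id):
        return self.promoters[gene_id]

    def __iter__(self):
        return iter(self.promoters.values())

    def __len__(self):
        return len(self.promoters)

    def __contains__(self, gene_id):
        return gene_id in self.promoters

    @property
    def gene_ids(self) -> list:
        return list(self.promoters)

    def sequences(self) -> dict:
        return {g: p.seq for g, p in self.promoters.items()}

    def subset(self, gene_ids) -> "PromoterSet":
        keep = {g: p for g, p in self.promoters.items() if g in set(gene_ids)}
        return PromoterSet(keep, self.params)


def read_fasta(path) -> dict:
    """FASTA -> {first header token: sequence string}."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq)
    return seqs


def read_gff3(path) -> list:
    """Parse GFF3 'gene' features into GeneModel records (1-based inclusive)."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(gid, feat.seqid, feat.strand, feat.start, feat.end))
    return genes


def extract_promoters(genes, genome: dict,
                      params: PromoterParams = PromoterParams()) -> PromoterSet:
    """Extract core promoters under the length and neighbour-truncation rules."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.chromosome not in genome:
            raise ValueError(f"{g.gene_id}: chromosome {g.chromosome!r} not in genome")
        if g.end0 > len(genome[g.chromosome]):
            raise ValueError(f"{g.gene_id}: end {g.end} exceeds length of {g.chromosome}")
        by_chrom.setdefault(g.chromosome, []).append(g)

    out = {}
    dropped = []
    for chrom, glist in by_chrom.items():
        seq = genome[chrom]
        for g in glist:
            if g.strand == "+":
                tss = g.start0
                lo = max(0, tss - params.max_length)
                if params.stop_at_neighbour:
                    for o in glist:
                        if o.gene_id == g.gene_id:
                            continue
                        # any gene body intersecting [lo, tss) pushes lo right
                        if o.start0 < tss and o.end0 > lo:
                            lo = max(lo, min(o.end0, tss))
                prom = seq[lo:tss]
                start1, end1 = lo + 1, tss
            else:
                tss = g.end0
                hi = min(len(seq), tss + params.max_length)
                if params.stop_at_neighbour:
                    for o in glist:
                        if o.gene_id == g.gene_id:
                            continue
                        if o.end0 > tss and o.start0 < hi:
                            hi = min(hi, max(o.start0, tss))
                prom = revcomp(seq[tss:hi])
                start1, end1 = tss + 1, hi
            if len(prom) < params.min_length:
                dropped.append(g.gene_id)
                continue
            out[g.gene_id] = Promoter(g.gene_id, chrom, g.strand, start1, end1, prom)
    if dropped:
        logger.info("dropped %d gene(s) with promoter shorter than %d bp: %s",
                    len(dropped), params.min_length, dropped[:10])
    return PromoterSet(out, params)


def write_promoter_fasta(pset: PromoterSet, path) -> None:
    """Headers: gene_id|chrom|strand|start-end (1-based inclusive)."""
    with open(path, "w") as fh:
        for p in pset:
            fh.write(f">{p.gene_id}|{p.chromosome}|{p.strand}|{p.start}-{p.end}\n")
            for i in range(0, len(p.seq), 70):
                fh.write(p.seq[i:i + 70] + "\n")


def read_promoter_fasta(path, params: PromoterParams = PromoterParams()) -> PromoterSet:
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) == 4:
            gid, chrom, strand, span = parts
            start, end = (int(x) for x in span.split("-"))
        else:
            gid, chrom, strand, start, end = rec.id, ".", "+", 1, len(rec.seq)
        out[gid] = Promoter(gid, chrom, strand, start, end, str(rec.seq))
    return PromoterSet(out, params)
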