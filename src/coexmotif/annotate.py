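"""Motif support counting, consensus scanning, and PWM library comparison.

``scan_consensus`` finds exact degenerate (IUPAC) matches on both strands;
the ``no_overlap`` option applies the greedy left-to-right rule per strand
(after a match at [i, i+w) the next search starts at i+w), mirroring the
"noov" behaviour of classic pattern scanners. Repeat-masked (lowercase)
positions never match.

``compare_motif_to_library`` is a Tomtom-style comparison: ungapped sliding
alignment of the query PPM against each library PPM in both orientations,
column similarity = Pearson correlation of the two 4-vectors, alignment
score = mean column similarity, and an empirical p-value from column-
shuffled targets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import IUPAC, IUPAC_FROM_SET, revcomp
from .discovery import Motif

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusPattern:
    pattern: str
    name: str = ""

    def __post_init__(self):
        if not self.pattern:
            raise ValueError("empty consensus pattern")
        bad = [c for c in self.pattern if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC letter(s) in pattern: {bad}")

    def __len__(self):
        return len(self.pattern)

    def reverse_complement(self) -> "ConsensusPattern":
        return ConsensusPattern(revcomp(self.pattern), self.name)


@dataclass(frozen=True)
class MotifOccurrence:
    gene_id: str
    start: int  # 0-based offset on the forward promoter strand
    strand: str
    sequence: str  # forward-strand slice of the promoter


@dataclass
class ScanResult:
    occurrences: list
    presence: pd.DataFrame  # index gene_id; columns n_plus, n_minus, present

    def n_genes_with_hit(self) -> int:
        return int(self.presence["present"].sum())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tstart\tstrand\tsequence\n")
            for o in self.occurrences:
                fh.write(f"{o.gene_id}\t{o.start}\t{o.strand}\t{o.sequence}\n")

    def to_bed(self, path, name: str = "site") -> None:
        with open(path, "w") as fh:
            for o in self.occurrences:
                fh.write(f"{o.gene_id}\t{o.start}\t{o.start + len(o.sequence)}"
                         f"\t{name}\t0\t{o.strand}\n")


@dataclass
class TFBSLibrary:
    """Named position probability matrices of known TF binding sites."""

    motifs: dict  # name -> (w, 4) ndarray
    source: str = ""

    def __post_init__(self):
        for name, m in self.motifs.items():
            m = np.asarray(m, dtype=float)
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"library motif {name!r}: rows must sum to 1")
            self.motifs[name] = m

    def __len__(self):
        return len(self.motifs)

    def items(self):
        return self.motifs.items()


@dataclass(frozen=True)
class MotifComparison:
    query: str
    target: str
    offset: int
    orientation: str  # orientation of the target relative to the query
    score: float
    p_value: float
    n_shuffles: int
    seed: int


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[c]}]" for c in pattern))


def _scan_one(seq: str, pattern: str, no_overlap: bool):
    """Match offsets of an IUPAC pattern on one strand of one sequence.
    Lowercase (masked) positions are replaced by a sentinel so they never
    match."""
    clean = "".join(c if c in "ACGT" else "#" for c in seq)
    rx = _iupac_regex(pattern)
    if no_overlap:
        return [m.start() for m in rx.finditer(clean)]
    return [m.start() for m in re.finditer(f"(?={rx.pattern})", clean)]


def scan_consensus(promoters, pattern, both_strands: bool = True,
                   no_overlap: bool = True) -> ScanResult:
    """All exact degenerate matches of ``pattern`` across the promoter set.

    Reverse-strand matches are found by matching the reverse complement of
    the pattern against the forward sequence; occurrences carry forward
    coordinates, strand '-', and the forward-strand slice as sequence.
    """
    if isinstance(pattern, str):
        pattern = ConsensusPattern(pattern)
    seqs = (promoters.sequences() if hasattr(promoters, "sequences")
            else dict(promoters))
    rc = pattern.reverse_complement().pattern
    w = len(pattern)
    occ = []
    rows = []
    for gid, seq in seqs.items():
        plus = _scan_one(seq, pattern.pattern, no_overlap)
        minus = _scan_one(seq, rc, no_overlap) if both_strands else []
        for i in plus:
            occ.append(MotifOccurrence(gid, i, "+", seq[i:i + w].upper()))
        for i in minus:
            occ.append(MotifOccurrence(gid, i, "-", seq[i:i + w].upper()))
        rows.append((gid, len(plus), len(minus), bool(plus or minus)))
    presence = pd.DataFrame(rows, columns=["gene_id", "n_plus", "n_minus",
                                           "present"]).set_index("gene_id")
    return ScanResult(occ, presence)


def count_gene_support(motif_or_pattern, promoters, **scan_kwargs) -> int:
    """Distinct genes with at least one occurrence (either strand).

    For a discovered :class:`Motif` the ZOOPS site list is used directly;
    for an IUPAC pattern the promoters are scanned.
    """
    if isinstance(motif_or_pattern, Motif):
        return motif_or_pattern.n_genes_with_site
    if hasattr(promoters, "__len__") and len(promoters) == 0:
        return 0
    return scan_consensus(promoters, motif_or_pattern, **scan_kwargs).n_genes_with_hit()


def filter_motifs_by_gene_support(motifs, promoters=None, min_genes: int = 4) -> list:
    """Keep motifs whose site list covers at least ``min_genes`` genes."""
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    return [m for m in motifs if m.n_genes_with_site >= min_genes]


def _column_scores(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of aligned columns (rows of the PPMs); a column
    with zero variance (e.g. all 0.25) scores 0 against anything."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac ** 2).sum(axis=1) * (bc ** 2).sum(axis=1))
    out = np.zeros(len(num))
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def _best_alignment(q: np.ndarray, t: np.ndarray, min_overlap: int):
    """Best (score, offset, orientation) over ungapped alignments of target
    against query, both orientations. Offset is the position of the target's
    first column relative to the query's first column."""
    best = (-np.inf, 0, "+")
    wq, wt = len(q), len(t)
    for orient, tm in (("+", t), ("-", t[::-1, ::-1])):
        for off in range(-(wt - min_overlap), wq - min_overlap + 1):
            qs, qe = max(0, off), min(wq, off + wt)
            if qe - qs < min_overlap:
                continue
            score = float(_column_scores(q[qs:qe], tm[qs - off:qe - off]).mean())
            if score > best[0]:
                best = (score, off, orient)
    return best


def compare_motif_to_library(query: Motif, lib: TFBSLibrary, min_overlap: int = 4,
                             n_shuffles: int = 1000, seed: int = 0) -> list:
    """Rank library motifs by similarity to the query.

    Empirical p-value: fraction of column-shuffled targets whose best
    alignment scores at least as well as the observed one, with the usual
    +1 correction.
    """
    if len(lib) == 0:
        raise ValueError("empty TFBS library")
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    q = np.asarray(query.matrix, dtype=float)
    results = []
    for name, t in lib.items():
        mo = min(min_overlap, len(q), len(t))
        obs, off, orient = _best_alignment(q, t, mo)
        rng = np.random.default_rng([seed & 0x7FFFFFFF, abs(hash(name)) % (2 ** 31)])
        hits = 0
        for _ in range(n_shuffles):
            perm = rng.permutation(len(t))
            s, _, _ = _best_alignment(q, t[perm], mo)
            if s >= obs - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_shuffles)
        results.append(MotifComparison(query.name, name, off, orient,
                                       obs, p, n_shuffles, seed))
    results.sort(key=lambda r: (r.p_value, -r.score, r.target))
    return results


def comparisons_to_tsv(comparisons, path) -> None:
    with open(path, "w") as fh:
        fh.write("query\ttarget\toffset\torientation\tscore\tp_value\n")
        for c in comparisons:
            fh.write(f"{c.query}\t{c.target}\t{c.offset}\t{c.orientation}"
                     f"\t{c.score:.6f}\t{c.p_value:.6g}\n")


def pwm_to_consensus(motif: Motif, inclusion_threshold: float = 0.25) -> ConsensusPattern:
    """Per column, the IUPAC code of the bases with probability >= threshold
    (an empty set maps to N)."""
    if not (0 < inclusion_threshold <= 1):
        raise ValueError("inclusion_threshold must be in (0, 1]")
    letters = []
    for row in motif.matrix:
        bases = frozenset("ACGT"[i] for i in range(4) if row[i] >= inclusion_threshold)
        letters.append(IUPAC_FROM_SET.get(bases, "N") if bases else "N")
    return ConsensusPattern("".join(letters), motif.name)
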