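"""ZOOPS (zero-or-one-occurrence-per-sequence) EM motif discovery.

Each promoter either contains one motif site (prior lambda) or is pure
background. For a sequence s with eligible site offsets j = 1..m_s the
mixture likelihood is

    P(s) = (1 - lambda) * P(s | background)
           + (lambda / m_s) * sum_j P(s with site at j | theta, background)

where P(s with site at j) replaces the background terms inside the site
window by the position probability matrix theta. EM alternates posterior
site responsibilities (E) with theta/lambda re-estimation (M); the
objective it ascends (mixture log-likelihood plus the Dirichlet pseudocount
prior on theta) is non-decreasing by the usual EM argument.

Motifs are found sequentially: after a motif is accepted its sites are
erased (masked) and the search repeats, up to ``n_motifs`` times, each time
scanning all widths in [w_min, w_max] from enumerated-substring seeds.
Repeat-masked (lowercase) positions never host sites or seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._util import BASES, decode_seq, encode_seq, revcomp_enc
from .background import MarkovBackground, train_markov_background

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifSite:
    gene_id: str
    start: int  # 0-based offset on the forward promoter strand
    strand: str
    sequence: str  # site in motif orientation


@dataclass
class Motif:
    """A discovered (or library) motif.

    ``matrix`` is the (width x 4) position probability matrix over A,C,G,T;
    every row sums to 1. ``sites`` lists at most one site per gene (ZOOPS).
    """

    matrix: np.ndarray
    name: str = ""
    sites: list = field(default_factory=list)
    log_likelihood_ratio: float = 0.0
    lambda_: float = 0.0
    trace: list = field(default_factory=list)
    seed_info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("motif matrix must be (width, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("motif matrix rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def nsites(self) -> int:
        return len(self.sites)

    @property
    def n_genes_with_site(self) -> int:
        return len({s.gene_id for s in self.sites})

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def information_content(self) -> float:
        """Total IC in bits against the uniform (2 bits/column) reference."""
        p = np.clip(self.matrix, 1e-12, 1.0)
        return float((2.0 + (p * np.log2(p)).sum(axis=1)).sum())

    def reverse_complement(self) -> "Motif":
        return Motif(self.matrix[::-1, ::-1].copy(), name=self.name + "_rc")


@dataclass(frozen=True)
class MotifParams:
    n_motifs: int = 10
    w_min: int = 6
    w_max: int = 12
    background_order: int = 3
    background_alpha: float = 0.5
    max_iter: int = 200
    tol: float = 1e-6
    max_seeds: int = 1000
    n_starts: int = 3
    seed_p0: float = 0.7
    pseudocount: float = 0.01
    min_llr: float = 1e-6
    both_strands: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.w_min > self.w_max:
            raise ValueError("w_min must be <= w_max")
        if self.n_motifs < 1:
            raise ValueError("n_motifs must be >= 1")


def _as_seq_dict(sequences) -> dict:
    if hasattr(sequences, "sequences"):  # PromoterSet
        return sequences.sequences()
    if isinstance(sequences, dict):
        return dict(sequences)
    return {f"seq{i}": s for i, s in enumerate(sequences)}


class _Windows:
    """All eligible site windows of one width across all sequences/strands."""

    def __init__(self, encs_f, encs_r, bg_f, bg_r, w, both_strands):
        bases, bg, seq_idx, strand, start_fwd = [], [], [], [], []
        for i, (ef, er, lf, lr) in enumerate(zip(encs_f, encs_r, bg_f, bg_r)):
            L = len(ef)
            if L < w:
                continue
            strands = [(0, ef, lf)] + ([(1, er, lr)] if both_strands else [])
            for st, enc, lp in strands:
                clean = (enc >= 0).astype(np.int64)
                csum = np.concatenate([[0], np.cumsum(clean)])
                ok = (csum[w:] - csum[:-w]) == w  # window fully unmasked
                if not ok.any():
                    continue
                offs = np.nonzero(ok)[0]
                win = np.lib.stride_tricks.sliding_window_view(enc, w)[offs]
                lpc = np.concatenate([[0.0], np.cumsum(np.where(np.isnan(lp), 0.0, lp))])
                bgw = lpc[offs + w] - lpc[offs]
                bases.append(win)
                bg.append(bgw)
                seq_idx.append(np.full(len(offs), i, dtype=np.int64))
                strand.append(np.full(len(offs), st, dtype=np.int8))
                start_fwd.append(offs if st == 0 else L - offs - w)
        if bases:
            self.bases = np.concatenate(bases).astype(np.int64)
            self.bg = np.concatenate(bg)
            self.seq_idx = np.concatenate(seq_idx)
            self.strand = np.concatenate(strand)
            self.start_fwd = np.concatenate(start_fwd)
        else:
            self.bases = np.zeros((0, w), dtype=np.int64)
            self.bg = np.zeros(0)
            self.seq_idx = np.zeros(0, dtype=np.int64)
            self.strand = np.zeros(0, dtype=np.int8)
            self.start_fwd = np.zeros(0, dtype=np.int64)
        self.w = w
        self.n = len(self.bg)
        self.n_seqs = len(encs_f)
        self.m_per_seq = np.bincount(self.seq_idx, minlength=self.n_seqs).astype(float)
        # one-hot window encoding, (n, 4w): column 4*pos + base
        flat = self.bases + 4 * np.arange(w)[None, :]
        oh = np.zeros((self.n, 4 * w))
        if self.n:
            oh[np.arange(self.n)[:, None], flat] = 1.0
        self.onehot = oh


def _zoops_objective_terms(lo, ws, lam):
    """Per-sequence a_s = (lam/m_s) sum_j exp(lo_j), for active sequences."""
    e = np.exp(lo)
    ssum = np.bincount(ws.seq_idx, weights=e, minlength=ws.n_seqs)
    active = ws.m_per_seq > 0
    a = np.zeros(ws.n_seqs)
    a[active] = lam * ssum[active] / ws.m_per_seq[active]
    return a, active


def _run_em(ws: _Windows, theta0: np.ndarray, params: MotifParams):
    """EM to convergence; returns (theta, lam, trace, llr)."""
    active = ws.m_per_seq > 0
    n_active = int(active.sum())
    theta = theta0.copy()
    lam = 1.0 / np.sqrt(max(n_active, 1))
    pc = params.pseudocount
    trace = []
    prev = -np.inf
    m_win = ws.m_per_seq[ws.seq_idx]
    for _ in range(params.max_iter):
        lo = ws.onehot @ np.log(theta).ravel() - ws.bg
        a, _ = _zoops_objective_terms(lo, ws, lam)
        denom = (1.0 - lam) + a
        obj_rel = float(np.log(denom[active]).sum())
        obj = obj_rel + pc * float(np.log(theta).sum())
        trace.append(obj)
        if obj - prev < params.tol and np.isfinite(prev):
            break
        prev = obj
        # E-step: window responsibilities
        z = (lam / m_win) * np.exp(lo) / denom[ws.seq_idx]
        # M-step
        counts = (ws.onehot.T @ z).reshape(ws.w, 4)
        theta = (counts + pc) / (counts.sum(axis=1, keepdims=True) + 4 * pc)
        q = a[active] / denom[active]
        lam = float(np.clip(q.mean(), 1e-6, 1.0 - 1e-6))
    lo = ws.onehot @ np.log(theta).ravel() - ws.bg
    a, _ = _zoops_objective_terms(lo, ws, lam)
    llr = float(np.log((1.0 - lam) + a[active]).sum())
    return theta, lam, trace, llr


def _seed_thetas(ws: _Windows, seed_idx, p0):
    w = ws.w
    n = len(seed_idx)
    lmat = np.full((n, 4 * w), np.log((1 - p0) / 3.0))
    flat = ws.bases[seed_idx] + 4 * np.arange(w)[None, :]
    lmat[np.arange(n)[:, None], flat] = np.log(p0)
    return lmat


def _score_seeds(ws: _Windows, seed_idx, p0, chunk=128):
    """Initial ZOOPS objective of every seed start, vectorized in chunks."""
    active = ws.m_per_seq > 0
    lam0 = 1.0 / np.sqrt(max(int(active.sum()), 1))
    lmat = _seed_thetas(ws, seed_idx, p0)
    out = np.empty(len(seed_idx))
    for lo_idx in range(0, len(seed_idx), chunk):
        block = lmat[lo_idx:lo_idx + chunk]
        s = ws.onehot @ block.T - ws.bg[:, None]  # (n_win, chunk)
        e = np.exp(s)
        ssum = np.zeros((ws.n_seqs, e.shape[1]))
        np.add.at(ssum, ws.seq_idx, e)
        a = lam0 * ssum[active] / ws.m_per_seq[active][:, None]
        out[lo_idx:lo_idx + chunk] = np.log((1.0 - lam0) + a).sum(axis=0)
    return out


def discover_motifs_zoops(promoters, params: MotifParams = MotifParams(),
                          background: MarkovBackground | None = None) -> list:
    """Sequential ZOOPS EM discovery of up to ``params.n_motifs`` motifs.

    Deterministic for a fixed ``params.seed``. Returns motifs ordered by
    their log-likelihood-ratio objective, best first.
    """
    seqs = _as_seq_dict(promoters)
    if len(seqs) < 2:
        raise ValueError("need at least 2 promoters")
    if background is None:
        background = train_markov_background(
            seqs, k=params.background_order, alpha=params.background_alpha,
            both_strands=params.both_strands)
    names = list(seqs)
    encs_f = [encode_seq(s) for s in seqs.values()]
    motifs = []
    for t in range(params.n_motifs):
        encs_r = [revcomp_enc(e) for e in encs_f]
        bg_f = [background.position_log_probs_enc(e) for e in encs_f]
        bg_r = [background.position_log_probs_enc(e) for e in encs_r]
        best = None
        for w in range(params.w_min, params.w_max + 1):
            ws = _Windows(encs_f, encs_r, bg_f, bg_r, w, params.both_strands)
            if ws.n == 0 or (ws.m_per_seq > 0).sum() < 2:
                continue
            fwd = np.nonzero(ws.strand == 0)[0]
            if len(fwd) == 0:
                continue
            rng = np.random.default_rng([params.seed & 0x7FFFFFFF, t, w])
            if len(fwd) > params.max_seeds:
                pick = rng.choice(len(fwd), size=params.max_seeds, replace=False)
                seed_idx = fwd[np.sort(pick)]
            else:
                seed_idx = fwd
            scores = _score_seeds(ws, seed_idx, params.seed_p0)
            order = np.argsort(-scores, kind="stable")[:params.n_starts]
            for oi in order:
                si = seed_idx[oi]
                theta0 = np.full((w, 4), (1 - params.seed_p0) / 3.0)
                theta0[np.arange(w), ws.bases[si]] = params.seed_p0
                theta, lam, trace, llr = _run_em(ws, theta0, params)
                cand = (llr, -w, theta, lam, trace, ws,
                        decode_seq(ws.bases[si]))
                if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                    best = cand
        if best is None or best[0] <= params.min_llr:
            logger.info("motif search stopped after %d motif(s): no improvement "
                        "over background", len(motifs))
            break
        llr, negw, theta, lam, trace, ws, seed_str = best
        w = -negw
        # site assignment: one site max per sequence, posterior > 0.5
        lo = ws.onehot @ np.log(theta).ravel() - ws.bg
        a, _ = _zoops_objective_terms(lo, ws, lam)
        denom = (1.0 - lam) + a
        sites = []
        for s in range(ws.n_seqs):
            if ws.m_per_seq[s] == 0:
                continue
            q = a[s] / denom[s]
            if q <= 0.5:
                continue
            idx = np.nonzero(ws.seq_idx == s)[0]
            j = idx[int(np.argmax(lo[idx]))]
            sites.append(MotifSite(names[s], int(ws.start_fwd[j]),
                                   "+" if ws.strand[j] == 0 else "-",
                                   decode_seq(ws.bases[j])))
            encs_f[s][ws.start_fwd[j]:ws.start_fwd[j] + w] = -1  # erase
        motifs.append(Motif(theta, name=f"motif_{t + 1}", sites=sites,
                            log_likelihood_ratio=llr, lambda_=lam, trace=list(trace),
                            seed_info={"seed_substring": seed_str, "width": w}))
    motifs.sort(key=lambda m: -m.log_likelihood_ratio)
    return motifs


def zoops_log_likelihood(motif: Motif, sequences, background: MarkovBackground,
                         lam: float, both_strands: bool = True) -> float:
    """ZOOPS mixture log-likelihood of ``sequences`` under one motif.

    Sequences shorter than the motif width (or fully masked) contribute
    their background-only term. Masked positions are excluded throughout.
    """
    if not (0 < lam < 1):
        raise ValueError("lambda must be in (0, 1)")
    seqs = _as_seq_dict(sequences)
    ltheta = np.log(np.clip(motif.matrix, 1e-300, 1.0))
    total = 0.0
    w = motif.width
    for s in seqs.values():
        enc = encode_seq(s)
        variants = [enc] + ([revcomp_enc(enc)] if both_strands else [])
        bg_ll = float(np.nansum(background.position_log_probs_enc(enc)))
        ratios = []
        for v in variants:
            lp = background.position_log_probs_enc(v)
            for j in range(0, len(v) - w + 1):
                win = v[j:j + w]
                if (win < 0).any():
                    continue
                site_bg = float(np.sum(lp[j:j + w]))
                site_m = float(ltheta[np.arange(w), win].sum())
                ratios.append(site_m - site_bg)
        if not ratios:
            total += bg_ll
            continue
        ratios = np.asarray(ratios)
        mix = (1.0 - lam) + lam * float(np.mean(np.exp(ratios)))
        total += bg_ll + np.log(mix)
    return float(total)
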