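"""Order-k Markov background model for promoter DNA.

The background supplies P(base | preceding k-mer). Positions whose context
is interrupted (sequence start, repeat-masked base, N) fall back to the
longest clean lower-order context, whose conditionals are estimated from
the same counts. Training can count both strands, mirroring standard
upstream-sequence background construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import BASES, encode_seq, revcomp

logger = logging.getLogger(__name__)


@dataclass
class MarkovBackground:
    """Conditional probabilities for orders 0..k.

    ``probs[o]`` has shape (4**o, 4); each row sums to 1. ``alpha`` is the
    pseudocount added to every transition count during estimation.
    """

    order: int
    probs: dict
    alpha: float = 0.5
    both_strands: bool = True

    def context_probs(self, context: str) -> np.ndarray:
        """P(. | context) for a clean A/C/G/T context of length <= order."""
        o = len(context)
        idx = 0
        for c in context:
            idx = idx * 4 + BASES.index(c)
        return self.probs[o][idx]

    def position_log_probs(self, seq: str) -> np.ndarray:
        """Per-position log P(base_i | longest clean context); NaN at
        masked/ambiguous positions."""
        enc = encode_seq(seq)
        return self.position_log_probs_enc(enc)

    def position_log_probs_enc(self, enc: np.ndarray) -> np.ndarray:
        n = len(enc)
        out = np.full(n, np.nan)
        logp = {o: np.log(p) for o, p in self.probs.items()}
        clean_run = 0  # clean bases immediately before i
        for i in range(n):
            b = enc[i]
            if b < 0:
                clean_run = 0
                continue
            o = min(self.order, clean_run)
            idx = 0
            for j in range(i - o, i):
                idx = idx * 4 + int(enc[j])
            out[i] = logp[o][idx, b]
            clean_run += 1
        return out

    def log_prob(self, seq: str) -> float:
        """Log probability of the clean positions of ``seq``."""
        lp = self.position_log_probs(seq)
        return float(np.nansum(lp))

    def sample(self, length: int, rng: np.random.Generator) -> str:
        """Sample a sequence from the chain (lower orders seed the start)."""
        out = []
        enc = []
        for i in range(length):
            o = min(self.order, i)
            idx = 0
            for j in range(i - o, i):
                idx = idx * 4 + enc[j]
            p = self.probs[o][idx]
            b = int(rng.choice(4, p=p))
            enc.append(b)
            out.append(BASES[b])
        return "".join(out)

    @classmethod
    def random(cls, order: int, rng: np.random.Generator,
               concentration: float = 20.0) -> "MarkovBackground":
        """A random background: each context's conditionals are a symmetric
        Dirichlet draw. Used by the synthetic-data generator."""
        probs = {o: rng.dirichlet([concentration] * 4, size=4 ** o)
                 for o in range(order + 1)}
        return cls(order, probs, alpha=0.0)


def _clean_segments(enc: np.ndarray):
    """Maximal runs of A/C/G/T (values >= 0)."""
    n = len(enc)
    i = 0
    while i < n:
        if enc[i] < 0:
            i += 1
            continue
        j = i
        while j < n and enc[j] >= 0:
            j += 1
        yield enc[i:j]
        i = j


def train_markov_background(sequences, k: int = 3, alpha: float = 0.5,
                            both_strands: bool = True) -> MarkovBackground:
    """Estimate transition probabilities from k-mer -> base counts.

    Repeat-masked (lowercase) and ambiguous positions break contexts and are
    never counted. When the total usable length is <= 4**k the order falls
    back (with a warning) until enough data supports it.
    """
    if hasattr(sequences, "sequences"):  # PromoterSet
        seqs = list(sequences.sequences().values())
    elif isinstance(sequences, dict):
        seqs = list(sequences.values())
    else:
        seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences to train background on")
    if both_strands:
        seqs = seqs + [revcomp(s) for s in seqs]
    encs = [encode_seq(s) for s in seqs]
    usable = sum(int((e >= 0).sum()) for e in encs)
    if usable == 0:
        raise ValueError("no usable (unmasked A/C/G/T) positions in input")
    while k > 0 and usable <= 4 ** k:
        warnings.warn(f"only {usable} usable bases: falling back from order {k} to {k - 1}")
        k -= 1
    counts = {o: np.zeros((4 ** o, 4)) for o in range(k + 1)}
    pows = {o: 4 ** np.arange(o - 1, -1, -1) for o in range(1, k + 1)}
    for enc in encs:
        for seg in _clean_segments(enc):
            n = len(seg)
            counts[0][0] += np.bincount(seg, minlength=4)
            for o in range(1, k + 1):
                if n <= o:
                    break
                ctx = np.lib.stride_tricks.sliding_window_view(seg[:-1], o) @ pows[o]
                nxt = seg[o:]
                np.add.at(counts[o], (ctx, nxt), 1.0)
    probs = {}
    for o, c in counts.items():
        c = c + alpha
        rows = c.sum(axis=1, keepdims=True)
        # a context never seen and alpha=0 would be 0/0; make it uniform
        zero = rows[:, 0] == 0
        c[zero] = 1.0
        rows = c.sum(axis=1, keepdims=True)
        probs[o] = c / rows
    return MarkovBackground(k, probs, alpha=alpha, both_strands=both_strands)
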