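"""Shared small helpers: DNA alphabet, IUPAC codes, seed derivation."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# IUPAC degenerate DNA alphabet -> set of concrete bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
# inverse lookup: frozenset of bases -> IUPAC letter
IUPAC_FROM_SET = {frozenset(v): k for k, v in IUPAC.items()}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC-aware; preserves case (masking)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode DNA to int8: A,C,G,T -> 0..3; anything else (incl. lowercase
    repeat-masked bases and N) -> -1, i.e. unusable for motif work."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def decode_seq(enc: np.ndarray) -> str:
    return "".join(BASES[i] if i >= 0 else "N" for i in enc)


def revcomp_enc(enc: np.ndarray) -> np.ndarray:
    out = enc[::-1].copy()
    valid = out >= 0
    out[valid] = 3 - out[valid]
    return out


def derive_seed(master: int, *tokens) -> int:
    """Derive a per-stage 31-bit seed from a master seed and stage tokens."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF] + [abs(hash(t)) % (2**31) for t in tokens])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
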