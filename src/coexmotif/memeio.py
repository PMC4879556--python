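"""Minimal MEME motif text format: write by hand, read via Bio.motifs.

The minimal format carries the alphabet, background letter frequencies and
one letter-probability matrix per motif with its width and site count —
enough to exchange PPMs with the MEME Suite tools.
"""

from __future__ import annotations

import numpy as np

from .annotate import TFBSLibrary
from .discovery import Motif


def write_meme(motifs, path, background_freqs=None) -> None:
    """Write motifs (Motif objects or (name, matrix) pairs) in minimal MEME
    format."""
    if background_freqs is None:
        background_freqs = [0.25, 0.25, 0.25, 0.25]
    items = []
    for i, m in enumerate(motifs):
        if isinstance(m, Motif):
            items.append((m.name or f"motif_{i + 1}", m.matrix, max(m.nsites, 1)))
        else:
            name, mat = m
            items.append((name, np.asarray(mat, dtype=float), 20))
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {0:.5f} C {1:.5f} G {2:.5f} T {3:.5f}\n\n".format(*background_freqs))
        for name, mat, nsites in items:
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(mat)} "
                     f"nsites= {nsites} E= 0\n")
            for row in mat:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme_motifs(path) -> list:
    """Read a minimal MEME file into Motif objects (renormalized rows).

    The probability matrices are read directly rather than via integer
    count reconstruction, so low-nsites diffuse matrices round-trip
    losslessly.
    """
    out = []
    name = None
    rows: list[list[float]] = []

    def flush():
        if name is not None and rows:
            mat = np.asarray(rows, dtype=float)
            out.append(Motif(mat / mat.sum(axis=1, keepdims=True), name=name))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                name = line.split()[1]
                rows = []
            elif name is not None and line and line[0] in "0123456789.":
                rows.append([float(x) for x in line.split()])
    flush()
    for m in out:
        if m.matrix.shape[1] != 4:
            raise ValueError(f"{path}: motif {m.name!r} is not a DNA PPM")
    return out


def read_meme_library(path, source: str = "") -> TFBSLibrary:
    """Read a minimal MEME file as a known-TFBS PWM library."""
    return TFBSLibrary({m.name: m.matrix for m in read_meme_motifs(path)},
                       source=source or str(path))
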