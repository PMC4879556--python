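import numpy as np
import pandas as pd
import pytest

from coexmotif import ExpressionMatrix, make_fixture, run_pipeline


@pytest.fixture
def small_matrix():
    """8 genes x 3 arrays; first array has values 1..8 in gene order."""
    genes = [f"g{i}" for i in range(1, 9)]
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        {"a1": np.arange(1.0, 9.0),
         "a2": rng.normal(size=8),
         "a3": rng.normal(size=8)},
        index=genes)
    return ExpressionMatrix(data, scale_tag="log2")


def consensus_distance(found: str, planted: str) -> int:
    """Distance between consensus strings of possibly different widths:
    minimum over ungapped alignments and both orientations of (mismatches
    in the overlap + planted positions left uncovered). Equal widths at
    offset 0 reduce to plain Hamming distance."""
    from coexmotif._util import revcomp

    best = len(planted)
    for cand in (found, revcomp(found)):
        for off in range(-len(cand) + 1, len(planted)):
            mism = 0
            covered = 0
            for i, c in enumerate(cand):
                j = i + off
                if 0 <= j < len(planted):
                    covered += 1
                    if c != planted[j]:
                        mism += 1
            best = min(best, mism + (len(planted) - covered))
    return best


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """The synthetic end-to-end fixture, run twice with the same
    configuration (shared across tests; the motif stage is the slow part).

    Returns (config, first report, byte snapshot of the first run's output
    tree, second report); the second run overwrote the same directory.
    """
    from pathlib import Path

    d = tmp_path_factory.mktemp("fixture")
    cfg = make_fixture(d, seed=1, n_motifs=2, promoter_length=300,
                       n_shuffles=200)
    report1 = run_pipeline(cfg)
    out = Path(cfg.out_dir)
    snapshot = {p.relative_to(out): p.read_bytes()
                for p in out.rglob("*") if p.is_file()}
    report2 = run_pipeline(cfg)
    return cfg, report1, snapshot, report2
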