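import numpy as np
import pytest

from coexmotif import (ConsensusPattern, Motif, TFBSLibrary,
                       compare_motif_to_library, count_gene_support,
                       filter_motifs_by_gene_support, pwm_to_consensus,
                       read_meme_library, read_meme_motifs, scan_consensus,
                       write_meme)
from coexmotif._util import IUPAC, revcomp
from coexmotif.discovery import MotifSite


def oracle_scan(seq, pattern, no_overlap):
    """Naive window-by-window scan on one strand; lowercase never matches."""
    w = len(pattern)
    hits, i = [], 0
    while i <= len(seq) - w:
        window = seq[i:i + w]
        ok = all(c in IUPAC[p] for c, p in zip(window, pattern))
        if ok:
            hits.append(i)
            i += w if no_overlap else 1
        else:
            i += 1
    return hits


class TestScanConsensus:
    def test_simple_two_hits(self):
        res = scan_consensus({"g1": "ACGTACGT"}, "ACGT", both_strands=False)
        assert [(o.start, o.strand) for o in res.occurrences] == [(0, "+"), (4, "+")]

    def test_degenerate_match(self):
        res = scan_consensus({"g1": "TTGCCGTAGG"}, "GCCGNM", both_strands=False)
        assert [(o.start, o.sequence) for o in res.occurrences] == [(2, "GCCGTA")]

    def test_no_overlap_greedy(self):
        with_noov = scan_consensus({"g1": "AAAAAA"}, "AAAA", both_strands=False,
                                   no_overlap=True)
        without = scan_consensus({"g1": "AAAAAA"}, "AAAA", both_strands=False,
                                 no_overlap=False)
        assert [o.start for o in with_noov.occurrences] == [0]
        assert [o.start for o in without.occurrences] == [0, 1, 2]

    def test_reverse_strand_reported_in_forward_coordinates(self):
        # revcomp(GCCGAA) = TTCGGC sits at offset 3 of the forward strand
        res = scan_consensus({"g1": "AAATTCGGCAA"}, "GCCGAA")
        assert [(o.start, o.strand, o.sequence) for o in res.occurrences] == \
            [(3, "-", "TTCGGC")]

    def test_masked_positions_never_match(self):
        res = scan_consensus({"g1": "acgtACGT"}, "ACGT", both_strands=False)
        assert [o.start for o in res.occurrences] == [4]

    def test_invalid_iupac_letter(self):
        with pytest.raises(ValueError, match="invalid IUPAC"):
            ConsensusPattern("ACGX")

    def test_strand_symmetry_without_noov(self):
        rng = np.random.default_rng(8)
        pat = "GCNRA"
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT"), size=60))
            fwd = scan_consensus({"g": s}, pat, no_overlap=False)
            rev = scan_consensus({"g": revcomp(s)}, revcomp(pat), no_overlap=False)
            plus = {o.start for o in fwd.occurrences if o.strand == "+"}
            # + matches of pat on s == + matches of rc(pat) on rc(s), mapped back
            mapped = {len(s) - o.start - len(pat)
                      for o in rev.occurrences if o.strand == "+"}
            assert plus == mapped

    @pytest.mark.parametrize("no_overlap", [True, False])
    def test_matches_window_oracle(self, no_overlap):
        rng = np.random.default_rng(5)
        for pat in ["ACGT", "GCCGNM", "AAAA", "RYSWKM"]:
            for _ in range(25):
                s = "".join(rng.choice(list("ACGTacgt"), size=80,
                                       p=[0.22] * 4 + [0.03] * 4))
                res = scan_consensus({"g": s}, pat, no_overlap=no_overlap)
                plus = [o.start for o in res.occurrences if o.strand == "+"]
                minus = [o.start for o in res.occurrences if o.strand == "-"]
                assert plus == oracle_scan(s, pat, no_overlap)
                assert minus == oracle_scan(s, revcomp(pat), no_overlap)


class TestGeneSupport:
    def _toy_promoters(self):
        return {"g1": "TTACGTTTACGT", "g2": "ACGTAAAA", "g3": "GGGGGGGG",
                "g4": "CCACGTCC", "g5": "TTTTTTTT"}

    def test_distinct_gene_counting(self):
        assert count_gene_support("ACGT", {"g1": "ACGTACGT"},
                                  both_strands=False) == 1
        assert count_gene_support("ACGT", self._toy_promoters(),
                                  both_strands=False) == 3
        assert count_gene_support("ACGT", {}) == 0

    def test_invariant_to_promoter_order(self):
        toy = self._toy_promoters()
        rev = dict(reversed(list(toy.items())))
        assert count_gene_support("ACGT", toy) == count_gene_support("ACGT", rev)

    def test_motif_support_uses_site_list(self):
        sites = [MotifSite(f"g{i}", 0, "+", "ACGTAC") for i in range(4)]
        m = Motif(np.full((6, 4), 0.25), sites=sites + [sites[0]])
        assert count_gene_support(m, None) == 4

    def test_filter_by_min_genes(self):
        def motif_with(n):
            return Motif(np.full((6, 4), 0.25),
                         sites=[MotifSite(f"g{i}", 0, "+", "A" * 6)
                                for i in range(n)])
        kept = filter_motifs_by_gene_support([motif_with(4), motif_with(3)],
                                             min_genes=4)
        assert len(kept) == 1 and kept[0].n_genes_with_site == 4
        assert filter_motifs_by_gene_support([], min_genes=4) == []


def _sharp(seq):
    m = np.full((len(seq), 4), 0.01)
    for i, c in enumerate(seq):
        m[i, "ACGT".index(c)] = 0.97
    return m / m.sum(axis=1, keepdims=True)


class TestLibraryComparison:
    @pytest.fixture(scope="class")
    def library(self):
        # distinct high-information columns: a column-shuffled copy cannot
        # tie the observed score the way a homopolymer-rich sharp motif can
        rng = np.random.default_rng(12)
        tgt = rng.dirichlet([0.3] * 4, size=8)
        return TFBSLibrary({"tgt": tgt, "other": _sharp("TTTTAAAA")}), tgt

    def test_self_match_ranks_first(self, library):
        lib, tgt = library
        q = Motif(tgt, name="q")
        res = compare_motif_to_library(q, lib, n_shuffles=200, seed=0)
        top = res[0]
        assert (top.target, top.offset, top.orientation) == ("tgt", 0, "+")
        assert top.score == pytest.approx(1.0)
        assert top.p_value < 0.05

    def test_trimmed_query_found_at_offset(self, library):
        lib, tgt = library
        q = Motif(tgt[2:], name="q")  # columns 2..7 of the target
        res = compare_motif_to_library(q, lib, n_shuffles=200, seed=0)
        assert res[0].target == "tgt"
        assert res[0].offset == -2 and res[0].orientation == "+"
        assert res[0].score == pytest.approx(1.0)

    def test_reverse_complement_orientation(self, library):
        lib, tgt = library
        q = Motif(tgt[::-1, ::-1], name="q")
        res = compare_motif_to_library(q, lib, n_shuffles=200, seed=0)
        assert res[0].target == "tgt" and res[0].orientation == "-"
        assert res[0].score == pytest.approx(1.0)

    def test_empty_library_errors(self):
        with pytest.raises(ValueError, match="empty"):
            compare_motif_to_library(Motif(_sharp("ACGTAC")),
                                     TFBSLibrary({}), n_shuffles=200)


class TestConsensusFromPWM:
    @pytest.mark.parametrize("column,expected", [
        ((1, 0, 0, 0), "A"),
        ((0.5, 0.5, 0, 0), "M"),
        ((0.25, 0.25, 0.25, 0.25), "N"),
    ])
    def test_iupac_column_codes(self, column, expected):
        rows = np.vstack([column, [0.25] * 4])
        pat = pwm_to_consensus(Motif(rows), inclusion_threshold=0.25)
        assert pat.pattern[0] == expected


class TestMemeIO:
    def test_round_trip_and_biopython_compatible(self, tmp_path):
        m1 = Motif(_sharp("GACGTG"), name="alpha",
                   sites=[MotifSite("g1", 0, "+", "GACGTG")])
        m2 = Motif(np.random.default_rng(0).dirichlet([2] * 4, size=9),
                   name="beta")
        p = tmp_path / "motifs.meme"
        write_meme([m1, m2], p)
        back = read_meme_motifs(p)
        assert [m.name for m in back] == ["alpha", "beta"]
        np.testing.assert_allclose(back[0].matrix, m1.matrix, atol=1e-5)
        np.testing.assert_allclose(back[1].matrix, m2.matrix, atol=1e-5)
        lib = read_meme_library(p)
        assert set(lib.motifs) == {"alpha", "beta"}
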