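# Methods

`coexmotif` implements a discriminative co-expression analysis for bulk
expression compendia: a positive gene list picks out the hybridizations in
which a biological process of interest is active, a Pearson-thresholded
network over a candidate gene set (computed on those arrays only) yields
co-expression clusters, and each cluster is characterised by *ab initio*
promoter motif discovery, known-TFBS comparison, IUPAC consensus scanning
and GO-term enrichment. This note records the models, the parameters that
matter, and the choices made where the procedure was genuinely open.

## Expression ingestion and normalization

The compendium is a genes × arrays matrix. Rows with missing or
non-numeric cells are dropped, never imputed: downstream steps are
rank-based (quantile membership) or correlation-based, and imputation
would bias both. Normalization is quantile normalization, optionally after
`log2(x + offset)`: every column is forced onto the across-column mean of
sorted columns, preserving within-column ranks. Ties receive the mean of
the reference values they span — deterministic and order-independent, but
note that a tied group collapses to a single value, so exact idempotence
and exactly-shared column distributions are tie-free properties (they hold
to 1e-9 for continuous data).

The `QuantileNormalizer` estimator learns the reference from `fit` data
and maps new columns onto it by rank, so it composes with sklearn
pipelines.

## Discriminative array selection

For each array, all genes are ranked; the extremes are the `k = floor(q·n)`
highest plus `k` lowest values (`q = 0.25`: the 25% highest or lowest
signals). The array's score is the fraction of positive-list genes (among
those present in the matrix) that fall in the extremes, and an array is
selected iff `score > f` with `f = 0.70` — a strict inequality, reading
"more than 70%" literally. Boundary ties are broken by ordering genes on
(value, gene id), so results are reproducible across platforms. Under the
null (no signal) the expected score is `2q`; with a list of `L` genes the
chance a null array exceeds `f` is a hypergeometric tail, which is *not*
negligible for small `L` — selection specificity is a function of list
size, and the synthetic benchmark measures exactly this.

## Co-expression network and clusters

Edges join candidate-gene pairs with sample Pearson correlation `r ≥ r0`
(`r0 = 0.90`, signed and inclusive: strong *positive* co-expression only),
computed across the selected arrays (at least 3 required; zero-variance
genes are excluded). Clusters are the connected components of the
thresholded graph with at least `min_cluster_size` members (default 5),
labelled C0, C1, … by decreasing size with ties broken by smallest member
id; smaller components form the reported remainder. Components are the
minimal clustering assumption for a thresholded graph; no soft
thresholding or seeded neighbourhood growth is attempted.

## Promoter extraction

The core promoter is the up-to-1000 bp immediately 5' of the gene model's
5' end, truncated at the nearest annotated gene body on either strand, and
discarded below 50 bp. Internally all coordinates are 0-based half-open;
GFF3's 1-based inclusive convention is converted at the boundary. The
transcription start is approximated by the gene-feature 5' end (no
UTR/transcript refinement). Lowercase (repeat-masked) bases are kept in
the sequence for coordinate bookkeeping but are unusable downstream: they
never host motif sites, seeds, or consensus matches, and they break Markov
background contexts.

## Markov background

An order-3 Markov chain (`P(base | preceding 3-mer)`) is estimated from
the promoter set, counting both strands, with pseudocount α added to every
transition. Positions whose context is interrupted (sequence start, masked
base) fall back to the longest clean lower-order context estimated from
the same counts. The published setting used genome-scale precomputed
backgrounds with zero pseudo-frequencies; for desk-scale training sets we
default to α = 0.5 so unseen contexts remain finite, and fall back to a
lower order (with a warning) when the usable training length is ≤ 4^k.

## ZOOPS EM motif discovery

Each promoter contains zero or one site of the motif being fit. For
sequence *s* with eligible offsets `j = 1..m_s`:

    P(s) = (1 − λ)·P(s | bg) + (λ / m_s) · Σ_j P(s with site at j | θ, bg)

where the site term replaces the background factors inside the window by
the position probability matrix θ (w × 4). Both strands contribute
offsets. EM alternates window responsibilities with θ/λ re-estimation; the
ascended objective is the mixture log-likelihood plus the Dirichlet
pseudocount prior on θ (0.01 per cell), which is non-decreasing by the
standard EM argument and is what the recorded trace shows. λ starts at
`1/√(#sequences)` and is re-estimated each M-step (clipped to (1e-6,
1−1e-6)); convergence is |Δobjective| < 1e-6 or 200 iterations.

Starting points are enumerated promoter substrings converted to θ by
giving probability 0.7 to the observed base; up to `max_seeds` (default
1000) seeds are subsampled with the run's RNG, scored by their initial
ZOOPS likelihood in one vectorized pass, and the top 3 are refined by full
EM — a tractable stand-in for MEME's starting-point search. For each motif
all widths 6–12 are tried and the width with the best likelihood-ratio
objective wins; after acceptance the motif's sites (posterior > 0.5, best
offset per sequence) are erased and the search repeats, up to 10 motifs.
Fixed seed ⇒ bit-identical matrices and site lists.

Two behaviours to know about. First, the raw likelihood-ratio objective
mildly favours wider widths (each extra column buys ~1.5 nats of
overfitting), so a planted core tends to be returned embedded in a wider
motif — recovery is therefore judged by consensus alignment, not width
equality. Second, on pure background the finder still converges on a fuzzy
apparent motif (~1 bit/column) because the best-matching window per
sequence aligns across sequences; this is the behaviour MEME's E-value
exists to flag, and the benchmark checks the contrast against a planted
run rather than an absolute information-content bound.

## Motif annotation

Gene support of a discovered motif is the number of distinct genes in its
ZOOPS site list (at most one per gene); motifs supported by fewer than 4
genes are dropped before library comparison. IUPAC consensus scanning
finds exact degenerate matches; minus-strand hits match the reverse
complement of the pattern against the forward sequence and are reported in
forward coordinates. The no-overlap rule is greedy left-to-right per
strand: after a match at `[i, i+w)` the next search starts at `i+w`.

Known-TFBS comparison is Tomtom-flavoured but self-contained: ungapped
sliding alignment in both orientations with ≥ 4 overlapping columns,
column similarity = Pearson correlation of the two probability 4-vectors
(zero-variance columns score 0), alignment score = mean column similarity,
and an empirical p-value against column-shuffled targets
(`p = (1 + #{shuffled ≥ observed}) / (1 + n_shuffles)`, seeded, default
1000 shuffles). Mean-over-overlap scoring means a short perfect overlap
can tie a long one; queries rich in repeated sharp columns therefore get
conservative (larger) empirical p-values.

## GO enrichment

For a cluster with `n` genes inside the annotation universe (all annotated
genes present in the expression matrix; size `N`), a term annotating `K`
universe genes and `k ≥ 1` cluster genes is tested with the right-sided
hypergeometric tail `P(X ≥ k)`. The Holm (Bonferroni step-down) procedure
corrects across the terms tested for that cluster. GO-graph propagation is
off by default; annotations are taken as given.

## Synthetic data: what it emulates, and what a green test establishes

`simulate_expression` draws background entries iid N(0, 1) on the
normalized scale; a module gene is `sqrt(ρ)·factor + sqrt(1−ρ)·ε`, so the
expected within-module correlation is exactly ρ (defaults: modules of
20/15/10 genes at ρ = 0.95 among 200 genes × 100 arrays). In the 10
discriminative arrays, each of the 20 positive-list genes is shifted by
±4 sd (sign fixed per gene). `simulate_promoters` samples 30 × 500 bp
from a random order-3 chain (Dirichlet(20) conditionals) and plants one
exact instance of an 8-bp consensus in each of 20 carriers, degenerate
positions resolved uniformly. `simulate_go_annotation` adds uniform decoy
terms plus planted terms covering a stated fraction of a module.

These generators reproduce the *statistical shape* the method assumes —
not probe-level artifacts, batch effects, correlated positive lists, or
real GO DAG topology. A green recovery test therefore establishes that the
implementation detects the structure it claims to detect at the stated
signal strengths; it does not certify performance on real compendia, where
the published analysis depended on a 3,800-array database and curated
inputs. One measured property worth stating: with a 20-gene positive list
among 200 genes, null arrays exceed the 0.70 score threshold with
probability ≈ 0.016–0.03 (hypergeometric tail, inflated slightly by module
clumping), so perfect selection specificity is not achievable in this
stated world — the benchmark reports it honestly rather than enlarging the
list.

## Numerical and reproducibility choices

- All randomness flows from one master seed through derived per-stage
  seeds (< 2^31); pipeline reruns are byte-identical, and report JSON/TSV
  writers sort keys and use shortest round-trip float formatting (the
  matrix reader parses through Python's exact float path for bit-exact
  round trips).
- Extreme-quantile boundary ties: lexicographic gene id. Cluster-size
  ties: smallest member id. Motif width ties: higher objective, then
  narrower width.
- Degenerate inputs: single-column matrices pass through normalization
  with a warning; fewer than 3 selected arrays yields an empty network
  (warning) rather than an error; empty motif search stops early with a
  log entry.
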