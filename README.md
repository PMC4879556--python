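# coexmotif

Discriminative gene co-expression network analysis with promoter motif
discovery and GO enrichment.

Large public expression compendia mix thousands of unrelated experiments.
When you care about one process — say, a developmental response driven by a
nutrient stress — most of those arrays are noise for your question.
`coexmotif` implements the discriminative strategy: use a **positive gene
list** (genes with validated roles in the process) to select only the
hybridizations in which that list sits in the extreme expression quantiles,
build a Pearson co-expression network of candidate genes over those arrays
alone, and then characterise the resulting clusters by promoter
cis-regulatory elements and GO enrichment. It is aimed at systems biologists
who have a numeric expression matrix, a couple of gene lists, and promoter
sequences, and want the whole chain reproducibly scripted instead of spread
across web tools.

## The method

1. **Array selection.** For each array, rank all genes; an array is kept
   when more than a fraction *f* of the positive-list genes fall in the
   top-*q* or bottom-*q* of all signals (defaults *q* = 0.25, *f* = 0.70,
   strict inequality).
2. **Network.** Over the selected arrays, connect candidate genes *a, b*
   when the sample Pearson correlation r(a,b) ≥ r₀ (default 0.90, signed).
   Clusters C0, C1, … are the connected components with ≥ 5 members, by
   decreasing size.
3. **Motifs.** Per cluster, extract core promoters (≤ 1000 bp, truncated at
   neighbouring genes, ≥ 50 bp, repeat-mask aware) and run ZOOPS
   (zero-or-one-occurrence-per-sequence) EM with an order-3 Markov
   background, widths 6–12, up to 10 motifs with site erasure between
   rounds. Motifs supported by ≥ 4 genes are compared to a known-TFBS PWM
   library (Tomtom-style column correlation with an empirical shuffle
   p-value), and promoters are scanned for IUPAC consensus elements on both
   strands with greedy non-overlap ("noov") counting.
4. **Enrichment.** Per cluster, a right-sided hypergeometric test per GO
   term with Holm (Bonferroni step-down) correction.

A synthetic-data module generates compendia with planted discriminative
arrays and co-expression modules, promoters with planted motif instances,
and annotations with planted enriched terms — plus the ground truth — so
every stage is testable without external downloads. See `docs/methods.md`
for models, parameters and caveats.

## Worked example

```python
import coexmotif as cm

m, positive, candidates, truth = cm.simulate_expression(seed=1)
sel = cm.select_discriminative_arrays(m, positive)
print(f"{sel.n_selected} arrays selected; "
      f"planted recovered: {set(truth.discriminative_arrays) <= set(sel.selected_arrays)}")

net = cm.build_network(m, candidates, sel.selected_arrays)
clusters = cm.extract_clusters(net)
print([(c.cluster_id, len(c)) for c in clusters], "| remainder:", len(clusters.remainder))

pset, ptruth = cm.simulate_promoters(seed=11)
motifs = cm.discover_motifs_zoops(pset, cm.MotifParams(n_motifs=1, seed=11))
top = motifs[0]
print(f"top motif: {top.consensus} (planted {ptruth.planted_consensus}), "
      f"sites in {top.n_genes_with_site} genes, LLR {top.log_likelihood_ratio:.1f}")

res = cm.scan_consensus(pset, "GACGTGGC")
print(f"consensus scan: {len(res.occurrences)} occurrences in "
      f"{res.n_genes_with_hit()} genes")
```

prints

```
15 arrays selected; planted recovered: True
[('C0', 20), ('C1', 14), ('C2', 10)] | remainder: 136
top motif: CGACGTGGCAAG (planted GACGTGGC), sites in 21 genes, LLR 75.3
consensus scan: 20 occurrences in 20 genes
```

All 10 planted discriminative arrays are recovered (plus 5 null arrays that
pass the 0.70 threshold by chance — with a 20-gene list the null score
hugs 0.5 with a fat hypergeometric tail). The three planted co-expression
modules come back as C0–C2 (one gene of the 15-member module missed its
correlation threshold on the 15 selected arrays). The ZOOPS finder returns
the planted 8-mer embedded in a wider motif, with a site in every carrier,
and the degenerate scan finds the planted element in all 20 carrier
promoters.

Estimator-style classes (`QuantileNormalizer`, `DiscriminativeArraySelector`,
`CoexpressionClusterer`, `ZoopsMotifFinder`) wrap the same stages with
sklearn `fit`/`transform` semantics, and a `coexmotif` CLI exposes
`simulate`, `normalize`, `select-arrays`, `network`, `motifs`, `scan`,
`enrich` and `run-all` (YAML config; every published parameter is a named,
defaulted field).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic fixture from the given seed and runs the complete
pipeline end to end (normalization → array selection → network → clusters →
motif discovery, TFBS comparison, consensus scanning → enrichment), then
writes the acceptance JSON to `--out`.
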