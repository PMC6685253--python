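# gomine

Offline functional mining of gene lists with the Gene Ontology: multi-list,
topology-aware GO enrichment followed by semantic-similarity clustering of
the enriched terms, with exportable dendrogram / heatmap / MDS / upset data
products. Everything runs from local files (OBO ontology, GAF or TSV
annotations, plain-text gene lists) — no live database access is needed, so
analyses are reproducible against a pinned ontology and annotation release.

It is aimed at transcriptomics studies (bulk or single-cell) with several
differential-expression contrasts: instead of reading three flat tables of
hundreds of enriched GO terms, the terms are organised by their semantic
similarity into functional clusters that can be compared across contrasts.

## Methods

**Enrichment.** Each interest list is tested per GO term with a one-sided
Fisher exact test. With `x` significant genes on a term, `n` annotated
interest genes, `K` annotated universe genes on the term and `N` annotated
universe genes,

```
p = Σ_{k=x}^{min(n,K)} C(K,k) · C(N−K, n−k) / C(N,n)
```

computed in log space. Besides the *classic* independent test, the *elim*
algorithm walks the DAG bottom-up and removes the genes of children already
significant at a cutoff α before testing their ancestors, so parents are not
flagged merely because one specific child drives the signal. Per-list
results are merged into one table keeping every term below the significance
threshold in at least one list (p-values are reported unadjusted; the merge
is exploratory).

**Semantic similarity.** Five pairwise measures over terms: four
information-content measures (Resnik, Lin, Schlicker's Rel, Jiang-Conrath)
built on IC(t) = −ln p(t) with p(t) the propagated annotation frequency, and
Wang's graph-based measure, which propagates semantic contributions
(S-values, weight 0.8 per `is_a` and 0.6 per `part_of` edge) through each
term's ancestor sub-DAG. Term *sets* are compared with max, avg, rcmax or
the best-match average (BMA), the symmetrised mean of each term's best match
in the other set.

**Clustering and visualisation.** Enriched terms are clustered on d = 1 − s
with Ward's criterion in its ward.D2 form (Lance–Williams on squared
dissimilarities, heights reported on the original scale). The dendrogram is
cut statically (fixed k or height) or dynamically (adaptive branch
detection with a minimum cluster size; unassignable leaves get label 0).
Clusters are named by the deepest common ancestor of their members, compared
as sets via BMA, and rendered as a clustered −log10(p) heatmap with an IC
sidebar, an MDS scatter (classical Torgerson scaling), a per-list term-count
barchart and an upset overlap plot. Every image has a TSV/JSON twin so
results are testable without image diffing.

## Worked example

Generate a synthetic study (a 300-term ontology over 2000 genes, three
interest lists, each with one planted over-represented term at 10× odds) and
run the whole workflow:

```
gomine fixtures --out study --seed 1
gomine all --config config.yaml --out out
```

with `config.yaml`:

```yaml
obo: study/ontology.obo
annotations: study/annotations.gaf
annotation_format: gaf
namespace: biological_process
background: study/background.txt
lists:
  list1: study/list1.txt
  list2: study/list2.txt
  list3: study/list3.txt
algorithm: elim
alpha: 0.01
threshold: 0.01
measure: wang
combine: BMA
cut: {mode: dynamic, min_size: 2, deep_split: 2}
```

The run retains 9 enriched terms (p < 0.01 in at least one list) and groups
them into 3 functional clusters. The planted terms dominate their lists, as
they should:

```
list1 GO:0000098 p=4.59e-10 gene frequency 21/55
list2 GO:0000187 p=4.25e-11 gene frequency 21/46
list3 GO:0000225 p=1.11e-18 gene frequency 29/44
```

Gene frequency is the "significant/annotated" count for the term, e.g.
21 of the 55 genes annotated to GO:0000098 are in list1. `out/` then holds
`enrichment.tsv` (the merged table), `simmatrix.tsv`, the dendrogram as
Newick and merge table, `clusters.tsv` (with each cluster's common-ancestor
name), the heatmap/barchart/upset/MDS twins and images, a self-contained
`report.html`, and `run.json` recording every parameter, input digest and
stage count for traceability.

The same stages are available individually (`gomine enrich`,
`gomine semsim`, `gomine cluster`), chained through the files above, and as
a library API (`gomine.elim_enrichment`, `gomine.sim_wang`,
`gomine.hclust_ward2`, ...).

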