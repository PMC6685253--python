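# Methods

This note records the models and procedures gomine implements, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions a maintainer should know.

## Ontology model

The ontology is a directed acyclic graph of GO terms with typed child→parent
edges. Only `is_a` and `part_of` are interpreted — these are the relations
along which the true-path rule propagates annotations and along which Wang's
S-values flow; other relations (`regulates`, `has_part`, ...) are dropped at
parse time with a warning. The relation set is configurable on every graph
operation. All analyses are single-namespace (BP, MF or CC), each namespace
must have exactly one root, and cross-namespace edges (rare in real OBO
releases) are dropped with a warning.

Term *level* is the longest-path distance from the root, not the shortest.
This guarantees that every child sits strictly deeper than each of its
parents, so processing terms by decreasing level visits all children before
any parent — exactly the order the elim sweep requires. Ties within a level
are broken by ascending accession so runs are bit-reproducible.

Obsolete terms are retained in the term map (so lookups resolve and produce
a clear error) but carry no edges and cannot be used in graph operations.
Alternative accessions resolve transparently to their primary id at lookup
time.

## Annotation model

A gene annotated to a term is implicitly annotated to every ancestor
(true-path rule); enrichment counts and information content both use this
propagated closure. Gene identity is the annotation file's object id (GAF
column 2) verbatim — identifier mapping across databases is out of scope and
should happen upstream. GAF rows with a `NOT` qualifier are discarded; the
evidence-code filter defaults to "keep everything" (computational and
experimental codes alike), restrictable by the user.

The enrichment universe counts only annotated background genes: a background
gene with no GO annotation can never appear in a term's 2×2 table, so
including it in N would deflate every p-value by a constant that carries no
information about term membership. The run log reports how many background
genes were annotated so the effective universe is always visible.

## Enrichment

`fisher_upper_tail` sums the hypergeometric upper tail in log space
(log-binomials + logsumexp), so p-values of 1e-300 keep full relative
precision. The elim variant follows the standard bookkeeping: elimination is
*per ancestor* — a significant term (p < α, default α = 0.01) marks its
annotated genes as eliminated at each of its ancestors, and an ancestor's
own test drops exactly the genes eliminated at it, while n and N stay
global. α is deliberately independent from the merge threshold (also 0.01
by default); both are exposed as flags.

Merged tables keep the union of sub-threshold terms across lists and report
every list's p-value for each retained term, significant or not. A term
never tested in a list (no annotated gene there) is NA — distinct from
p = 1, which means "tested, not enriched". No multiple-testing correction is
applied; the table is an exploratory ranking, and the heatmap's −log10(p)
scale makes relative strength visible.

## Semantic similarity

IC(t) = −ln(|genes on t| / |genes on root|) over the propagated annotation
of the analysis universe by default (configurable to the full annotation
corpus); natural log, so IC is in nats. Terms with zero annotation have no
IC and raise a clear error when used in an IC-based measure.

- Resnik is normalised by the corpus' maximum finite IC so every measure
  lives on [0, 1] and d = 1 − s is a valid clustering distance.
- Jiang-Conrath uses the bounded form 1 − min(1, IC(a)+IC(b)−2·IC(MICA)).
- Lin and Rel are defined as 0 when both terms carry root IC (the 0/0
  case); this is logged.
- MICA ties are broken lexicographically by accession.
- Wang uses the canonical contribution weights 0.8 (`is_a`) / 0.6
  (`part_of`), configurable. S-values are computed over the induced
  ancestor sub-DAG in decreasing-level order; the measure is purely
  topological and never consults annotations.

Set combinations (max, avg, rcmax, BMA) operate on the full pairwise matrix
between two term sets. Similarity matrices are symmetrised and clamped to
[0, 1] after floating-point rounding, and the diagonal is fixed at 1.

## Clustering

ward.D2 is the Lance–Williams recurrence on squared dissimilarities with
heights square-rooted back to the original scale; the implementation is
scipy's `linkage(..., method="ward")` on the condensed distance matrix,
which computes exactly this. Merge ties (zero-measure on real-valued
similarity data) follow scipy's deterministic nearest-neighbor-chain order.

The dynamic cut is an adaptive branch detector: a merge is a *separator*
when (a) its height is at least a fraction of the maximum merge height —
the fraction set by `deep_split` 0–4 (0.95, 0.88, 0.81, 0.74, 0.67); (b) it
stands clear of its branches' internal merge profile by a relative height
gap of at least 0.15; and (c) at least one branch has internal structure
(two bare leaves have nothing to stand clear of). Clusters are the maximal
separator-free subtrees; clusters smaller than `min_cluster_size` (default
2) are left unassigned with label 0. Consequences worth knowing: a
structureless height continuum (e.g. mutually equidistant leaves) never
splits and returns one cluster, and an outlier leaf attached high in the
tree is labelled 0 rather than forced into a cluster. Defaults
`min_cluster_size = 2, deep_split = 2` keep small GO clusters representable;
all parameters are echoed into the run log.

"First common ancestor" naming is interpreted as the *deepest* (most
specific) common ancestor of the cluster's members, with ties broken by
higher IC, then lexicographic accession; the interpretation is recorded in
the run log.

MDS is classical Torgerson scaling: double-centre −½·J·D²·J, eigendecompose,
scale the top eigenvectors by √eigenvalue. Negative eigenvalues (the
distance being non-Euclidean) are truncated to zero and the discarded
fraction of absolute eigenvalue mass is logged as a distortion diagnostic.

## Synthetic-data generator

The generator emulates the structural features the pipeline depends on: a
rooted single-namespace DAG with controlled depth (default 8) and a part_of
edge fraction (0.2); direct annotations whose density decays with term depth
(weight ∝ 0.8^level, ~4 direct terms per annotated gene, 15% of genes
unannotated); and interest lists (~8% of a 2000-gene background) in which
one planted term per list is over-represented at 10× odds. Planted terms
are chosen among well-annotated *leaf* terms (level ≥ 2, 20–100 genes):
planting at an internal term would make "the most enriched term"
ill-defined, since its signal is inherited by descendants. One RNG stream
per component (DAG, annotations, study) derives from the master seed, so
regenerating one component never perturbs another, and a fixed seed
determines every output byte.

What the generator does **not** emulate: the real GO's scale (tens of
thousands of terms) and its heavy-tailed branching; correlated annotations
between related genes; evidence-code structure; gene identifier synonymy;
and contrast-to-contrast correlation between interest lists. Passing tests
therefore demonstrate algorithmic correctness and end-to-end reproducibility
on realistic topology, not biological validity on any particular organism's
annotation.

## Problem sizes and numerical tolerances

The standard synthetic study is 300 terms / 2000 genes / 3 lists — large
enough that levels reach depth 8, elim has real work and the dendrogram has
visible structure, while a complete pipeline run takes about a second.
Exhaustive hypergeometric verification covers every valid table with
N ≤ 30 (46k tables) and agrees with exact integer enumeration to 1e-12 in
log space; set-combination and ward.D2 checks agree with their brute-force
oracles to 1e-12 and 1e-9; MDS reproduces planar configurations to a
Procrustes residual below 1e-6. Planted-signal recovery is measured over
20 independent seeds.

## Known limitations

- Only the classic and elim algorithms are implemented; score-based (KS)
  tests and the weight/parent-child algorithms are not.
- The dynamic cut is a deliberately simple branch detector; it does not
  implement the hybrid variant with its PAM-like reassignment stage, and
  its gap threshold (0.15) is a fixed design constant.
- No multiple-testing correction is offered, by design.
- OBO parsing interprets only the tags the pipeline needs (id, name,
  namespace, is_a, relationship, is_obsolete, alt_id); OWL is out of scope.
- Cluster-level similarity excludes unassigned (label 0) terms entirely.
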