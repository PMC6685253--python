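"""Over-representation tests per GO term: classic and elim Fisher variants.

Each interest list is tested against an annotated background universe with a
one-sided (upper-tail) Fisher exact test per term.  The ``elim`` variant walks
the DAG bottom-up and removes the genes of significantly enriched children
before testing their ancestors, so parents are not flagged merely because a
specific child drives the signal.  P-values are reported unadjusted: the merge
step is an exploratory union across lists, not a decision procedure.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.special import gammaln, logsumexp

from .annotation import AnnotationSet, term_gene_index
from .ontology import OntologyDag

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyInput:
    """Counts for one term's 2x2 table.

    x: interest genes annotated to the term; n: annotated interest-list size;
    K: annotated universe genes on the term; N: annotated universe size.
    """

    x: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        ok = 0 <= self.x <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N
        if not ok or self.x < self.n + self.K - self.N:
            raise ValueError(f"invalid contingency counts {self}")


def _log_comb(n: int, k) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_upper_tail(c: ContingencyInput) -> float:
    """P(X >= x) for X hypergeometric(N, K, n), summed in log space.

    Exact and deterministic: the tail is accumulated with log-binomials and
    ``logsumexp`` so tiny p-values keep full relative precision.
    """
    hi = min(c.n, c.K)
    if c.x == 0:
        return 1.0
    ks = range(c.x, hi + 1)
    log_terms = [
        _log_comb(c.K, k) + _log_comb(c.N - c.K, c.n - k) - _log_comb(c.N, c.n) for k in ks
    ]
    return min(1.0, math.exp(logsumexp(log_terms)))


@dataclass(frozen=True)
class TermResult:
    p_value: float
    x: int  # significant (interest) genes on the term, as tested
    K: int  # annotated universe genes on the term, as tested
    significant_genes: frozenset[str]

    @property
    def gene_frequency(self) -> str:
        return f"{self.x}/{self.K}"


@dataclass
class EnrichmentRun:
    """Per-term results of one algorithm run on one interest list."""

    list_id: str
    algorithm: str
    results: dict[str, TermResult]
    n: int  # annotated interest-list size
    N: int  # annotated universe size
    alpha: float | None = None  # elim cutoff, None for classic

    def p_values(self) -> dict[str, float]:
        return {t: r.p_value for t, r in self.results.items()}


def _prepare(interest, universe, annot: AnnotationSet, dag: OntologyDag):
    """Restrict to annotated genes; N counts only annotated background genes."""
    universe = frozenset(universe)
    interest = frozenset(interest) & universe
    if not frozenset(interest):
        raise ValueError("empty interest list (after intersecting with the universe)")
    prop = annot.propagated(dag)
    annotated_universe = frozenset(g for g in universe if prop.get(g))
    annotated_interest = interest & annotated_universe
    if not annotated_universe:
        raise ValueError("no annotated genes in the universe")
    index = term_gene_index(annot, dag, annotated_universe)
    return annotated_interest, annotated_universe, index


def classic_enrichment(
    interest,
    universe,
    annot: AnnotationSet,
    dag: OntologyDag,
    list_id: str = "interest",
) -> EnrichmentRun:
    """Independent Fisher upper-tail test for every term with >=1 annotated gene."""
    interest, annotated_universe, index = _prepare(interest, universe, annot, dag)
    n, N = len(interest), len(annotated_universe)
    results: dict[str, TermResult] = {}
    for term in sorted(index):
        genes = index[term]
        sig = genes & interest
        p = fisher_upper_tail(ContingencyInput(x=len(sig), n=n, K=len(genes), N=N))
        results[term] = TermResult(p, len(sig), len(genes), frozenset(sig))
    return EnrichmentRun(list_id, "classic", results, n=n, N=N)


def elim_enrichment(
    interest,
    universe,
    annot: AnnotationSet,
    dag: OntologyDag,
    alpha: float = 0.01,
    list_id: str = "interest",
) -> EnrichmentRun:
    """Bottom-up Fisher tests with elimination of significant children's genes.

    Terms are processed by decreasing longest-path level (children strictly
    before parents, ties by ascending accession).  A term significant at
    ``alpha`` marks all its annotated genes as eliminated at every ancestor;
    each ancestor's test then drops exactly the genes eliminated at it.  n and
    N stay global: elimination shrinks the term's annotation, not the universe.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    interest, annotated_universe, index = _prepare(interest, universe, annot, dag)
    n, N = len(interest), len(annotated_universe)
    eliminated: dict[str, set[str]] = {}
    results: dict[str, TermResult] = {}
    for term in dag.processing_order(annot.namespace):
        genes = index.get(term)
        if not genes:
            continue
        kept = genes - eliminated.get(term, set())
        sig = kept & interest
        p = fisher_upper_tail(ContingencyInput(x=len(sig), n=n, K=len(kept), N=N))
        results[term] = TermResult(p, len(sig), len(kept), frozenset(sig))
        if p < alpha:
            for anc in dag.ancestors(term, annot.relations):
                eliminated.setdefault(anc, set()).update(genes)
    return EnrichmentRun(list_id, "elim", results, n=n, N=N, alpha=alpha)


ALGORITHMS = {"classic": classic_enrichment, "elim": elim_enrichment}


@dataclass
class EnrichmentTable:
    """Merged multi-list table of enriched terms.

    ``data`` has one row per retained term (union of sub-threshold terms over
    lists) and, per list, columns ``<list>.pvalue``, ``<list>.gene_frequency``
    and ``<list>.significant_genes``.  A term absent from a list's tested set
    carries NaN/empty markers, distinct from p = 1.
    """

    data: pd.DataFrame
    list_ids: list[str]
    threshold: float
    algorithm: str

    def __len__(self) -> int:
        return len(self.data)

    @property
    def term_ids(self) -> list[str]:
        return list(self.data.index)

    def p_matrix(self) -> pd.DataFrame:
        """term x list matrix of p-values (NaN where the term was not tested)."""
        cols = {lid: self.data[f"{lid}.pvalue"] for lid in self.list_ids}
        return pd.DataFrame(cols, index=self.data.index)

    def significant_genes(self, term: str, list_id: str) -> frozenset[str]:
        cell = self.data.at[term, f"{list_id}.significant_genes"]
        return frozenset(cell.split(";")) if cell else frozenset()

    def to_tsv(self, path) -> None:
        out = self.data.reset_index().rename(columns={"index": "term_id"})
        header = f"# merged enrichment table; algorithm={self.algorithm}; threshold={self.threshold}\n"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            out.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "EnrichmentTable":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            df = pd.read_csv(fh, sep="\t", index_col="term_id", keep_default_na=False)
        meta = dict(
            item.strip().split("=") for item in header.split(";")[1:] if "=" in item
        )
        list_ids = [c[: -len(".pvalue")] for c in df.columns if c.endswith(".pvalue")]
        for lid in list_ids:
            df[f"{lid}.pvalue"] = pd.to_numeric(df[f"{lid}.pvalue"], errors="coerce")
        return cls(
            data=df,
            list_ids=list_ids,
            threshold=float(meta.get("threshold", 0.01)),
            algorithm=meta.get("algorithm", "unknown").strip(),
        )


def merge_enrich_terms(
    runs: list[EnrichmentRun], dag: OntologyDag, threshold: float = 0.01
) -> EnrichmentTable:
    """Union the sub-threshold terms of all runs into one table.

    Retained terms are those with p < ``threshold`` in at least one list; the
    table then reports every list's p (significant or not) for each retained
    term.  No multiple-testing correction is applied.
    """
    if not runs:
        raise ValueError("no enrichment runs to merge")
    algorithms = {r.algorithm for r in runs}
    retained = sorted(
        {t for run in runs for t, r in run.results.items() if r.p_value < threshold}
    )
    rows = {}
    for term in retained:
        meta = dag.terms[term]
        row: dict[str, object] = {"name": meta.name, "namespace": meta.namespace}
        for run in runs:
            res = run.results.get(term)
            row[f"{run.list_id}.pvalue"] = res.p_value if res else float("nan")
            row[f"{run.list_id}.gene_frequency"] = res.gene_frequency if res else ""
            row[f"{run.list_id}.significant_genes"] = (
                ";".join(sorted(res.significant_genes)) if res else ""
            )
        rows[term] = row
    columns = ["name", "namespace"] + [
        f"{run.list_id}.{col}"
        for run in runs
        for col in ("pvalue", "gene_frequency", "significant_genes")
    ]
    data = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    data.index.name = "term_id"
    for run in runs:
        n_sig = sum(r.p_value < threshold for r in run.results.values())
        logger.info("list %s: %d enriched terms (p < %g)", run.list_id, n_sig, threshold)
    return EnrichmentTable(
        data=data,
        list_ids=[run.list_id for run in runs],
        threshold=threshold,
        algorithm="+".join(sorted(algorithms)),
    )


def go_count(table: EnrichmentTable) -> dict[str, int]:
    """Enriched-term count per list (p < threshold), for the barchart."""
    p = table.p_matrix()
    return {lid: int((p[lid] < table.threshold).sum()) for lid in table.list_ids}


@dataclass
class UpsetMemberships:
    """Binary term x list significance matrix plus exclusive-intersection counts."""

    matrix: pd.DataFrame  # bool, index=term_id, columns=list_ids
    counts: dict[tuple[str, ...], int]  # exclusive pattern -> n terms

    def to_json(self, path) -> None:
        payload = {
            "lists": list(self.matrix.columns),
            "intersections": [
                {"lists": list(k), "count": v} for k, v in sorted(self.counts.items())
            ],
            "union_size": int(len(self.matrix)),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def upset_memberships(table: EnrichmentTable) -> UpsetMemberships:
    """Exclusive intersection pattern counts of sub-threshold significance."""
    p = table.p_matrix()
    matrix = p.lt(table.threshold).fillna(False)
    counts: dict[tuple[str, ...], int] = {}
    for _term, row in matrix.iterrows():
        pattern = tuple(lid for lid in table.list_ids if row[lid])
        if pattern:
            counts[pattern] = counts.get(pattern, 0) + 1
    return UpsetMemberships(matrix=matrix.astype(bool), counts=counts)
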