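"""Semantic similarity between GO terms and between sets of GO terms.

Two families of pairwise measures are provided.  The information-content (IC)
family (Resnik, Lin, Schlicker's Rel, Jiang-Conrath) scores a pair by how
informative their most informative common ancestor (MICA) is, where
IC(t) = -ln p(t) and p(t) is the term's propagated annotation frequency
relative to the namespace root.  Wang's graph-based measure instead propagates
semantic-contribution values (S-values) through each term's ancestor sub-DAG
with relation-specific weights and compares the overlap; it depends only on
topology, never on annotation.

Set-level similarity combines the pairwise matrix M over two term sets with
one of max, avg, rcmax or BMA (best-match average).  All similarities live in
[0, 1]; the matching distance is d = 1 - s.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, term_gene_index
from .ontology import DEFAULT_RELATIONS, OntologyDag

logger = logging.getLogger(__name__)

#: canonical Wang semantic-contribution weights per relation
WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}

PAIRWISE_MEASURES = ("resnik", "lin", "rel", "jiang", "wang")
COMBINE_METHODS = ("max", "avg", "rcmax", "BMA")


@dataclass
class ICTable:
    """Information content per term over an annotation corpus.

    Only terms with at least one propagated annotation have an entry;
    IC(root) = 0 and IC never decreases from parent to child.
    """

    ic: dict[str, float]
    prob: dict[str, float]
    corpus_size: int
    max_ic: float
    namespace: str

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise KeyError(f"term {term} has no annotation in the IC corpus") from None

    def p(self, term: str) -> float:
        return self.prob[term]


def compute_ic(annot: AnnotationSet, dag: OntologyDag, universe=None) -> ICTable:
    """IC(t) = -ln( |genes on t| / |genes on the namespace root| ).

    The corpus defaults to every annotated gene in the annotation set; pass
    ``universe`` to restrict it (e.g. to the analysis background).
    """
    universe = frozenset(universe) if universe is not None else annot.genes
    index = term_gene_index(annot, dag, universe)
    root = dag.roots[annot.namespace]
    corpus = len(index.get(root, frozenset()))
    if corpus == 0:
        raise ValueError("empty IC corpus: no annotated genes reach the namespace root")
    prob = {t: len(genes) / corpus for t, genes in index.items()}
    ic = {t: -math.log(p) for t, p in prob.items()}
    finite = [v for v in ic.values() if math.isfinite(v)]
    return ICTable(
        ic=ic, prob=prob, corpus_size=corpus, max_ic=max(finite), namespace=annot.namespace
    )


def mica(dag: OntologyDag, ic: ICTable, a: str, b: str) -> str:
    """Most informative common ancestor (reflexive); ties go to the smallest id."""
    a, b = dag.resolve(a), dag.resolve(b)
    for t in (a, b):
        if t not in ic:
            raise KeyError(f"term {t} has no annotation in the IC corpus")
    common = dag.common_ancestors([a]) & dag.common_ancestors([b])
    scored = [t for t in common if t in ic]
    if not scored:
        raise ValueError(f"{a} and {b} share no annotated common ancestor")
    return min(scored, key=lambda t: (-ic[t], t))


def sim_resnik(dag: OntologyDag, ic: ICTable, a: str, b: str) -> float:
    """IC(MICA) normalised by the corpus' maximum finite IC, so s in [0, 1]."""
    m = ic[mica(dag, ic, a, b)]
    return m / ic.max_ic if ic.max_ic > 0 else 0.0


def sim_lin(dag: OntologyDag, ic: ICTable, a: str, b: str) -> float:
    denom = ic[dag.resolve(a)] + ic[dag.resolve(b)]
    if denom == 0.0:
        logger.info("Lin(%s, %s): both terms at root IC, similarity defined as 0", a, b)
        return 0.0
    return 2.0 * ic[mica(dag, ic, a, b)] / denom


def sim_rel(dag: OntologyDag, ic: ICTable, a: str, b: str) -> float:
    """Schlicker's relevance measure: Lin weighted by 1 - p(MICA)."""
    denom = ic[dag.resolve(a)] + ic[dag.resolve(b)]
    if denom == 0.0:
        return 0.0
    m = mica(dag, ic, a, b)
    return 2.0 * ic[m] / denom * (1.0 - ic.p(m))


def sim_jiang(dag: OntologyDag, ic: ICTable, a: str, b: str) -> float:
    """Bounded Jiang-Conrath: 1 - min(1, IC(a) + IC(b) - 2 IC(MICA))."""
    d = ic[dag.resolve(a)] + ic[dag.resolve(b)] - 2.0 * ic[mica(dag, ic, a, b)]
    return 1.0 - min(1.0, max(0.0, d))


def wang_svalues(
    dag: OntologyDag, term: str, weights: dict[str, float] | None = None
) -> dict[str, float]:
    """S-values of Wang's method over the term's ancestor sub-DAG.

    S_t(term) = 1; for an ancestor u, S_t(u) is the best weighted contribution
    through any child of u inside the sub-DAG.
    """
    weights = WANG_WEIGHTS if weights is None else weights
    sub = dag.induced_ancestor_graph(term, frozenset(weights))
    levels = dag.term_levels(dag.terms[sub.target].namespace)
    s: dict[str, float] = {sub.target: 1.0}
    for node in sorted(sub.nodes, key=lambda t: (-levels[t], t)):
        if node == sub.target:
            continue
        s[node] = max(weights[rel] * s[child] for child, rel in sub.children_in(node))
    return s


def sim_wang(
    dag: OntologyDag, a: str, b: str, weights: dict[str, float] | None = None
) -> float:
    """Wang's graph-based similarity: shared S-value mass over total S-value mass."""
    a, b = dag.resolve(a), dag.resolve(b)
    sa, sb = wang_svalues(dag, a, weights), wang_svalues(dag, b, weights)
    shared = set(sa) & set(sb)
    num = sum(sa[t] + sb[t] for t in shared)
    return num / (sum(sa.values()) + sum(sb.values()))


def _combine(m: np.ndarray, method: str) -> float:
    if method == "max":
        return float(m.max())
    if method == "avg":
        return float(m.mean())
    row_best, col_best = m.max(axis=1), m.max(axis=0)
    if method == "rcmax":
        return float(max(row_best.mean(), col_best.mean()))
    if method == "BMA":
        return float((row_best.sum() + col_best.sum()) / (m.shape[0] + m.shape[1]))
    raise ValueError(f"unknown combine method {method!r}; pick from {COMBINE_METHODS}")


def termset_sim(
    set1: Sequence[str],
    set2: Sequence[str],
    pairwise: Callable[[str, str], float],
    combine: str = "BMA",
) -> float:
    """Similarity of two GO term sets under a pairwise measure and a combination rule."""
    set1, set2 = list(set1), list(set2)
    if not set1 or not set2:
        raise ValueError("termset_sim of an empty set")
    m = np.array([[pairwise(t1, t2) for t2 in set2] for t1 in set1])
    return _combine(m, combine)


def pairwise_measure(
    name: str,
    dag: OntologyDag,
    ic: ICTable | None = None,
    weights: dict[str, float] | None = None,
) -> Callable[[str, str], float]:
    """Bind a measure name to its context; returns a memoised f(a, b) -> s."""
    if name == "wang":
        base = lambda a, b: sim_wang(dag, a, b, weights)  # noqa: E731
    elif name in ("resnik", "lin", "rel", "jiang"):
        if ic is None:
            raise ValueError(f"measure {name!r} needs an ICTable")
        fn = {"resnik": sim_resnik, "lin": sim_lin, "rel": sim_rel, "jiang": sim_jiang}[name]
        base = lambda a, b: fn(dag, ic, a, b)  # noqa: E731
    else:
        raise ValueError(f"unknown measure {name!r}; pick from {PAIRWISE_MEASURES}")
    cache: dict[tuple[str, str], float] = {}

    def measure(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = base(*key)
        return cache[key]

    return measure


@dataclass
class SimilarityMatrix:
    """Symmetric similarity in [0, 1] over terms or clusters, with a distance view."""

    ids: list[str]
    values: np.ndarray
    measure: str
    combine: str | None = None  # set for cluster-level matrices

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape does not match ids")
        v = np.clip((v + v.T) / 2.0, 0.0, 1.0)  # symmetrise + clamp fp rounding
        np.fill_diagonal(v, 1.0)
        self.values = v

    def distance(self) -> np.ndarray:
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# similarity matrix; measure={self.measure}"
                     + (f"; combine={self.combine}" if self.combine else "") + "\n")
            self.to_frame().rename_axis("id").to_csv(fh, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            df = pd.read_csv(fh, sep="\t", index_col="id")
        meta = dict(
            item.strip().split("=") for item in header.split(";")[1:] if "=" in item
        )
        return cls(
            ids=list(df.index),
            values=df.to_numpy(),
            measure=meta.get("measure", "unknown").strip(),
            combine=meta.get("combine"),
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format (id1, id2, similarity) triplets of the upper triangle."""
        rows = [
            (self.ids[i], self.ids[j], self.values[i, j])
            for i in range(len(self.ids))
            for j in range(i, len(self.ids))
        ]
        return pd.DataFrame(rows, columns=["id1", "id2", "similarity"])


def similarity_matrix(
    items: Sequence[str] | dict[str, Sequence[str]],
    measure: Callable[[str, str], float],
    measure_name: str,
    combine: str | None = None,
) -> SimilarityMatrix:
    """Evaluate all pairs of terms (sequence) or term sets (mapping).

    For a mapping, each value is a term set and ``combine`` picks the set-level
    rule (default BMA).
    """
    if isinstance(items, dict):
        ids = sorted(items)
        combine = combine or "BMA"
        sets = {i: list(items[i]) for i in ids}
        n = len(ids)
        v = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                v[i, j] = v[j, i] = termset_sim(sets[ids[i]], sets[ids[j]], measure, combine)
        return SimilarityMatrix(ids=ids, values=v, measure=measure_name, combine=combine)
    ids = list(items)
    n = len(ids)
    v = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = measure(ids[i], ids[j])
    return SimilarityMatrix(ids=ids, values=v, measure=measure_name)
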