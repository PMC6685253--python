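"""Gene -> GO annotation sets: GAF/TSV readers and true-path propagation.

A gene annotated to a term is implicitly annotated to every ancestor of that
term (the true-path rule); both enrichment counts and information content are
computed on the propagated closure.  Gene identity is taken verbatim from the
annotation file (GAF column 2); no identifier mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .ontology import DEFAULT_RELATIONS, OntologyDag

logger = logging.getLogger(__name__)

# GAF aspect column -> namespace
ASPECT = {"P": "biological_process", "F": "molecular_function", "C": "cellular_component"}
ASPECT_OF = {v: k for k, v in ASPECT.items()}

GAF_COLUMNS = 17


@dataclass
class AnnotationSet:
    """Gene <-> term incidence for a single namespace.

    ``direct`` holds the annotations as read; the ancestor-propagated closure
    is derived lazily against a DAG and cached.
    """

    direct: dict[str, frozenset[str]]
    namespace: str
    provenance: str = ""
    relations: frozenset[str] = DEFAULT_RELATIONS
    _propagated: dict[str, frozenset[str]] | None = field(default=None, repr=False)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.direct)

    def propagated(self, dag: OntologyDag) -> dict[str, frozenset[str]]:
        if self._propagated is None:
            self._propagated = {
                g: frozenset().union(*({t} | dag.ancestors(t, self.relations) for t in ts))
                if ts
                else frozenset()
                for g, ts in self.direct.items()
            }
        return self._propagated

    def terms(self, dag: OntologyDag) -> frozenset[str]:
        """All terms carrying at least one (propagated) annotation."""
        prop = self.propagated(dag)
        return frozenset().union(*prop.values()) if prop else frozenset()


def _ingest(
    pairs: list[tuple[str, str]], dag: OntologyDag, namespace: str, provenance: str
) -> AnnotationSet:
    """Common tail of the readers: resolve alt ids, drop obsolete/foreign terms."""
    direct: dict[str, set[str]] = {}
    dropped_obsolete = 0
    dropped_namespace = 0
    for gene, term in pairs:
        try:
            primary = dag.resolve(term)
        except KeyError:
            logger.warning("%s: unknown term %s, row dropped", provenance, term)
            continue
        if dag.terms[primary].is_obsolete:
            dropped_obsolete += 1
            continue
        if dag.terms[primary].namespace != namespace:
            dropped_namespace += 1
            continue
        direct.setdefault(gene, set()).add(primary)
    if dropped_obsolete:
        logger.warning("%s: dropped %d annotation(s) to obsolete terms", provenance, dropped_obsolete)
    if dropped_namespace:
        logger.info("%s: dropped %d annotation(s) outside %s", provenance, dropped_namespace, namespace)
    annot = AnnotationSet(
        direct={g: frozenset(ts) for g, ts in direct.items()},
        namespace=namespace,
        provenance=provenance,
    )
    logger.info(
        "%s: %d genes annotated with at least one %s term", provenance, len(annot.direct), namespace
    )
    return annot


def read_gaf(
    source,
    dag: OntologyDag,
    namespace: str,
    evidence_filter: set[str] | None = None,
) -> AnnotationSet:
    """Read a GAF 2.x file restricted to one namespace.

    Rows whose qualifier contains ``NOT`` are discarded; ``evidence_filter``,
    if given, keeps only the listed evidence codes.  The gene key is the
    DB object id (column 2).
    """
    close = False
    if isinstance(source, str) and "\t" not in source and "\n" not in source:
        source = open(source)
        close = True
    try:
        aspect_wanted = ASPECT_OF[namespace]
        pairs: list[tuple[str, str]] = []
        lines = source.splitlines() if isinstance(source, str) else source
        for lineno, line in enumerate(lines, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) != GAF_COLUMNS:
                raise ValueError(
                    f"GAF line {lineno}: expected {GAF_COLUMNS} columns, got {len(fields)}"
                )
            _db, gene, _symbol, qualifier, term, _ref, evidence = fields[:7]
            aspect = fields[8]
            if "NOT" in qualifier.split("|"):
                continue
            if aspect != aspect_wanted:
                continue
            if evidence_filter is not None and evidence not in evidence_filter:
                continue
            pairs.append((gene, term))
        name = getattr(source, "name", "<gaf>")
        filt = f"evidence={sorted(evidence_filter)}" if evidence_filter else "all evidence"
        return _ingest(pairs, dag, namespace, f"{name} [{namespace}, {filt}]")
    finally:
        if close:
            source.close()


def read_tsv_annotation(source, dag: OntologyDag, namespace: str) -> AnnotationSet:
    """Read a two-column ``gene_id<TAB>go_id`` annotation file."""
    close = False
    if isinstance(source, str) and "\t" not in source and "\n" not in source:
        source = open(source)
        close = True
    try:
        pairs: list[tuple[str, str]] = []
        lines = source.splitlines() if isinstance(source, str) else source
        for lineno, line in enumerate(lines, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"annotation TSV line {lineno}: expected 2 columns, got {len(fields)}")
            pairs.append((fields[0], fields[1]))
        name = getattr(source, "name", "<tsv>")
        return _ingest(pairs, dag, namespace, f"{name} [{namespace}]")
    finally:
        if close:
            source.close()


def propagate(annot: AnnotationSet, dag: OntologyDag) -> AnnotationSet:
    """Return an AnnotationSet whose direct sets are the ancestor closure (idempotent)."""
    return AnnotationSet(
        direct=dict(annot.propagated(dag)),
        namespace=annot.namespace,
        provenance=annot.provenance + " [propagated]",
        relations=annot.relations,
    )


def annotated_genes(
    annot: AnnotationSet, dag: OntologyDag, term: str, universe: frozenset[str] | set[str]
) -> frozenset[str]:
    """Genes of ``universe`` whose propagated annotation contains ``term``."""
    t = dag.resolve(term)
    prop = annot.propagated(dag)
    return frozenset(g for g in universe if t in prop.get(g, frozenset()))


def term_gene_index(
    annot: AnnotationSet, dag: OntologyDag, universe: frozenset[str] | set[str]
) -> dict[str, frozenset[str]]:
    """Invert the propagated annotation over a universe: term -> annotated genes."""
    index: dict[str, set[str]] = {}
    prop = annot.propagated(dag)
    for gene in universe:
        for term in prop.get(gene, frozenset()):
            index.setdefault(term, set()).add(gene)
    return {t: frozenset(gs) for t, gs in index.items()}


def read_gene_list(path) -> list[str]:
    """One gene id per line, UTF-8; blank lines ignored; order kept, duplicates dropped."""
    seen: dict[str, None] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            gene = line.strip()
            if gene:
                seen.setdefault(gene, None)
    return list(seen)
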