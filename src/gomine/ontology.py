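"""Gene Ontology DAG: OBO parsing, validation and graph primitives.

The ontology is a directed acyclic graph whose nodes are GO terms and whose
edges are typed child->parent relations.  Only ``is_a`` and ``part_of`` are
interpreted; these are the relations along which annotations propagate and
along which Wang's semantic-contribution values flow.  All analyses are
single-namespace (BP, MF or CC), so each namespace must have exactly one
root term.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")

#: relations interpreted throughout the package (propagation, Wang, ancestors)
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass(frozen=True)
class GoTerm:
    """A single GO term (node of the ontology)."""

    id: str
    name: str
    namespace: str
    is_obsolete: bool = False
    alt_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not GO_ID_PATTERN.match(self.id):
            raise ValueError(f"not a GO accession: {self.id!r}")
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {self.namespace!r} for {self.id}")


@dataclass
class AncestorGraph:
    """The induced sub-DAG on a term and all its ancestors (Wang's DAG_A)."""

    target: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str, str]]  # (child, parent, relation)

    def children_in(self, term: str) -> list[tuple[str, str]]:
        """(child, relation) pairs for edges pointing at ``term`` inside the sub-DAG."""
        return [(c, r) for (c, p, r) in self.edges if p == term]


class OntologyDag:
    """Validated GO graph with typed edges and per-namespace roots.

    Parameters
    ----------
    terms
        Mapping of primary accession to :class:`GoTerm`.  Obsolete terms may
        be present but carry no edges.
    edges
        Iterable of ``(child_id, parent_id, relation)`` triples with relation
        in ``{"is_a", "part_of"}``.
    """

    def __init__(self, terms: dict[str, GoTerm], edges: Iterable[tuple[str, str, str]]):
        self.terms = dict(terms)
        self.edges: frozenset[tuple[str, str, str]] = frozenset(edges)
        self._parents: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
        self._children: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
        self._alt: dict[str, str] = {}
        for term in self.terms.values():
            for alt in term.alt_ids:
                prev = self._alt.get(alt)
                if prev is not None and prev != term.id:
                    raise ValueError(f"alt_id {alt} maps to both {prev} and {term.id}")
                self._alt[alt] = term.id
        self._validate_edges()
        self.roots: dict[str, str] = self._find_roots()
        self._anc_cache: dict[frozenset[str], dict[str, frozenset[str]]] = {}
        self._level_cache: dict[str, dict[str, int]] = {}

    # -- construction / validation ------------------------------------------

    def _validate_edges(self) -> None:
        for child, parent, rel in self.edges:
            for endpoint in (child, parent):
                if endpoint not in self.terms:
                    raise ValueError(f"edge references undeclared term {endpoint}")
            if rel not in DEFAULT_RELATIONS:
                raise ValueError(f"unsupported relation {rel!r} on edge {child}->{parent}")
            if self.terms[child].is_obsolete or self.terms[parent].is_obsolete:
                raise ValueError(f"obsolete term with incident edge: {child}->{parent}")
            self._parents[child].append((parent, rel))
            self._children[parent].append((child, rel))
        for ns in {t.namespace for t in self.terms.values()}:
            g = nx.DiGraph(
                (c, p) for (c, p, _r) in self.edges if self.terms[c].namespace == ns
            )
            try:
                cycle = nx.find_cycle(g)
            except nx.NetworkXNoCycle:
                continue
            path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
            raise ValueError(f"cycle in namespace {ns}: {path}")

    def _find_roots(self) -> dict[str, str]:
        roots: dict[str, str] = {}
        for ns in sorted({t.namespace for t in self.terms.values() if not t.is_obsolete}):
            candidates = sorted(
                t.id
                for t in self.terms.values()
                if t.namespace == ns and not t.is_obsolete and not self._parents[t.id]
            )
            if len(candidates) != 1:
                raise ValueError(
                    f"namespace {ns} must have exactly one root, found {candidates}"
                )
            roots[ns] = candidates[0]
        return roots

    # -- lookups -------------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Resolve an alt_id to its primary accession (identity for primaries)."""
        if term_id in self.terms:
            return term_id
        primary = self._alt.get(term_id)
        if primary is not None:
            logger.info("alt_id %s resolved to %s", term_id, primary)
            return primary
        raise KeyError(f"unknown GO term {term_id}")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt

    def _check_usable(self, term_id: str) -> str:
        t = self.resolve(term_id)
        if self.terms[t].is_obsolete:
            raise ValueError(f"term {t} is obsolete")
        return t

    def parents(self, term_id: str, relations: frozenset[str] = DEFAULT_RELATIONS):
        t = self.resolve(term_id)
        return [(p, r) for (p, r) in self._parents[t] if r in relations]

    def children(self, term_id: str, relations: frozenset[str] = DEFAULT_RELATIONS):
        t = self.resolve(term_id)
        return [(c, r) for (c, r) in self._children[t] if r in relations]

    def namespace_terms(self, namespace: str, include_obsolete: bool = False) -> list[str]:
        return sorted(
            t.id
            for t in self.terms.values()
            if t.namespace == namespace and (include_obsolete or not t.is_obsolete)
        )

    # -- graph primitives ----------------------------------------------------

    def ancestors(
        self, term_id: str, relations: frozenset[str] = DEFAULT_RELATIONS
    ) -> frozenset[str]:
        """All terms reachable from ``term_id`` along ``relations``; excludes the term."""
        t = self._check_usable(term_id)
        relations = frozenset(relations)
        cache = self._anc_cache.setdefault(relations, {})
        if t in cache:
            return cache[t]
        # iterative DFS with memoisation; DAG guarantees termination
        stack = [t]
        order: list[str] = []
        seen = {t}
        while stack:
            node = stack.pop()
            order.append(node)
            for parent, _r in self._parents[node]:
                if _r in relations and parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        for node in reversed(order):
            if node in cache:
                continue
            acc: set[str] = set()
            for parent, _r in self._parents[node]:
                if _r in relations:
                    acc.add(parent)
                    if parent not in cache:
                        self.ancestors(parent, relations)
                    acc.update(cache[parent])
            cache[node] = frozenset(acc)
        return cache[t]

    def descendants(
        self, term_id: str, relations: frozenset[str] = DEFAULT_RELATIONS
    ) -> frozenset[str]:
        """Mirror of :meth:`ancestors`: all terms from which ``term_id`` is reachable."""
        t = self._check_usable(term_id)
        out: set[str] = set()
        stack = [t]
        while stack:
            node = stack.pop()
            for child, rel in self._children[node]:
                if rel in relations and child not in out:
                    out.add(child)
                    stack.append(child)
        return frozenset(out)

    def induced_ancestor_graph(
        self, term_id: str, relations: frozenset[str] = DEFAULT_RELATIONS
    ) -> AncestorGraph:
        """Sub-DAG on a term plus its ancestors, edge relation labels preserved."""
        t = self._check_usable(term_id)
        nodes = frozenset({t} | self.ancestors(t, relations))
        edges = frozenset(
            (c, p, r) for (c, p, r) in self.edges if c in nodes and p in nodes and r in relations
        )
        return AncestorGraph(target=t, nodes=nodes, edges=edges)

    def term_levels(self, namespace: str) -> dict[str, int]:
        """Longest-path depth from the namespace root (root = 0).

        Guarantees every child sits at a strictly higher level than each of
        its parents, so processing by decreasing level visits all children
        before any parent (the order the elim sweep requires).
        """
        if namespace in self._level_cache:
            return self._level_cache[namespace]
        members = set(self.namespace_terms(namespace))
        g = nx.DiGraph()
        g.add_nodes_from(members)
        g.add_edges_from(
            (p, c) for (c, p, _r) in self.edges if c in members and p in members
        )
        levels: dict[str, int] = {}
        for node in nx.topological_sort(g):
            preds = [levels[p] for p in g.predecessors(node)]
            levels[node] = 1 + max(preds) if preds else 0
        self._level_cache[namespace] = levels
        return levels

    def processing_order(self, namespace: str) -> list[str]:
        """Terms by decreasing level, ties by ascending accession (bit-reproducible)."""
        levels = self.term_levels(namespace)
        return sorted(levels, key=lambda t: (-levels[t], t))

    def common_ancestors(self, terms: Iterable[str]) -> frozenset[str]:
        """Reflexive common ancestors of a term set (a singleton includes itself)."""
        terms = [self._check_usable(t) for t in terms]
        if not terms:
            raise ValueError("common_ancestors of an empty set")
        acc: set[str] | None = None
        for t in terms:
            closure = {t} | set(self.ancestors(t))
            acc = closure if acc is None else acc & closure
        return frozenset(acc or set())


def parse_obo(source) -> OntologyDag:
    """Parse OBO 1.2 text into a validated :class:`OntologyDag`.

    Accepts a path, a file object or the raw OBO text.  Obsolete terms are
    retained in the term map but stripped of all edges; relations other than
    ``is_a``/``part_of`` and (rare) cross-namespace edges are dropped with a
    warning.  A cycle within a namespace or an edge to an undeclared id is a
    hard error.
    """
    if isinstance(source, str) and "[Term]" in source:
        source = io.StringIO(source)
    graph = obonet.read_obo(source, ignore_obsolete=False)

    terms: dict[str, GoTerm] = {}
    undeclared = []
    for node, data in graph.nodes(data=True):
        if "namespace" not in data and "name" not in data:
            undeclared.append(node)
            continue
        terms[node] = GoTerm(
            id=node,
            name=data.get("name", ""),
            namespace=data["namespace"],
            is_obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
            alt_ids=frozenset(data.get("alt_id", [])),
        )
    if undeclared:
        raise ValueError(f"edges reference undeclared term(s): {sorted(undeclared)}")

    edges: set[tuple[str, str, str]] = set()
    for child, parent, rel in graph.edges(keys=True):
        if rel not in DEFAULT_RELATIONS:
            logger.warning("dropping edge %s -[%s]-> %s (unsupported relation)", child, rel, parent)
            continue
        if terms[child].is_obsolete or terms[parent].is_obsolete:
            # obsolete stanzas keep their term entry but carry no edges
            continue
        if terms[child].namespace != terms[parent].namespace:
            logger.warning(
                "dropping cross-namespace edge %s (%s) -> %s (%s)",
                child, terms[child].namespace, parent, terms[parent].namespace,
            )
            continue
        edges.add((child, parent, rel))
    return OntologyDag(terms, edges)
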