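"""Shared fixtures: tiny hand-checkable DAGs and a small synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from gomine.annotation import AnnotationSet
from gomine.fixtures import FixtureSpec, make_annotations, make_dag, make_study
from gomine.ontology import GoTerm, OntologyDag

BP = "biological_process"


def build_dag(edges, extra_terms=(), namespace=BP, obsolete=()):
    """OntologyDag from (child, parent, relation) triples; terms inferred."""
    ids = {t for e in edges for t in e[:2]} | set(extra_terms)
    terms = {
        t: GoTerm(t, f"term {t}", namespace, is_obsolete=t in obsolete) for t in ids
    }
    return OntologyDag(terms, edges)


# accession aliases used throughout the tests
A, B, C, D, E = (f"GO:000000{i}" for i in range(1, 6))
ROOT = "GO:0000099"


@pytest.fixture
def chain_dag():
    """A is_a B is_a C (C is the root)."""
    return build_dag([(A, B, "is_a"), (B, C, "is_a")])


@pytest.fixture
def diamond_dag():
    """A -> {B, C} -> D: two paths from A to the root D."""
    return build_dag([(A, B, "is_a"), (A, C, "is_a"), (B, D, "is_a"), (C, D, "is_a")])


@pytest.fixture
def small_spec():
    return FixtureSpec(n_terms=80, n_genes=400, n_lists=2, seed=7)


@pytest.fixture
def small_fixture(small_spec):
    dag = make_dag(small_spec)
    annot = make_annotations(small_spec, dag)
    study = make_study(small_spec, dag, annot)
    return small_spec, dag, annot, study


def random_dag(rng: np.random.Generator, n_terms: int = 12) -> OntologyDag:
    """Random rooted single-namespace DAG (parents only from earlier terms)."""
    ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_parents = 1 + (rng.random() < 0.3)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            rel = "part_of" if rng.random() < 0.25 else "is_a"
            edges.append((ids[i], ids[int(p)], rel))
    return build_dag(edges, extra_terms=ids)


def annotation_from_direct(direct: dict[str, set[str]], namespace=BP) -> AnnotationSet:
    return AnnotationSet(
        direct={g: frozenset(ts) for g, ts in direct.items()}, namespace=namespace
    )
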