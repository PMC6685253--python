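"""Synthetic ontology / annotation / study generator.

Everything downstream of the file readers is testable offline against data
with known structure: a single-namespace rooted DAG whose depth and branching
are controlled, per-gene annotations whose density decays with term depth
(deep, specific terms annotate few genes, as in the real ontology), and
interest gene lists in which chosen "planted" terms are over-represented at a
known odds ratio.  A fixed master seed fully determines every output byte;
each component (DAG, annotations, study) draws from its own RNG stream so
regenerating one does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import AnnotationSet
from .ontology import GoTerm, OntologyDag

GAF_HEADER = "!gaf-version: 2.2\n"


@dataclass
class FixtureSpec:
    """Knobs of the generator; defaults describe the standard study conditions.

    A mid-size single-namespace ontology (300 terms, depth 8) annotated over
    2000 genes at ~4 direct terms per annotated gene, three interest lists of
    roughly 10% of the background each, and one planted term per list whose
    genes enter the list at 10x odds.
    """

    n_terms: int = 300
    max_depth: int = 8
    extra_parent_prob: float = 0.25  # chance of a second parent (DAG, not tree)
    part_of_fraction: float = 0.2
    n_genes: int = 2000
    mean_direct_terms: float = 4.0
    annotation_decay: float = 0.8  # direct-annotation weight ~ decay**level
    unannotated_fraction: float = 0.15
    n_lists: int = 3
    n_planted: int | None = None  # default: one per list
    planted_odds: float = 10.0
    base_rate: float = 0.08  # background gene's chance of entering a list
    namespace: str = "biological_process"
    seed: int = 0

    def rng(self, component: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, component])


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def make_dag(spec: FixtureSpec) -> OntologyDag:
    """Rooted single-namespace DAG, acyclic by construction.

    Terms are created in accession order; each non-root term gets a primary
    parent one level up (so its longest-path level equals its drawn depth) and
    possibly an extra parent from any strictly shallower level.
    """
    rng = spec.rng(0)
    terms: dict[str, GoTerm] = {}
    edges: set[tuple[str, str, str]] = set()
    by_depth: dict[int, list[str]] = {0: [_term_id(0)]}
    terms[_term_id(0)] = GoTerm(_term_id(0), "root process", spec.namespace)
    for i in range(1, spec.n_terms):
        tid = _term_id(i)
        terms[tid] = GoTerm(tid, f"synthetic process {i}", spec.namespace)
        depth = int(rng.integers(1, spec.max_depth + 1))
        depth = min(depth, max(by_depth) + 1)
        parent = str(rng.choice(by_depth[depth - 1]))
        rel = "part_of" if rng.random() < spec.part_of_fraction else "is_a"
        edges.add((tid, parent, rel))
        if depth > 1 and rng.random() < spec.extra_parent_prob:
            extra_depth = int(rng.integers(0, depth - 1))
            extra = str(rng.choice(by_depth[extra_depth]))
            if extra != parent:
                rel2 = "part_of" if rng.random() < spec.part_of_fraction else "is_a"
                edges.add((tid, extra, rel2))
        by_depth.setdefault(depth, []).append(tid)
    return OntologyDag(terms, edges)


def write_obo(dag: OntologyDag, path) -> None:
    """Serialise a DAG as OBO 1.2; round-trips through parse_obo exactly."""
    lines = ["format-version: 1.2", "ontology: gomine-fixture", ""]
    for tid in sorted(dag.terms):
        term = dag.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        lines.append(f"name: {term.name}")
        lines.append(f"namespace: {term.namespace}")
        for alt in sorted(term.alt_ids):
            lines.append(f"alt_id: {alt}")
        if term.is_obsolete:
            lines.append("is_obsolete: true")
        for parent, rel in sorted(dag.parents(tid)):
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def make_annotations(spec: FixtureSpec, dag: OntologyDag) -> AnnotationSet:
    """Direct annotations per gene, sampling terms with depth-decaying weight."""
    rng = spec.rng(1)
    levels = dag.term_levels(spec.namespace)
    candidates = sorted(t for t in levels if levels[t] > 0)
    weights = np.array([spec.annotation_decay ** levels[t] for t in candidates])
    weights /= weights.sum()
    direct: dict[str, frozenset[str]] = {}
    n_annotated = int(round(spec.n_genes * (1.0 - spec.unannotated_fraction)))
    for g in range(n_annotated):
        gene = f"gene{g + 1:05d}"
        k = 1 + rng.poisson(max(spec.mean_direct_terms - 1.0, 0.0))
        k = min(k, len(candidates))
        chosen = rng.choice(len(candidates), size=k, replace=False, p=weights)
        direct[gene] = frozenset(candidates[int(i)] for i in chosen)
    return AnnotationSet(direct=direct, namespace=spec.namespace, provenance="fixture")


def all_genes(spec: FixtureSpec) -> list[str]:
    return [f"gene{g + 1:05d}" for g in range(spec.n_genes)]


def write_gaf(annot: AnnotationSet, path, aspect: str = "P") -> None:
    rows = []
    for gene in sorted(annot.direct):
        for term in sorted(annot.direct[gene]):
            cols = [
                "GOMINE", gene, gene, "involved_in", term, "GOMINE:0000001", "IEA",
                "", aspect, "", "", "protein", "taxon:0000", "20240101", "GOMINE", "", "",
            ]
            rows.append("\t".join(cols))
    Path(path).write_text(GAF_HEADER + "\n".join(rows) + "\n", encoding="utf-8")


def pick_planted_terms(
    spec: FixtureSpec, dag: OntologyDag, annot: AnnotationSet
) -> list[str]:
    """Deterministically pick well-annotated leaf terms to plant.

    Planting at leaves keeps the ground truth unambiguous: a planted signal
    on an internal term is inherited by its descendants, so the "most
    enriched term" would be ill-defined.  Preferred candidates are leaves at
    level >= 2 with 20-100 annotated genes (specific, but big enough to carry
    a detectable signal); the most annotated candidates win, ties by accession.
    """
    from .annotation import term_gene_index

    n_planted = spec.n_planted if spec.n_planted is not None else spec.n_lists
    levels = dag.term_levels(spec.namespace)
    index = term_gene_index(annot, dag, annot.genes)
    sizes = {t: len(g) for t, g in index.items()}
    leaves = {t for t in sizes if not dag.descendants(t)}
    preferred = sorted(
        (t for t in leaves if levels[t] >= 2 and 20 <= sizes[t] <= 100),
        key=lambda t: (-sizes[t], t),
    )
    fallback = sorted(
        (t for t in sizes if levels[t] >= 1 and t not in set(preferred)),
        key=lambda t: (-sizes[t], t),
    )
    ranked = preferred + fallback
    if len(ranked) < n_planted:
        raise ValueError("not enough annotated terms to plant the requested signals")
    return ranked[:n_planted]


@dataclass
class Study:
    """Background + interest lists with a ground-truth manifest."""

    background: list[str]
    interest: dict[str, list[str]]  # list_id -> gene ids
    planted: dict[str, str]  # list_id -> planted term
    manifest: dict = field(default_factory=dict)


def make_study(spec: FixtureSpec, dag: OntologyDag, annot: AnnotationSet) -> Study:
    """Sample interest lists in which each list's planted term is over-represented.

    A background gene enters a list with probability ``base_rate``; genes
    carrying the list's planted term (by propagated annotation) enter with the
    probability whose odds are ``planted_odds`` times the base odds, so
    ``planted_odds = 1`` reduces to uniform sampling.
    """
    from .annotation import term_gene_index

    rng = spec.rng(2)
    background = all_genes(spec)
    planted_terms = pick_planted_terms(spec, dag, annot)
    index = term_gene_index(annot, dag, annot.genes)
    q0 = spec.base_rate
    odds0 = q0 / (1.0 - q0)
    q1 = (spec.planted_odds * odds0) / (1.0 + spec.planted_odds * odds0)
    interest: dict[str, list[str]] = {}
    planted: dict[str, str] = {}
    for li in range(spec.n_lists):
        list_id = f"list{li + 1}"
        term = planted_terms[li % len(planted_terms)]
        planted[list_id] = term
        carriers = index.get(term, frozenset())
        draws = rng.random(len(background))
        members = [
            g
            for g, u in zip(background, draws)
            if u < (q1 if g in carriers else q0)
        ]
        interest[list_id] = members
    manifest = {
        "seed": spec.seed,
        "planted": planted,
        "planted_odds": spec.planted_odds,
        "base_rate": spec.base_rate,
        "list_sizes": {k: len(v) for k, v in interest.items()},
        "n_background": len(background),
    }
    return Study(background=background, interest=interest, planted=planted, manifest=manifest)


def write_study(study: Study, out_dir) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    bg = out_dir / "background.txt"
    bg.write_text("\n".join(study.background) + "\n", encoding="utf-8")
    paths["background"] = bg
    for list_id, genes in study.interest.items():
        p = out_dir / f"{list_id}.txt"
        p.write_text("\n".join(genes) + "\n", encoding="utf-8")
        paths[list_id] = p
    manifest = out_dir / "manifest.json"
    with open(manifest, "w", encoding="utf-8") as fh:
        json.dump(study.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = manifest
    return paths


def generate_fixture_files(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Full fixture: OBO + GAF + gene lists + manifest under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dag = make_dag(spec)
    annot = make_annotations(spec, dag)
    study = make_study(spec, dag, annot)
    paths = write_study(study, out_dir)
    obo = out_dir / "ontology.obo"
    write_obo(dag, obo)
    paths["obo"] = obo
    gaf = out_dir / "annotations.gaf"
    write_gaf(annot, gaf)
    paths["gaf"] = gaf
    return paths
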