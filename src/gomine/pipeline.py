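"""End-to-end orchestration: annotate -> enrich -> similarity -> cluster -> report.

`run_pipeline` drives the whole workflow from a config mapping (the YAML the
CLI reads) and writes every artifact — merged enrichment table, similarity
matrix, dendrograms, cluster assignments, MDS coordinates, heatmap/barchart/
upset twins, static images, HTML report and the structured run log — into one
output directory.  All tabular outputs are byte-reproducible for fixed inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import annotation as ann
from . import clustering as cl
from . import enrichment as enr
from . import reporting as rep
from . import semsim as ss
from .ontology import OntologyDag, parse_obo

logger = logging.getLogger(__name__)

NAMESPACE_ALIASES = {
    "bp": "biological_process",
    "mf": "molecular_function",
    "cc": "cellular_component",
}


def resolve_namespace(value: str) -> str:
    ns = NAMESPACE_ALIASES.get(value.lower(), value)
    if ns not in ("biological_process", "molecular_function", "cellular_component"):
        raise ValueError(f"unknown namespace {value!r}")
    return ns


def load_annotations(path, fmt: str, dag: OntologyDag, namespace: str,
                     evidence: set[str] | None = None) -> ann.AnnotationSet:
    if fmt == "gaf":
        return ann.read_gaf(str(path), dag, namespace, evidence_filter=evidence)
    if fmt == "tsv":
        return ann.read_tsv_annotation(str(path), dag, namespace)
    raise ValueError(f"unknown annotation format {fmt!r} (expected gaf or tsv)")


def run_enrichment(config: dict, dag: OntologyDag, annot: ann.AnnotationSet,
                   log: rep.RunLog) -> enr.EnrichmentTable:
    background = ann.read_gene_list(config["background"])
    algorithm = config.get("algorithm", "elim")
    alpha = float(config.get("alpha", 0.01))
    threshold = float(config.get("threshold", 0.01))
    runs = []
    for list_id, list_path in config["lists"].items():
        interest = ann.read_gene_list(list_path)
        if algorithm == "elim":
            run = enr.elim_enrichment(interest, background, annot, dag,
                                      alpha=alpha, list_id=list_id)
        elif algorithm == "classic":
            run = enr.classic_enrichment(interest, background, annot, dag, list_id=list_id)
        else:
            raise ValueError(f"unknown algorithm {algorithm!r} (expected classic or elim)")
        runs.append(run)
        log.record("enrichment", **{f"{list_id}_n_interest_annotated": run.n})
    table = enr.merge_enrich_terms(runs, dag, threshold=threshold)
    log.record(
        "enrichment",
        algorithm=algorithm, alpha=alpha, threshold=threshold,
        n_background=len(background), n_annotated_universe=runs[0].N,
        n_terms_retained=len(table), per_list_enriched=enr.go_count(table),
    )
    return table


def run_pipeline(config: dict, out_dir) -> dict[str, Path]:
    """Execute every stage of the workflow; returns the artifact path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = rep.RunLog()
    artifacts: dict[str, Path] = {}

    # --- load ontology and annotations -----------------------------------
    namespace = resolve_namespace(config.get("namespace", "biological_process"))
    dag = parse_obo(str(config["obo"]))
    log.record_input("load", "obo", config["obo"])
    log.record("load", namespace=namespace, n_terms=len(dag.terms))
    fmt = config.get("annotation_format", "gaf")
    evidence = set(config["evidence"]) if config.get("evidence") else None
    annot = load_annotations(config["annotations"], fmt, dag, namespace, evidence)
    log.record_input("load", "annotations", config["annotations"])
    log.record("load", n_genes_annotated=len(annot.direct))

    # --- enrichment -------------------------------------------------------
    table = run_enrichment(config, dag, annot, log)
    artifacts["enrichment"] = out / "enrichment.tsv"
    table.to_tsv(artifacts["enrichment"])
    counts = enr.go_count(table)
    memberships = enr.upset_memberships(table)
    artifacts["gocount"] = out / "gocount.tsv"
    artifacts["upset"] = out / "upset.json"
    rep.render_barchart(counts, out / "gocount.png", twin_path=artifacts["gocount"])
    rep.render_upset(memberships, out / "upset.png", twin_path=artifacts["upset"])
    if len(table) < 2:
        logger.warning("fewer than two enriched terms; similarity/clustering skipped")
        log.record("enrichment", note="fewer than two enriched terms, stopped after merge")
        log.write(out / "run.json")
        artifacts["run_log"] = out / "run.json"
        return artifacts

    # --- semantic similarity ---------------------------------------------
    measure_name = config.get("measure", "wang")
    combine = config.get("combine", "BMA")
    background = ann.read_gene_list(config["background"])
    ic = ss.compute_ic(annot, dag, universe=frozenset(background) & annot.genes)
    measure = ss.pairwise_measure(measure_name, dag, ic=ic)
    simmat = ss.similarity_matrix(table.term_ids, measure, measure_name)
    artifacts["similarity"] = out / "simmatrix.tsv"
    simmat.to_tsv(artifacts["similarity"])
    log.record("semsim", measure=measure_name, combine=combine, n_terms=len(simmat.ids))

    # --- clustering -------------------------------------------------------
    tree = cl.hclust_ward2(simmat)
    artifacts["merges"] = out / "dendrogram_merges.tsv"
    tree.to_merge_table(artifacts["merges"])
    artifacts["newick"] = out / "dendrogram.nwk"
    artifacts["newick"].write_text(tree.to_newick() + "\n", encoding="utf-8")
    cut_cfg = dict(config.get("cut", {}))
    mode = cut_cfg.get("mode", "dynamic")
    if mode == "static":
        assignment = cl.cut_static(tree, k=cut_cfg.get("k"), h=cut_cfg.get("h"))
    elif mode == "dynamic":
        assignment = cl.cut_dynamic(
            tree,
            min_cluster_size=int(cut_cfg.get("min_size", 2)),
            deep_split=int(cut_cfg.get("deep_split", 2)),
        )
    else:
        raise ValueError(f"unknown cut mode {mode!r}")
    names = cl.name_clusters(dag, ic, assignment)
    artifacts["clusters"] = out / "clusters.tsv"
    assignment.to_frame(names, dag).to_csv(artifacts["clusters"], sep="\t", index=False)
    log.record(
        "clustering",
        linkage="ward.D2", cut=mode, parameters=assignment.parameters,
        n_clusters=assignment.n_clusters,
        cluster_names={str(k): v for k, v in names.items()},
        common_ancestor_rule="deepest common ancestor, ties by IC then accession",
    )

    # --- term-level MDS ---------------------------------------------------
    coords, distortion = cl.mds_classical(simmat.distance())
    artifacts["mds_terms"] = out / "mds_terms.tsv"
    rep.render_mds(coords, simmat.ids, out / "mds_terms.png", twin_path=artifacts["mds_terms"])
    log.record("mds", terms_distortion=round(distortion, 6))

    # --- terms heatmap ----------------------------------------------------
    bundle = rep.build_terms_heatmap(table, tree, assignment, ic, dag)
    artifacts["heatmap"] = out / "terms_heatmap.tsv"
    bundle.to_tsv(artifacts["heatmap"])
    rep.render_terms_heatmap(bundle, out / "terms_heatmap.png")

    # --- second-level clustering (clusters of clusters) -------------------
    if assignment.n_clusters >= 2:
        cluster_mat = cl.cluster_set_matrix(assignment, measure, measure_name, combine=combine)
        artifacts["cluster_similarity"] = out / "cluster_simmatrix.tsv"
        cluster_mat.to_tsv(artifacts["cluster_similarity"])
        sizes = {str(k): len(v) for k, v in assignment.members().items()}
        if len(cluster_mat.ids) >= 2:
            ctree = cl.hclust_ward2(cluster_mat)
            artifacts["cluster_newick"] = out / "cluster_dendrogram.nwk"
            artifacts["cluster_newick"].write_text(ctree.to_newick() + "\n", encoding="utf-8")
            cbundle = rep.build_clusters_heatmap(assignment, ctree, names, dag)
            artifacts["clusters_heatmap"] = out / "clusters_heatmap.tsv"
            cbundle.to_tsv(artifacts["clusters_heatmap"])
            rep.render_clusters_heatmap(cbundle, out / "clusters_heatmap.png")
            ccoords, cdist = cl.mds_classical(cluster_mat.distance())
            artifacts["mds_clusters"] = out / "mds_clusters.tsv"
            rep.render_mds(ccoords, cluster_mat.ids, out / "mds_clusters.png",
                           point_sizes=sizes, twin_path=artifacts["mds_clusters"])
            log.record("mds", clusters_distortion=round(cdist, 6))

    # --- report -----------------------------------------------------------
    rep.write_html_report(
        out,
        {
            "Enriched GO terms per list": "gocount.png",
            "List overlaps (upset)": "upset.png",
            "Clustered -log10(p) heatmap with IC": "terms_heatmap.png",
            "MDS of GO terms": "mds_terms.png",
            "MDS of GO clusters": "mds_clusters.png",
            "Cluster sizes": "clusters_heatmap.png",
        },
    )
    artifacts["report"] = out / "report.html"
    log.record("report", artifacts=sorted(str(p.name) for p in artifacts.values()))
    artifacts["run_log"] = out / "run.json"
    log.write(artifacts["run_log"])
    return artifacts
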