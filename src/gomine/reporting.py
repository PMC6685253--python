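"""Data products and static images for the mined GO-term landscape.

Every plot (clustered -log10(p) heatmap with IC sidebar, enriched-term
barchart, upset overlap plot, MDS scatter, cluster-size heatmap) is written
twice: a machine-readable TSV/JSON twin that tests and downstream code read,
and a static SVG/PNG for humans.  Absent p-values (a term never tested in a
list) stay NA in the twin and blank in the image -- "not tested" is not the
same as "not enriched".
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .clustering import ClusterAssignment, Dendrogram
from .enrichment import EnrichmentTable, UpsetMemberships
from .ontology import OntologyDag
from .semsim import ICTable

logger = logging.getLogger(__name__)

_CLUSTER_CMAP = plt.get_cmap("tab20")


@dataclass
class HeatmapBundle:
    """Joined enrichment x clustering x IC structure behind the terms heatmap."""

    row_order: list[str]  # dendrogram leaf order
    row_labels: list[str]  # "GO:... name [cluster k]"
    matrix: pd.DataFrame  # -log10(p), rows=row_order, cols=lists, NaN=not tested
    ic: pd.Series  # IC per term, aligned to row_order
    clusters: pd.Series  # cluster label per term, aligned to row_order

    def cluster_boundaries(self) -> list[int]:
        """Row indices where the cluster label changes (for drawing separators)."""
        labels = self.clusters.to_numpy()
        return [i for i in range(1, len(labels)) if labels[i] != labels[i - 1]]

    def to_tsv(self, path) -> None:
        out = self.matrix.copy()
        out.insert(0, "cluster", self.clusters)
        out["IC"] = self.ic
        out.rename_axis("term_id").to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")


def build_terms_heatmap(
    table: EnrichmentTable,
    tree: Dendrogram,
    assignment: ClusterAssignment,
    ic: ICTable,
    dag: OntologyDag | None = None,
) -> HeatmapBundle:
    """Assemble the -log10(p) heatmap in dendrogram leaf order with IC sidebar."""
    order = tree.leaf_order()
    missing = set(order) - set(table.term_ids)
    if missing:
        raise ValueError(f"dendrogram leaves absent from the enrichment table: {sorted(missing)}")
    logp = -np.log10(table.p_matrix().reindex(order))
    ic_col = pd.Series({t: ic.ic.get(t, np.nan) for t in order}, name="IC")
    clusters = pd.Series({t: assignment.labels.get(t, 0) for t in order}, name="cluster")
    labels = [
        f"{t} {dag.terms[t].name if dag else table.data.at[t, 'name']} [cl{clusters[t]}]"
        for t in order
    ]
    return HeatmapBundle(
        row_order=order, row_labels=labels, matrix=logp, ic=ic_col, clusters=clusters
    )


def render_terms_heatmap(bundle: HeatmapBundle, path) -> None:
    n = len(bundle.row_order)
    fig, (ax, ax_ic) = plt.subplots(
        1, 2, figsize=(6 + 0.6 * len(bundle.matrix.columns), max(3.0, 0.22 * n)),
        width_ratios=[len(bundle.matrix.columns), 1], sharey=True,
    )
    im = ax.imshow(bundle.matrix.to_numpy(), aspect="auto", cmap="Reds")
    ax.set_xticks(range(len(bundle.matrix.columns)), bundle.matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(n), bundle.row_labels, fontsize=5)
    for b in bundle.cluster_boundaries():
        ax.axhline(b - 0.5, color="black", lw=0.6)
    fig.colorbar(im, ax=ax, label="-log10(p)", shrink=0.6)
    ax_ic.imshow(bundle.ic.to_numpy()[:, None], aspect="auto", cmap="Blues")
    ax_ic.set_xticks([0], ["IC"])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class ClustersHeatmapBundle:
    """Cluster-level view: one row per cluster, value = member term count."""

    row_order: list[str]  # cluster ids in cluster-dendrogram leaf order
    row_labels: list[str]  # "k: GO:... ancestor name"
    counts: pd.Series  # member count per cluster, aligned to row_order

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"label": self.row_labels, "n_terms": self.counts.to_numpy()},
            index=pd.Index(self.row_order, name="cluster"),
        ).to_csv(path, sep="\t")


def build_clusters_heatmap(
    assignment: ClusterAssignment,
    cluster_tree: Dendrogram,
    names: dict[int, str],
    dag: OntologyDag | None = None,
) -> ClustersHeatmapBundle:
    members = assignment.members()
    order = cluster_tree.leaf_order()
    labels, counts = [], []
    for cid in order:
        lbl = int(cid)
        anc = names.get(lbl, "")
        desc = dag.terms[anc].name if (dag and anc) else anc
        labels.append(f"{cid}: {anc} {desc}".strip())
        counts.append(len(members[lbl]))
    return ClustersHeatmapBundle(
        row_order=list(order),
        row_labels=labels,
        counts=pd.Series(counts, index=order, name="n_terms"),
    )


def render_clusters_heatmap(bundle: ClustersHeatmapBundle, path) -> None:
    n = len(bundle.row_order)
    fig, ax = plt.subplots(figsize=(4, max(2.0, 0.4 * n)))
    im = ax.imshow(bundle.counts.to_numpy()[:, None], aspect="auto", cmap="Purples")
    ax.set_yticks(range(n), bundle.row_labels, fontsize=7)
    ax.set_xticks([0], ["n GO terms"])
    for i, v in enumerate(bundle.counts):
        ax.text(0, i, str(int(v)), ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_barchart(counts: dict[str, int], path, twin_path=None) -> None:
    """Enriched GO term count per list; twin TSV written alongside."""
    if twin_path is not None:
        pd.Series(counts, name="n_enriched").rename_axis("list_id").to_csv(twin_path, sep="\t")
    fig, ax = plt.subplots(figsize=(1.2 * max(3, len(counts)), 3.2))
    ax.bar(list(counts), list(counts.values()), color="steelblue")
    ax.set_ylabel("enriched GO terms")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_upset(memberships: UpsetMemberships, path, twin_path=None) -> None:
    """Overlap of enriched-term lists as an upset-style plot with JSON twin."""
    if twin_path is not None:
        memberships.to_json(twin_path)
    patterns = sorted(memberships.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    lists = list(memberships.matrix.columns)
    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(max(3, 0.7 * len(patterns) + 2), 4),
        height_ratios=[2, 1], sharex=True,
    )
    xs = range(len(patterns))
    ax_bar.bar(xs, [c for _p, c in patterns], color="black")
    ax_bar.set_ylabel("terms")
    for x, (pattern, _c) in zip(xs, patterns):
        for y, lid in enumerate(lists):
            filled = lid in pattern
            ax_dot.plot(x, y, "o", color="black" if filled else "lightgray", ms=6)
    ax_dot.set_yticks(range(len(lists)), lists)
    ax_dot.set_xticks(list(xs))
    ax_dot.set_xticklabels(["&".join(p) for p, _c in patterns], rotation=60, ha="right", fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_mds(
    coords: np.ndarray,
    ids: list[str],
    path,
    point_sizes: dict[str, int] | None = None,
    twin_path=None,
) -> None:
    """2-D MDS scatter; dot area scales with cluster size when sizes are given."""
    df = pd.DataFrame(coords[:, :2], columns=["dim1", "dim2"], index=pd.Index(ids, name="id"))
    if point_sizes is not None:
        df["size"] = [point_sizes.get(i, 1) for i in ids]
    if twin_path is not None:
        df.to_csv(twin_path, sep="\t", float_format="%.10g")
    sizes = 30.0 * df["size"].to_numpy() if point_sizes is not None else 30.0
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(df["dim1"], df["dim2"], s=sizes, alpha=0.7, color="firebrick")
    for i, row in df.iterrows():
        ax.annotate(str(i), (row["dim1"], row["dim2"]), fontsize=6)
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunLog:
    """Structured per-stage record of parameters, input digests and counts."""

    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        entry = self.stages.setdefault(stage, {})
        for key, value in info.items():
            if isinstance(value, Path):
                value = str(value)
            entry[key] = value
        logger.info("run log / %s: %s", stage, info)

    def record_input(self, stage: str, name: str, path) -> None:
        self.record(stage, **{f"{name}_file": str(path), f"{name}_sha256": file_digest(path)})

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.stages, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def write_html_report(out_dir, images: dict[str, str], title: str = "GO mining report") -> Path:
    """Single self-contained HTML page embedding the rendered PNGs."""
    import base64

    out_dir = Path(out_dir)
    parts = [f"<html><head><title>{title}</title></head><body><h1>{title}</h1>"]
    for caption, img in images.items():
        img_path = out_dir / img
        if not img_path.exists():
            continue
        data = base64.b64encode(img_path.read_bytes()).decode("ascii")
        parts.append(f"<h2>{caption}</h2><img src='data:image/png;base64,{data}'/>")
    parts.append("</body></html>")
    path = out_dir / "report.html"
    path.write_text("\n".join(parts), encoding="utf-8")
    return path
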