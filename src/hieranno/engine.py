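"""The multiresolution annotation driver and the single-resolution baseline.

``run_multires`` descends the reference tree: all cells are embedded,
clustered and scored against the broadest cell types; the cells assigned to
each type are then re-embedded (variable genes re-chosen, PCA re-run) and
re-clustered on their own, so the effective clustering resolution rises
with annotation depth. Descent along a branch stops at a leaf or at the
first level whose winner fails the enrichment gate ("unassigned").

``run_uniform`` is the conventional baseline: one clustering at a fixed
resolution, each cluster scored once against every leaf type.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .annotate import (
    UNASSIGNED,
    cluster_profile,
    score_cluster,
    assign,
)
from .clustering import ClusterLabeling, knn_graph, louvain, snn_graph
from .config import RunConfig
from .matrix import CountMatrix, ExpressionMatrix
from .preprocess import normalize, qc_filter, subset_embedding
from .reference import CellTypeNode, ReferenceTree, compute_gene_weights, propagate_markers


class EngineError(ValueError):
    pass


def _prepare(counts: CountMatrix, tree: ReferenceTree, config: RunConfig):
    """Shared setup: QC, normalization, marker propagation, weights, overlap check."""
    tree.validate()
    propagate_markers(tree)
    weights = compute_gene_weights(tree, scope=config.weight_scope)
    qc_report = None
    if config.qc:
        counts, qc_report = qc_filter(
            counts,
            mito_prefix=config.mito_prefix,
            max_mito_frac=config.max_mito_frac,
            min_umi=config.min_umi,
            min_genes=config.min_genes,
            max_genes=config.max_genes,
        )
    if counts.n_cells == 0:
        raise EngineError("no cells left to annotate")
    expr = normalize(counts, scale_to=config.scale_to)
    universe = set(expr.gene_index())
    shared = len(tree.all_markers() & universe)
    if shared < config.min_shared_markers:
        warnings.warn(
            f"only {shared} reference markers are present in the expression "
            f"matrix; annotation is unlikely to be meaningful",
            stacklevel=3,
        )
    return counts, expr, weights, universe, qc_report


def _cluster_subset(
    expr: ExpressionMatrix, cell_index: np.ndarray, config: RunConfig
) -> ClusterLabeling:
    """Embed and Louvain-cluster one cell subset (k capped at subset - 1)."""
    embedding = subset_embedding(
        expr,
        cell_index,
        n_hvg=config.n_hvg,
        span=config.span,
        n_pcs=config.n_pcs,
        clip=config.clip,
        seed=config.seed,
    )
    knn = knn_graph(embedding, k=config.k)
    snn = snn_graph(knn, prune=config.prune)
    return louvain(
        snn, resolution=config.resolution, seed=config.seed, n_restarts=config.n_restarts
    )


def _single_cluster(n: int) -> ClusterLabeling:
    return ClusterLabeling(np.zeros(n, dtype=np.int64), resolution=0.0, seed=0, modularity=0.0)


class _Records:
    """Per-cell annotation state accumulated during the descent."""

    def __init__(self, barcodes: list[str], depth: int) -> None:
        self.barcodes = barcodes
        self.depth = depth
        n = len(barcodes)
        self.paths: list[list[str]] = [[] for _ in range(n)]
        self.status = np.array(["pending"] * n, dtype=object)
        self.cluster = np.full((n, depth), -1, dtype=np.int64)
        self.score = np.full((n, depth), np.nan)
        self.pvalue = np.full((n, depth), np.nan)

    def record_level(self, cells, level, cluster_id, label, score, pvalue) -> None:
        col = level - 1
        for i in cells:
            self.cluster[i, col] = cluster_id
            self.score[i, col] = score
            self.pvalue[i, col] = pvalue
            if label != UNASSIGNED:
                self.paths[i].append(label)

    def finish(self, cells, status: str) -> None:
        for i in cells:
            self.status[i] = status

    def to_frame(self) -> pd.DataFrame:
        data: dict = {"barcode": self.barcodes}
        for lvl in range(1, self.depth + 1):
            data[f"level{lvl}"] = [
                p[lvl - 1] if len(p) >= lvl else "" for p in self.paths
            ]
        data["final_label"] = [p[-1] if p else UNASSIGNED for p in self.paths]
        data["final_level"] = [len(p) for p in self.paths]
        data["status"] = list(self.status)
        for lvl in range(1, self.depth + 1):
            col = lvl - 1
            data[f"cluster_l{lvl}"] = self.cluster[:, col]
            data[f"AS_l{lvl}"] = self.score[:, col]
            data[f"p_l{lvl}"] = self.pvalue[:, col]
        return pd.DataFrame(data)


def run_multires(
    counts: CountMatrix,
    tree: ReferenceTree,
    config: RunConfig | None = None,
    collect_scores: list | None = None,
) -> pd.DataFrame:
    """Iterative cluster-and-annotate against a hierarchical reference.

    Returns one row per surviving cell: the assigned root-to-node path
    (``level1..levelK``), the final label and level, a status
    (``leaf-resolved`` or ``unassigned-at-level-L``), and per-level cluster
    ids with the winning candidate's activity score and enrichment p.
    ``collect_scores`` (optional list) receives every per-cluster candidate
    table for debugging/report export.
    """
    config = config or RunConfig()
    counts, expr, weights, universe, _ = _prepare(counts, tree, config)
    records = _Records(list(expr.barcodes), tree.depth)
    all_cells = np.arange(expr.n_cells)

    # frontier entries: (parent node, cell indices); root children are level 1
    frontier: list[tuple[CellTypeNode, np.ndarray]] = [(tree.root, all_cells)]
    while frontier:
        parent, cells = frontier.pop(0)
        children = parent.children
        level = parent.level + 1
        if not children:
            records.finish(cells, "leaf-resolved")
            continue
        first = parent.level == 0
        # one child needs no split to discriminate; tiny subsets are kept whole
        if len(children) > 1 and cells.size >= config.min_recluster_cells and cells.size > 1:
            labeling = _cluster_subset(expr, cells, config)
        else:
            labeling = _single_cluster(cells.size)
        mode = "average" if first else "z"
        r = config.r_first if first else config.r_deep
        profile = cluster_profile(expr.values[:, cells], labeling, mode=mode, genes=expr.genes)
        by_child: dict[str, list[np.ndarray]] = {}
        for cid in profile.cluster_ids:
            result = score_cluster(
                profile, cid, children, weights, r, universe, config.expressed_quantile
            )
            if collect_scores is not None:
                collect_scores.append((level, parent.name, result))
            label, best_as, best_p = assign(result, alpha=config.alpha)
            members = cells[labeling.members(cid)]
            records.record_level(members, level, cid, label, best_as, best_p)
            if label == UNASSIGNED:
                records.finish(members, f"unassigned-at-level-{level}")
            else:
                by_child.setdefault(label, []).append(members)
        # clusters mapped to the same child merge before the next round
        for child_name, groups in by_child.items():
            merged = np.concatenate(groups) if len(groups) > 1 else groups[0]
            merged.sort()
            frontier.append((tree.node(child_name), merged))
    return records.to_frame()


def run_uniform(
    counts: CountMatrix,
    tree: ReferenceTree,
    resolution: float | None = None,
    config: RunConfig | None = None,
    collect_scores: list | None = None,
) -> pd.DataFrame:
    """Single-resolution baseline: cluster once, score against all leaves.

    Each cluster is summarized in average mode and scored with r = 0.3
    against every leaf type of the reference in one step; the assigned
    cell's path is the full root-to-leaf path of the winner.
    """
    config = config or RunConfig()
    if resolution is None:
        resolution = config.resolution
    counts, expr, weights, universe, _ = _prepare(counts, tree, config)
    records = _Records(list(expr.barcodes), tree.depth)
    all_cells = np.arange(expr.n_cells)
    if all_cells.size > 1:
        sub_config = RunConfig(**{**config.to_dict(), "resolution": resolution})
        labeling = _cluster_subset(expr, all_cells, sub_config)
    else:
        labeling = _single_cluster(all_cells.size)
    profile = cluster_profile(expr, labeling, mode="average")
    leaves = tree.leaves()
    for cid in profile.cluster_ids:
        result = score_cluster(
            profile, cid, leaves, weights, config.r_deep, universe, config.expressed_quantile
        )
        if collect_scores is not None:
            collect_scores.append((1, "<uniform>", result))
        label, best_as, best_p = assign(result, alpha=config.alpha)
        members = all_cells[labeling.members(cid)]
        if label == UNASSIGNED:
            records.record_level(members, 1, cid, UNASSIGNED, best_as, best_p)
            records.finish(members, "unassigned-at-level-1")
        else:
            path = tree.node(label).path()
            for lvl, step in enumerate(path, start=1):
                records.record_level(
                    members, lvl, cid if lvl == 1 else -1, step, best_as, best_p
                )
            records.finish(members, "leaf-resolved")
    return records.to_frame()


def write_annotation(
    table: pd.DataFrame, path: str, config: RunConfig | None = None
) -> None:
    """Write the per-cell annotation TSV with the config echoed as a header."""
    with open(path, "w") as fh:
        if config is not None:
            for line in config.header_lines():
                fh.write(line + "\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_score_report(collected: list, path: str) -> None:
    """Per-cluster candidate tables (level, parent, candidate, AS, p) as TSV."""
    rows = []
    for level, parent, result in collected:
        for name, as_, p, n in zip(
            result.names, result.scores, result.pvalues, result.n_markers
        ):
            rows.append((level, parent, result.cluster_id, name, n, result.r, as_, p))
    pd.DataFrame(
        rows,
        columns=["level", "parent", "cluster", "candidate", "n_markers", "r", "AS", "p"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
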