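"""Cluster-level scoring of candidate cell types.

A cluster is summarized either by the average normalized log expression of
its cells ("average" mode, used at the first, broadest level) or by that
average z-transformed per gene across the clusters of the current round
("z" mode, used at deeper levels where sibling types share most of their
transcriptome and only relative differences discriminate).

Each candidate type t with markers (t_1..t_N) receives an activity score

    AS(c, t) = sum_i Exp(t_i, c) * w(t_i) / N**r

where w is the reference-frequency weight and r compresses the dependence
on marker-set size (r = 0.6 at the first level, 0.3 deeper). Markers absent
from the expression matrix contribute 0 to the sum but still count in N.
The winner is the candidate with the highest score, accepted only if a
one-sided Fisher's exact test finds its markers enriched among the
cluster's "expressed" genes at p < alpha; otherwise the cluster is left
unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .clustering import ClusterLabeling
from .matrix import ExpressionMatrix
from .reference import CellTypeNode, GeneWeightTable

UNASSIGNED = "unassigned"


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotationConfig:
    r_first: float = 0.6
    r_deep: float = 0.3
    alpha: float = 0.05
    # fraction of the gene universe a cluster summary must exceed to count
    # as "expressed" in the Fisher gate
    expressed_quantile: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ClusterProfile:
    """Per-(gene, cluster) summary expression; mode is 'average' or 'z'.

    ``values`` holds the scoring summary (means, or their per-gene
    z-transform across clusters in z mode); ``means`` always holds the raw
    per-cluster mean expression, which the enrichment gate uses to decide
    which genes a cluster "expresses" independently of the scoring mode.
    """

    values: np.ndarray  # (n_genes, n_clusters)
    genes: list[str]
    mode: str
    cluster_ids: list[int]
    means: np.ndarray = None
    _gene_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.means is None:
            self.means = self.values

    @property
    def n_clusters(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict:
        if self._gene_index is None:
            idx: dict = {}
            for i, g in enumerate(self.genes):
                idx.setdefault(g.upper(), i)
            self._gene_index = idx
        return self._gene_index

    def column(self, cluster_id: int) -> np.ndarray:
        return self.values[:, self.cluster_ids.index(cluster_id)]


@dataclass
class ActivityScoreResult:
    """Scores of every candidate type for one cluster."""

    cluster_id: int
    names: list[str]
    scores: np.ndarray
    pvalues: np.ndarray
    n_markers: np.ndarray
    r: float


def cluster_profile(
    expr: ExpressionMatrix | np.ndarray,
    labeling: ClusterLabeling | np.ndarray,
    mode: str = "average",
    genes: list[str] | None = None,
) -> ClusterProfile:
    """Mean expression per cluster, optionally z-transformed across clusters.

    The z-transform is per gene across the cluster means of the current
    round (population sd, clusters weighted equally); genes constant across
    clusters map to 0. With a single cluster the z-transform is undefined
    and the profile falls back to average mode.
    """
    if isinstance(expr, ExpressionMatrix):
        values, genes = expr.values, expr.genes
    else:
        values = np.asarray(expr)
        if genes is None:
            raise ValueError("gene symbols required with a bare array")
    labels = labeling.labels if isinstance(labeling, ClusterLabeling) else np.asarray(labeling)
    if labels.shape[0] != values.shape[1]:
        raise AnnotationError("labeling does not cover the expression columns")
    cluster_ids = sorted(int(c) for c in np.unique(labels))
    cols = []
    for cid in cluster_ids:
        members = np.flatnonzero(labels == cid)
        if members.size == 0:
            raise AnnotationError(f"cluster {cid} is empty")
        cols.append(values[:, members].mean(axis=1))
    means = np.column_stack(cols)
    if mode == "z" and len(cluster_ids) > 1:
        mu = means.mean(axis=1, keepdims=True)
        sd = means.std(axis=1, keepdims=True)
        profile = np.where(sd > 0, (means - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        out_mode = "z"
    elif mode in ("z", "average"):
        profile = means
        out_mode = "average"
    else:
        raise ValueError(f"unknown profile mode {mode!r}")
    return ClusterProfile(
        values=profile, genes=list(genes), mode=out_mode, cluster_ids=cluster_ids, means=means
    )


def activity_score(
    profile_column: np.ndarray,
    node: CellTypeNode,
    weights: GeneWeightTable,
    r: float,
    gene_index: dict,
) -> float:
    """Weighted marker activity of one cluster for one candidate type.

    ``profile_column`` is the cluster's summary over all genes;
    ``gene_index`` maps upper-cased symbols to rows. N counts every marker
    of the node, including those the dataset does not measure.
    """
    markers = sorted(node.markers)
    n = len(markers)
    if n == 0:
        raise AnnotationError(f"candidate {node.name!r} has no markers")
    total = 0.0
    for g in markers:
        row = gene_index.get(g)
        if row is not None:
            total += float(profile_column[row]) * weights.weight(g)
    return total / n**r


def expressed_genes(
    profile_column: np.ndarray, genes: list[str], quantile: float = 0.5
) -> set:
    """Genes whose cluster summary strictly exceeds the given quantile.

    Upper-cased symbols are returned. The quantile cut is scale-free, so it
    behaves identically for average profiles (all positive) and z profiles
    (centered), and stays informative for a single cluster.
    """
    cut = float(np.quantile(profile_column, quantile))
    return {genes[i].upper() for i in np.flatnonzero(profile_column > cut)}


def fisher_gate(
    cluster_expressed: set, node: CellTypeNode, universe: set
) -> float:
    """One-sided (enrichment) Fisher's exact test p-value.

    The 2x2 table crosses membership in the cluster's expressed set with
    membership in the candidate's marker set over the measured gene
    universe; the p-value is the upper hypergeometric tail at the observed
    overlap, which is exactly the one-sided Fisher p for the table.
    """
    if not universe:
        raise AnnotationError("empty gene universe")
    markers = node.markers & universe
    expressed = cluster_expressed & universe
    M = len(universe)
    K = len(markers)
    n = len(expressed)
    a = len(expressed & markers)
    return float(hypergeom.sf(a - 1, M, K, n))


def assign(result: ActivityScoreResult, alpha: float = 0.05) -> tuple[str, float, float]:
    """Pick the candidate with the highest activity score, gated by its p.

    Ties on the score break toward the smaller p-value, then the
    lexicographically smaller name. Returns (name, AS, p); the name is
    ``"unassigned"`` when the winner's p >= alpha, with the winner's score
    and p still reported for diagnostics.
    """
    if not result.names:
        raise AnnotationError("no candidates to assign")
    order = sorted(
        range(len(result.names)),
        key=lambda i: (-result.scores[i], result.pvalues[i], result.names[i]),
    )
    best = order[0]
    name = result.names[best]
    score, p = float(result.scores[best]), float(result.pvalues[best])
    if p < alpha:
        return name, score, p
    return UNASSIGNED, score, p


def score_cluster(
    profile: ClusterProfile,
    cluster_id: int,
    candidates: list[CellTypeNode],
    weights: GeneWeightTable,
    r: float,
    universe: set,
    expressed_quantile: float = 0.5,
) -> ActivityScoreResult:
    """Activity scores and enrichment p-values of all candidates for one cluster."""
    col = profile.cluster_ids.index(cluster_id)
    column = profile.values[:, col]
    gene_index = profile.gene_index()
    # the gate always works on mean expression: "highly expressed in this
    # cluster" is a property of the cluster, not of the scoring transform
    expressed = expressed_genes(profile.means[:, col], profile.genes, expressed_quantile)
    names, scores, pvals, sizes = [], [], [], []
    for node in candidates:
        names.append(node.name)
        scores.append(activity_score(column, node, weights, r, gene_index))
        pvals.append(fisher_gate(expressed, node, universe))
        sizes.append(len(node.markers))
    return ActivityScoreResult(
        cluster_id=cluster_id,
        names=names,
        scores=np.asarray(scores, dtype=float),
        pvalues=np.asarray(pvals, dtype=float),
        n_markers=np.asarray(sizes, dtype=int),
        r=r,
    )
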