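"""Hierarchical marker references.

A reference is a rooted tree of cell types from broad (level 1) to specific
(leaves). Each node carries a set of marker-gene symbols; after propagation
an intermediate node's effective marker set is its own markers united with
every descendant's markers, so broad types aggregate all the evidence of
their subtypes.

Marker specificity is encoded as a per-gene weight

    w(g) = 1 + sqrt((max(f) - f(g)) / (max(f) - min(f)))

where f(g) counts how many leaf cell types list gene g. A marker shared by
every leaf gets w = 1; a marker private to the rarest frequency class gets
w = 2, so common markers are down-weighted when scoring candidate types.

File dialect: UTF-8 TSV with header columns ``path`` and ``gene``; ``path``
is the root-to-node label sequence joined by ``|`` (for example
``Hematopoietic cell|T|T helper cell``), one row per (node, gene). A wide
dialect with columns ``level1..levelK, gene`` is converted on the fly.
Gene symbols are matched case-insensitively and stored upper-cased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd


class ReferenceError(ValueError):
    """Structural or validation failure in a marker reference."""


@dataclass
class CellTypeNode:
    name: str
    level: int
    parent: "CellTypeNode | None" = None
    children: list = field(default_factory=list)
    own_markers: set = field(default_factory=set)
    markers: set = field(default_factory=set)

    def is_leaf(self) -> bool:
        return not self.children

    def path(self) -> list[str]:
        """Root-to-node label sequence (excluding the virtual root)."""
        labels: list[str] = []
        node: CellTypeNode | None = self
        while node is not None and node.level > 0:
            labels.append(node.name)
            node = node.parent
        return labels[::-1]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CellTypeNode({self.name!r}, level={self.level}, markers={len(self.markers)})"


class ReferenceTree:
    """Rooted cell-type tree with a virtual, marker-free root at level 0."""

    def __init__(self, species: str = "") -> None:
        self.root = CellTypeNode("<root>", 0)
        self.species = species
        self._by_name: dict[str, CellTypeNode] = {}

    # -- construction -------------------------------------------------

    def add_path(self, path: list[str], genes: set[str] | None = None) -> CellTypeNode:
        """Insert (or extend) a root-to-node path; return the final node."""
        if not path:
            raise ReferenceError("empty cell-type path")
        parent = self.root
        for depth, label in enumerate(path, start=1):
            node = self._by_name.get(label)
            if node is None:
                node = CellTypeNode(label, depth, parent=parent)
                parent.children.append(node)
                self._by_name[label] = node
            else:
                if node.parent is not parent or node.level != depth:
                    raise ReferenceError(
                        f"cell type {label!r} appears under two distinct parents "
                        f"({node.parent.name!r} and {parent.name!r})"
                    )
            parent = node
        if genes:
            parent.own_markers.update(g.strip().upper() for g in genes if g.strip())
        return parent

    # -- access -------------------------------------------------------

    def node(self, name: str) -> CellTypeNode:
        try:
            return self._by_name[name]
        except KeyError:
            raise ReferenceError(f"unknown cell type {name!r}") from None

    def nodes(self) -> list[CellTypeNode]:
        out: list[CellTypeNode] = []
        stack = list(self.root.children)[::-1]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children[::-1])
        return out

    def leaves(self) -> list[CellTypeNode]:
        return [n for n in self.nodes() if n.is_leaf()]

    @property
    def depth(self) -> int:
        return max((n.level for n in self.nodes()), default=0)

    def all_markers(self) -> set[str]:
        markers: set[str] = set()
        for node in self.nodes():
            markers |= node.own_markers
        return markers

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        if not self.root.children:
            raise ReferenceError("reference has no cell types")
        for node in self.nodes():
            if node.level != node.parent.level + 1:
                raise ReferenceError(f"level mismatch at {node.name!r}")
            if node.is_leaf() and not node.own_markers:
                raise ReferenceError(f"leaf cell type {node.name!r} has no marker genes")


@dataclass
class GeneWeightTable:
    """Per-gene leaf frequency f and specificity weight w in [1, 2]."""

    f: dict[str, int]
    w: dict[str, float]
    max_f: int
    min_f: int

    def weight(self, gene: str, default: float = 1.0) -> float:
        return self.w.get(gene.upper(), default)


def parse_reference(path: str, species: str = "") -> ReferenceTree:
    """Parse a long-format (``path``, ``gene``) TSV into a validated tree.

    A wide dialect with columns ``level1..levelK, gene`` is accepted and
    converted; blank trailing levels shorten the path. The returned tree is
    already marker-propagated.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except OSError as exc:
        raise OSError(f"cannot read reference file {path!r}: {exc}") from exc
    except pd.errors.EmptyDataError:
        raise ReferenceError(f"reference file {path!r} is empty") from None
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "gene" not in cols:
        raise ReferenceError(f"{path!r}: reference needs a 'gene' column")
    if "path" in cols:
        paths = df["path"].fillna("").map(lambda s: [p.strip() for p in s.split("|") if p.strip()])
    else:
        level_cols = sorted(
            (c for c in cols if c.startswith("level") and c[5:].isdigit()),
            key=lambda c: int(c[5:]),
        )
        if not level_cols:
            raise ReferenceError(
                f"{path!r}: expected a 'path' column or wide 'level1..levelK' columns"
            )
        paths = df[level_cols].apply(
            lambda row: [str(v).strip() for v in row if isinstance(v, str) and str(v).strip()],
            axis=1,
        )
    tree = ReferenceTree(species=species)
    for node_path, gene in zip(paths, df["gene"].fillna("")):
        if not node_path:
            raise ReferenceError(f"{path!r}: row with empty cell-type path")
        tree.add_path(node_path, {gene} if gene.strip() else None)
    tree.validate()
    propagate_markers(tree)
    return tree


def propagate_markers(tree: ReferenceTree) -> ReferenceTree:
    """Set every node's effective markers to own ∪ descendants'. Idempotent."""

    def visit(node: CellTypeNode) -> set[str]:
        acc = set(node.own_markers)
        for child in node.children:
            acc |= visit(child)
        node.markers = acc
        return acc

    for child in tree.root.children:
        visit(child)
    tree.root.markers = set()
    return tree


def compute_gene_weights(tree: ReferenceTree, scope: str = "leaves") -> GeneWeightTable:
    """Marker frequencies and weights over the reference.

    ``scope='leaves'`` (default) counts, for each gene, the number of leaf
    cell types listing it — propagated intermediate sets would otherwise
    count the same leaf marker once per ancestor. ``scope='nodes'`` counts
    membership in every node's effective set instead.
    """
    if scope == "leaves":
        groups = [leaf.markers for leaf in tree.leaves()]
    elif scope == "nodes":
        groups = [node.markers for node in tree.nodes()]
    else:
        raise ValueError(f"unknown frequency scope {scope!r}")
    if not groups:
        raise ReferenceError("reference has no cell types")
    f: dict[str, int] = {g: 0 for g in tree.all_markers()}
    for markers in groups:
        for g in markers:
            f[g] = f.get(g, 0) + 1
    max_f, min_f = max(f.values()), min(f.values())
    if max_f == min_f:
        # 0/0 in the weight formula: equal frequency carries no ranking signal
        w = {g: 1.0 for g in f}
    else:
        span = max_f - min_f
        w = {g: 1.0 + math.sqrt((max_f - fg) / span) for g, fg in f.items()}
    return GeneWeightTable(f=f, w=w, max_f=max_f, min_f=min_f)


def write_reference(tree: ReferenceTree, path: str) -> None:
    """Write the long (path, gene) TSV dialect, one row per (node, gene)."""
    rows = []
    for node in tree.nodes():
        label = "|".join(node.path())
        for gene in sorted(node.own_markers):
            rows.append((label, gene))
        if not node.own_markers and not node.children:
            rows.append((label, ""))
    pd.DataFrame(rows, columns=["path", "gene"]).to_csv(path, sep="\t", index=False)
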