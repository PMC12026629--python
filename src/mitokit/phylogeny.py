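"""Supermatrix construction, p-distances, neighbor joining, and clade queries.

A desk-scale distance pipeline for concatenated protein-coding gene
alignments: build a partitioned supermatrix from per-gene alignments,
compute pairwise p-distances with pairwise gap deletion (optionally
Poisson-corrected), infer an unrooted tree by the Saitou-Nei
neighbor-joining algorithm, root it on an outgroup, and test monophyly of
taxon sets.  Newick import lets the same clade queries run on trees
computed elsewhere (e.g. Bayesian or maximum-likelihood trees).
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Supermatrix",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "concat_supermatrix",
    "p_distance_matrix",
    "neighbor_joining",
    "root_with_outgroup",
    "is_monophyletic",
    "read_newick",
    "write_newick",
    "NewickParseError",
]

GAP_CHARS = frozenset("-?")


@dataclass
class Supermatrix:
    """Concatenated alignment with per-gene partition spans (1-based)."""

    taxa: list[str]
    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def concat_supermatrix(
    per_gene_alignments: dict[str, dict[str, str]]
) -> Supermatrix:
    """Concatenate per-gene alignments over the union of taxa.

    Within each gene all sequences must have equal length.  A taxon absent
    from a gene is gap-filled for that partition (logged).  Taxa are
    ordered by first appearance across genes.
    """
    taxa: list[str] = []
    for aln in per_gene_alignments.values():
        for t in aln:
            if t not in taxa:
                taxa.append(t)
    parts: dict[str, tuple[int, int]] = {}
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    col = 0
    for gene, aln in per_gene_alignments.items():
        lengths = {len(s) for s in aln.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"gene {gene}: ragged alignment (lengths {sorted(lengths)})"
            )
        glen = lengths.pop() if lengths else 0
        parts[gene] = (col + 1, col + glen)
        col += glen
        for t in taxa:
            if t in aln:
                chunks[t].append(aln[t].upper())
            else:
                logger.warning("taxon %s missing from gene %s: gap-filled", t, gene)
                chunks[t].append("-" * glen)
    return Supermatrix(
        taxa=taxa, rows={t: "".join(chunks[t]) for t in taxa}, partitions=parts
    )


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxon list")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if (m < -1e-12).any():
            raise ValueError("negative distances")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])

    def to_tsv(self) -> str:
        out = ["\t" + "\t".join(self.taxa)]
        for i, t in enumerate(self.taxa):
            out.append(t + "\t" + "\t".join(f"{x:.6g}" for x in self.matrix[i]))
        return "\n".join(out) + "\n"


def p_distance_matrix(
    sm: Supermatrix, poisson_correction: bool = False
) -> DistanceMatrix:
    """Pairwise p-distances (mismatches / compared columns).

    Only columns where both rows are non-gap are compared (pairwise
    deletion), so gap-filled missing-gene partitions never contribute.
    With ``poisson_correction`` the multiple-hit corrected distance
    ``-ln(1 - p)`` is returned instead.
    """
    if len(sm.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    n = len(sm.taxa)
    arrays = {
        t: np.frombuffer(sm.rows[t].encode(), dtype="S1") for t in sm.taxa
    }
    gap = {t: np.isin(arrays[t], [b"-", b"?"]) for t in sm.taxa}
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = sm.taxa[i], sm.taxa[j]
            ok = ~(gap[ti] | gap[tj])
            n_ok = int(ok.sum())
            if n_ok == 0:
                raise ValueError(
                    f"no comparable columns between {ti} and {tj}"
                )
            p = float((arrays[ti][ok] != arrays[tj][ok]).mean())
            if poisson_correction:
                if p >= 1.0:
                    raise ValueError(
                        f"p-distance 1.0 between {ti} and {tj}: "
                        "Poisson correction undefined"
                    )
                p = -math.log(1.0 - p)
            m[i, j] = m[j, i] = p
    return DistanceMatrix(taxa=list(sm.taxa), matrix=m)


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: Optional[float] = None  # branch length to the parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class PhyloTree:
    root: TreeNode
    rooted: bool = False

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()


# ---------------------------------------------------------------- Newick I/O


class NewickParseError(ValueError):
    pass


def write_newick(tree: PhyloTree) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            s = node.name or ""
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                s += node.name
        if node.length is not None:
            s += f":{node.length:.10g}"
        return s

    return fmt(tree.root) + ";"


def read_newick(text: str, rooted: Optional[bool] = None) -> PhyloTree:
    """Parse a Newick string (delegating to dendropy).

    A tree whose root has two children is treated as rooted unless
    ``rooted`` overrides it.
    """
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at position {pos}"
                )
    if depth != 0:
        raise NewickParseError(f"{depth} unclosed '(' in newick string")
    import dendropy

    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as e:  # dendropy raises assorted error types
        raise NewickParseError(f"newick parse error: {e}") from e

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            name=dnode.taxon.label
            if dnode.taxon is not None
            else (dnode.label or None),
            length=dnode.edge.length,
        )
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dt.seed_node)
    if rooted is None:
        rooted = len(root.children) == 2
    return PhyloTree(root=root, rooted=rooted)


# ------------------------------------------------------------------ NJ


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Agglomerates by the Q-criterion, breaking ties by the smallest
    ``(i, j)`` index pair; negative branch-length estimates are clamped to
    zero with the deficit logged.  On an additive matrix the generating
    topology and branch lengths are recovered exactly.  The result is
    unrooted, represented with a trifurcating root.
    """
    n = len(d.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=t) for t in d.taxa]
    dist = d.matrix.astype(float).copy()
    active = list(range(n))

    def clamp(x: float, where: str) -> float:
        if x < 0:
            logger.info("negative branch length %.6g at %s clamped to 0", x, where)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = dist[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        ni, nj = nodes[i], nodes[j]
        ni.length = clamp(li, f"join({ni.name or 'internal'})")
        nj.length = clamp(lj, f"join({nj.name or 'internal'})")
        parent.children = [ni, nj]
        # distances from the new node to every other active node
        new_row = np.zeros(dist.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (dist[i, k] + dist[j, k] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_row[:-1]
        dist[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # resolve the final three nodes around a trifurcating root
    i, j, k = active
    li = 0.5 * (dist[i, j] + dist[i, k] - dist[j, k])
    lj = 0.5 * (dist[i, j] + dist[j, k] - dist[i, k])
    lk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
    root = TreeNode()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = clamp(ln, "final-join")
        root.children.append(nodes[idx])
    return PhyloTree(root=root, rooted=False)


# ------------------------------------------------------------- rooting


def root_with_outgroup(t: PhyloTree, outgroup: str) -> PhyloTree:
    """Root a tree on the midpoint of the outgroup's pendant edge."""
    if outgroup not in t.leaf_names():
        raise KeyError(f"unknown taxon {outgroup!r}")

    # build parent pointers on a deep copy
    import copy

    tree = copy.deepcopy(t)
    parent: dict[int, TreeNode] = {}
    for node in tree.root.walk():
        for c in node.children:
            parent[id(c)] = node
    leaf = next(l for l in tree.root.leaves() if l.name == outgroup)
    pend = leaf.length if leaf.length is not None else 0.0
    old_parent = parent.get(id(leaf))
    if old_parent is None:  # tree is just the outgroup leaf
        raise ValueError("cannot root a single-leaf tree")

    # reverse the path old_parent -> ... -> old root, re-hanging subtrees
    path = [old_parent]
    while id(path[-1]) in parent:
        path.append(parent[id(path[-1])])
    old_parent.children = [c for c in old_parent.children if c is not leaf]
    for child, par in zip(path, path[1:]):
        par.children = [c for c in par.children if c is not child]
        edge = child.length
        child.children.append(par)
        par.length = edge
    # a trifurcating old root that lost a child may become a pass-through
    # node of degree 2; splice it out to keep the topology clean
    def splice(node: TreeNode):
        for idx, c in enumerate(list(node.children)):
            splice(c)
            if not c.is_leaf and len(c.children) == 1:
                only = c.children[0]
                only.length = (only.length or 0.0) + (c.length or 0.0)
                node.children[idx] = only

    leaf.length = pend / 2.0
    old_parent.length = pend / 2.0
    new_root = TreeNode(children=[leaf, old_parent])
    splice(new_root)
    return PhyloTree(root=new_root, rooted=True)


def is_monophyletic(t: PhyloTree, taxa) -> bool:
    """True iff some node's leaf-descendant set equals ``taxa`` exactly."""
    query = frozenset(taxa)
    all_leaves = t.leaf_names()
    unknown = query - all_leaves
    if unknown:
        raise KeyError(f"unknown taxa: {sorted(unknown)}")
    return any(node.leaf_names() == query for node in t.root.walk())
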