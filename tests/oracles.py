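"""Independent oracles used by the test suite.

Everything here is deliberately written from scratch, without reusing the
package's own search/recursion code paths, so agreement between the two is
meaningful.
"""

from __future__ import annotations

import numpy as np

from mitokit.phylogeny import DistanceMatrix, PhyloTree, TreeNode
from mitokit.trna_structure import FoldingConfig

# ---------------------------------------------------------------- folding

_PAIR_SCORE = {
    ("A", "U"): 2, ("U", "A"): 2, ("G", "C"): 2, ("C", "G"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
    ("C", "C"): 0, ("U", "U"): 0,
    ("C", "A"): 0, ("A", "C"): 0,
    ("U", "C"): 0, ("C", "U"): 0,
}


def brute_force_best(seq: str, cfg: FoldingConfig, anticodon: str | None = None):
    """Exhaustively score every admissible cloverleaf segmentation.

    Returns the best (score, n_wc, unpaired, d_start) ordering key, or None
    when no segmentation fits.  Written with explicit cursor arithmetic,
    independent of the package's placement generator.
    """
    rna = seq.upper().replace("T", "U")
    L = len(rna)
    best_key = None
    for a in range(cfg.linker1_range[0], cfg.linker1_range[1] + 1):
        d_choices = [(0, k) for k in range(cfg.d_absent_linker_range[0],
                                           cfg.d_absent_linker_range[1] + 1)]
        d_choices += [
            (d, dl)
            for d in range(cfg.d_stem_range[0], cfg.d_stem_range[1] + 1)
            for dl in range(cfg.d_loop_range[0], cfg.d_loop_range[1] + 1)
        ]
        for d, dl in d_choices:
            for b in range(cfg.linker2_range[0], cfg.linker2_range[1] + 1):
                for t in range(cfg.t_stem_range[0], cfg.t_stem_range[1] + 1):
                    for tl in range(cfg.t_loop_range[0], cfg.t_loop_range[1] + 1):
                        v = (L - 14 - a - 2 * d - dl - b - 17
                             - 2 * t - tl)
                        if not (cfg.variable_range[0] <= v <= cfg.variable_range[1]):
                            continue
                        pairs = []
                        for k in range(7):  # acceptor stem
                            pairs.append((k, L - 1 - k))
                        cur = 7 + a
                        d_start = L + 1
                        if d:
                            d_start = cur + 1  # 1-based
                            for k in range(d):
                                pairs.append((cur + k, cur + 2 * d + dl - 1 - k))
                            cur += 2 * d + dl
                        else:
                            cur += dl
                        cur += b
                        ac_loop = rna[cur + 5 : cur + 12]
                        if anticodon is not None:
                            if anticodon.upper().replace("T", "U") not in ac_loop:
                                cur += 17 + v
                                # still need cursor for T-arm below, but this
                                # placement is rejected
                                continue
                        for k in range(5):
                            pairs.append((cur + k, cur + 16 - k))
                        cur += 17 + v
                        for k in range(t):
                            pairs.append((cur + k, cur + 2 * t + tl - 1 - k))
                        score = sum(
                            _PAIR_SCORE.get((rna[i], rna[j]), -1) for i, j in pairs
                        )
                        n_wc = sum(
                            1
                            for i, j in pairs
                            if _PAIR_SCORE.get((rna[i], rna[j])) == 2
                        )
                        key = (-score, -n_wc, L - 2 * len(pairs), d_start)
                        if best_key is None or key < best_key:
                            best_key = key
    return best_key


# ------------------------------------------------------------- phylogenies


def random_binary_tree(rng: np.random.Generator, n_leaves: int,
                       min_len: float = 0.1, max_len: float = 1.0) -> PhyloTree:
    """Random rooted binary tree with positive branch lengths."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(min_len, max_len))
        b.length = float(rng.uniform(min_len, max_len))
        parent = TreeNode(children=[a, b])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    for x in nodes:
        x.length = float(rng.uniform(min_len, max_len))
    return PhyloTree(root=TreeNode(children=nodes), rooted=True)


def path_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix by explicit root-path comparison."""
    paths = {}

    def walk(node, acc):
        acc = acc + [(id(node), node.length or 0.0)]
        if node.is_leaf:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, [])
    taxa = sorted(paths)
    m = np.zeros((len(taxa), len(taxa)))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if i >= j:
                continue
            pi = {nid for nid, _ in paths[ti]}
            pj = {nid for nid, _ in paths[tj]}
            d = sum(l for nid, l in paths[ti] if nid not in pj)
            d += sum(l for nid, l in paths[tj] if nid not in pi)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(taxa=taxa, matrix=m)


def unrooted_splits(tree: PhyloTree) -> set[frozenset]:
    """Non-trivial bipartitions of the leaf set, orientation-free."""
    all_leaves = tree.leaf_names()
    splits = set()
    for node in tree.root.walk():
        side = node.leaf_names()
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(frozenset({side, all_leaves - side}))
    return splits
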