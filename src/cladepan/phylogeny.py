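"""Distance-based species tree from single-copy core families.

A deterministic stand-in for maximum-likelihood phylogenomics: extract
families present exactly once in every genome, compute pairwise
p-distances (1 − length-weighted mean identity of globally aligned family
sequences), build a neighbor-joining tree with fixed tie-breaking, and
root it on the outgroup's pendant edge. p-distance is monotone in
divergence at the ranges simulated and parameter-free, which is all the
gain/loss stage needs from the tree.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .alignment import global_identity
from .pangenome import OrthogroupMatrix
from .tree import Node, PhyloTree

logger = logging.getLogger(__name__)


def single_copy_core(matrix: OrthogroupMatrix, genome_subset: list[str] | None = None) -> list[str]:
    """Families with occurrence count exactly 1 in every genome of the subset."""
    subset = genome_subset if genome_subset is not None else matrix.genomes
    counts = matrix.counts[subset]
    families = sorted(counts.index[(counts == 1).all(axis=1)])
    if not families:
        raise ValueError(
            "no single-copy core families in the subset; try a smaller genome subset"
        )
    return families


def family_distance_matrix(
    families: list[str], sequences: dict[str, dict[str, str]]
) -> pd.DataFrame:
    """Pairwise p-distance = 1 − length-weighted mean identity per family.

    ``sequences`` maps genome → family → sequence; every (family, genome)
    must be present. These are raw p-distances, so occasional triangle
    inequality violations are tolerated (and logged at debug level).
    """
    genomes = sorted(sequences)
    for g in genomes:
        missing = [f for f in families if f not in sequences[g]]
        if missing:
            raise ValueError(f"genome {g} missing sequences for {missing[:3]}...")
    dist = pd.DataFrame(0.0, index=genomes, columns=genomes)
    for a, b in itertools.combinations(genomes, 2):
        matches = 0
        columns = 0
        for fam in families:
            ident, cols = global_identity(sequences[a][fam], sequences[b][fam])
            matches += ident * cols
            columns += cols
        d = 1.0 - matches / columns
        dist.loc[a, b] = dist.loc[b, a] = d
    return dist


def neighbor_joining(dist: pd.DataFrame) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q-criterion resolve to the lexicographically smallest
    (name, name) pair; negative branch lengths are clamped to zero with
    the deficit shifted to the sister branch.
    """
    names = list(dist.index)
    if len(names) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    matrix = dist.to_numpy(dtype=float).copy()
    nodes: list[Node] = [Node(n) for n in names]
    labels = names[:]  # label of each active row (for tie-breaks)

    while len(nodes) > 3:
        m = len(nodes)
        r = matrix.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * matrix[i, j] - r[i] - r[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = matrix[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = matrix[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = Node()
        nodes[i].length = li
        nodes[j].length = max(lj, 0.0)
        new.add(nodes[i])
        new.add(nodes[j])
        d_new = 0.5 * (matrix[i] + matrix[j] - matrix[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        matrix = np.vstack([matrix[keep][:, keep], d_new[keep]])
        matrix = np.column_stack([matrix, np.append(d_new[keep], 0.0)])
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # closed-form star for the final three lineages
    (a, b, c) = nodes
    dab, dac, dbc = matrix[0, 1], matrix[0, 2], matrix[1, 2]
    root = Node()
    a.length = max((dab + dac - dbc) / 2, 0.0)
    b.length = max((dab + dbc - dac) / 2, 0.0)
    c.length = max((dac + dbc - dab) / 2, 0.0)
    for n in (a, b, c):
        root.add(n)
    tree = PhyloTree(root, rooted=False)
    tree.label_internals()
    return tree


def root_with_outgroup(tree: PhyloTree, outgroup_id: str) -> PhyloTree:
    """Root on the midpoint of the outgroup's pendant edge.

    Internal nodes are relabelled N1..Nk in preorder of the rooted tree;
    a former degree-2 root left over from re-orientation is spliced out.
    """
    leaf = tree.find(outgroup_id)
    if leaf is None or not leaf.is_leaf:
        raise ValueError(f"outgroup {outgroup_id!r} is not a leaf of the tree")

    # undirected adjacency with edge lengths
    adj: dict[int, list[tuple[Node, float]]] = {}
    registry: dict[int, Node] = {}

    def link(u: Node, v: Node, length: float) -> None:
        adj.setdefault(id(u), []).append((v, length))
        adj.setdefault(id(v), []).append((u, length))
        registry[id(u)] = u
        registry[id(v)] = v

    for parent, child in tree.branches():
        if child is leaf:
            continue
        link(parent, child, child.length or 0.0)
    pendant = leaf.length or 0.0
    new_root = Node()
    link(leaf.parent, new_root, pendant / 2)
    link(new_root, leaf, pendant / 2)

    def build(node: Node, prev: Node | None, length: float | None) -> Node:
        neighbours = [(nb, l) for nb, l in adj[id(node)] if nb is not prev]
        is_leaf = not neighbours
        out = Node(node.name if is_leaf else "", length)
        for nb, l in neighbours:
            out.add(build(nb, node, l))
        return out

    root = build(new_root, None, None)

    # splice out degree-2 passthrough nodes (the old unrooted attachment)
    def splice(node: Node) -> None:
        for child in list(node.children):
            splice(child)
        if len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            idx = node.parent.children.index(node)
            node.parent.children[idx] = child
            child.parent = node.parent

    splice(root)
    rooted = PhyloTree(root, rooted=True)
    rooted.label_internals()
    return rooted


def _bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    splits: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
    for _parent, child in tree.branches():
        side = below[id(child)]
        if len(side) <= 1 or len(all_leaves - side) <= 1:
            continue
        if ref in side:
            side = all_leaves - side
        splits.add(side)
    return splits


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson–Foulds symmetric difference over non-trivial bipartitions."""
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise ValueError("trees have different leaf sets")
    s1, s2 = _bipartitions(t1), _bipartitions(t2)
    return len(s1 ^ s2)
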