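"""Wagner-parsimony reconstruction of ancestral gene content.

Each family's presence/absence pattern at the leaves is explained by a
minimum-penalty history over the rooted tree: a gain (absent→present
along a branch) costs ``gain_penalty``, a loss costs ``loss_penalty``,
and a family present at the root pays one gain for its origination (so
"gain at the root" competes on equal terms with later independent
gains). The optimum is found per family by a Sankoff dynamic program
over the two states, vectorised across all families at once.

Ties are broken toward absence, resolved root-first: when a gain at an
ancestor plus later losses ties with independent gains in subtrees, the
reconstruction prefers the later gains. This is deliberately conservative
about ancestral gene content; set ``tie_break="present"`` for the
opposite convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pangenome import OrthogroupMatrix
from .tree import PhyloTree

_BIG = 1e15


@dataclass
class PenaltyConfig:
    gain_penalty: float = 1.0
    loss_penalty: float = 1.0

    def __post_init__(self) -> None:
        if self.gain_penalty <= 0 or self.loss_penalty <= 0:
            raise ValueError("penalties must be positive")


@dataclass
class GainLossReconstruction:
    tree: PhyloTree
    families: list[str]
    node_state: dict[str, np.ndarray]  # node name -> bool array over families
    branch_gains: dict[str, frozenset[str]]  # child node name -> gained families
    branch_losses: dict[str, frozenset[str]]
    total_cost: float
    penalties: PenaltyConfig = field(default_factory=PenaltyConfig)

    def families_at(self, node_name: str) -> frozenset[str]:
        state = self.node_state.get(node_name)
        if state is None:
            raise KeyError(f"unknown node {node_name!r}")
        fams = np.asarray(self.families, dtype=object)
        return frozenset(fams[state])


def wagner_parsimony(
    tree: PhyloTree,
    matrix: OrthogroupMatrix | pd.DataFrame,
    penalties: PenaltyConfig | None = None,
    tie_break: str = "absent",
) -> GainLossReconstruction:
    """Minimum gain/loss history for every family on a rooted tree.

    ``matrix`` is an occurrence matrix (counts are binarised at ≥1) whose
    columns must cover every leaf of the tree.
    """
    if not tree.rooted:
        raise ValueError("gain/loss reconstruction requires a rooted tree")
    if tie_break not in ("absent", "present"):
        raise ValueError("tie_break must be 'absent' or 'present'")
    pen = penalties or PenaltyConfig()
    g, l = pen.gain_penalty, pen.loss_penalty

    presence = matrix.presence() if isinstance(matrix, OrthogroupMatrix) else (matrix > 0).astype(int)
    leaves = tree.leaf_names()
    missing = [x for x in leaves if x not in presence.columns]
    if missing:
        raise ValueError(f"tree leaves missing from matrix: {missing}")
    families = list(presence.index)
    n_fam = len(families)
    leaf_state = {x: presence[x].to_numpy(dtype=bool) for x in leaves}

    post = list(tree.postorder())
    c0: dict[int, np.ndarray] = {}
    c1: dict[int, np.ndarray] = {}
    for node in post:
        if node.is_leaf:
            obs = leaf_state[node.name]
            c0[id(node)] = np.where(obs, _BIG, 0.0)
            c1[id(node)] = np.where(obs, 0.0, _BIG)
        else:
            z0 = np.zeros(n_fam)
            z1 = np.zeros(n_fam)
            for child in node.children:
                z0 += np.minimum(c0[id(child)], c1[id(child)] + g)
                z1 += np.minimum(c0[id(child)] + l, c1[id(child)])
            c0[id(node)] = z0
            c1[id(node)] = z1

    root = tree.root
    total0 = c0[id(root)]
    total1 = c1[id(root)] + g  # origination of the family costs one gain
    if tie_break == "absent":
        state_root = total1 < total0
    else:
        state_root = total1 <= total0

    node_state: dict[str, np.ndarray] = {root.name: state_root}
    branch_gains: dict[str, frozenset[str]] = {}
    branch_losses: dict[str, frozenset[str]] = {}
    fams_arr = np.asarray(families, dtype=object)
    # root-present families are booked as gains on the root's virtual branch
    branch_gains[root.name] = frozenset(fams_arr[state_root])
    branch_losses[root.name] = frozenset()

    state_of: dict[int, np.ndarray] = {id(root): state_root}
    for node in tree.preorder():
        s = state_of[id(node)]
        for child in node.children:
            cost0 = np.where(s, c0[id(child)] + l, c0[id(child)])
            cost1 = np.where(s, c1[id(child)], c1[id(child)] + g)
            if tie_break == "absent":
                cs = cost1 < cost0
            else:
                cs = cost1 <= cost0
            state_of[id(child)] = cs
            node_state[child.name] = cs
            branch_gains[child.name] = frozenset(fams_arr[~s & cs])
            branch_losses[child.name] = frozenset(fams_arr[s & ~cs])

    total_cost = g * sum(len(v) for v in branch_gains.values()) + l * sum(
        len(v) for v in branch_losses.values()
    )
    return GainLossReconstruction(
        tree, families, node_state, branch_gains, branch_losses, float(total_cost), pen
    )


def branch_summary(recon: GainLossReconstruction) -> pd.DataFrame:
    """One row per branch: gained, lost and present-at-child counts.

    The root appears with parent "-"; its "gained" count is the inferred
    ancestral repertoire size. For every branch
    |child| = |parent| + gains − losses holds by construction.
    """
    rows = []
    root = recon.tree.root
    rows.append(
        [
            "-",
            root.name,
            len(recon.branch_gains[root.name]),
            0,
            int(recon.node_state[root.name].sum()),
        ]
    )
    for parent, child in recon.tree.branches():
        rows.append(
            [
                parent.name,
                child.name,
                len(recon.branch_gains[child.name]),
                len(recon.branch_losses[child.name]),
                int(recon.node_state[child.name].sum()),
            ]
        )
    return pd.DataFrame(rows, columns=["parent", "child", "gained", "lost", "present_child"])


def lca_content(recon: GainLossReconstruction, query: str | tuple[str, str]) -> frozenset[str]:
    """Family set at a named node, or at the LCA of a leaf pair."""
    if isinstance(query, tuple):
        node = recon.tree.lca(*query)
        return recon.families_at(node.name)
    return recon.families_at(query)


def category_profile(
    family_set: frozenset[str] | set[str], annotation: dict[str, str]
) -> pd.Series:
    """Percentage of a family set per functional category (plus unassigned).

    ``annotation`` maps family ID to a category label (e.g., COG
    meta-category); unmapped families count as "unassigned". Percentages
    sum to 100.
    """
    if not family_set:
        raise ValueError("empty family set")
    counts: dict[str, int] = {}
    for fam in family_set:
        cat = annotation.get(fam, "unassigned")
        counts[cat] = counts.get(cat, 0) + 1
    series = pd.Series(counts, dtype=float).sort_index()
    return 100.0 * series / series.sum()
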