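"""Distance-based neighbor-joining phylogeny of cluster representatives.

Distances are 1 - pairwise identity (the clustering module's alignment
definition), so the tree is self-contained without an external multiple
alignment; a pre-computed distance matrix is accepted for users who run
their own MSA. Neighbor joining is the standard Q-matrix agglomeration
with deterministic tie-breaking by label order; negative branch-length
estimates are clamped to zero (logged), a common convention.
"""

from __future__ import annotations

import io
import logging

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .clustering import pairwise_identity

logger = logging.getLogger("smdiv")


def distance_matrix(representatives: list[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise-identity distances (1 - identity) between representatives."""
    labels = [rid for rid, _ in representatives]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - pairwise_identity(
                representatives[i][1], representatives[j][1]
            )
    return DistanceMatrix(d, labels)


def _clamp(length: float) -> float:
    if length < 0:
        logger.info("neighbor_joining: clamped negative branch length %.4g to 0", length)
        return 0.0
    return float(length)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard neighbor joining on a distance matrix.

    Returns an unrooted tree represented with a trivalent root (n >= 3);
    for n < 3 a trivial tree is returned. Ties in the Q criterion break by
    the lexicographically smallest pair of clade labels (a clade is
    labelled by its smallest leaf), making the topology deterministic.
    """
    labels = list(dm.ids)
    d = np.array(dm.data, dtype=float)
    n = len(labels)
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    tags = list(labels)  # smallest leaf label per active clade

    if n == 1:
        return nodes[0]
    if n == 2:
        root = TreeNode(children=[nodes[0], nodes[1]])
        nodes[0].length = _clamp(d[0, 1] / 2.0)
        nodes[1].length = _clamp(d[0, 1] / 2.0)
        return root

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        tol = 1e-10 * max(1.0, abs(qmin))
        pairs = [
            (ai, aj)
            for ai in range(m)
            for aj in range(ai + 1, m)
            if q[ai, aj] <= qmin + tol
        ]
        ai, aj = min(pairs, key=lambda p: tuple(sorted((tags[active[p[0]]], tags[active[p[1]]]))))
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = _clamp(li)
        nodes[j].length = _clamp(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to the remaining clades
        new_row = np.zeros(d.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = (d[i, k] + d[j, k] - dij) / 2.0
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        tags.append(min(tags[i], tags[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    # three-point formulas for the final trivalent node
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    nodes[i].length = _clamp(li)
    nodes[j].length = _clamp(lj)
    nodes[k].length = _clamp(lk)
    order = sorted((i, j, k), key=lambda x: tags[x])
    return TreeNode(children=[nodes[x] for x in order])


def tree_distances(tree: TreeNode) -> DistanceMatrix:
    """Patristic (path-length) distances between the tree's leaves."""
    return tree.tip_tip_distances()


_ESCAPE = str.maketrans({c: "_" for c in "():;, '\""})


def write_newick(
    tree: TreeNode, annotations: dict[str, tuple[str, str, str]] | None = None
) -> str:
    """Serialize a tree to Newick, encoding annotations into leaf labels.

    ``annotations`` maps leaf name -> (site, stage, origin); annotated
    leaves are written ``id|site|stage|origin``. Characters with syntactic
    meaning in Newick are replaced by underscores.
    """
    out = tree.copy()
    for tip in out.tips():
        name = tip.name or ""
        if annotations and name in annotations:
            site, stage, origin = annotations[name]
            name = f"{name}|{site}|{stage}|{origin}"
        tip.name = name.translate(_ESCAPE)
    buf = io.StringIO()
    out.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string back into a tree."""
    return TreeNode.read(io.StringIO(text), format="newick")
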