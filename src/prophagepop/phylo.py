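"""Neighbour-joining trees and patristic distances.

The tANI similarity matrix is mapped linearly to a distance
(``d = (100 - tANI) / 100``) and a tree is built by the Saitou–Nei
neighbour-joining agglomeration.  The implementation is deterministic:
Q-matrix ties are broken by the lexicographically smallest pair of clade
representative labels, and negative estimated branch lengths are clamped to
zero with the deficit transferred to the sibling branch so path lengths are
preserved and patristic distances stay metric.  On additive (tree-metric)
inputs NJ recovers the generating tree exactly.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .io_formats import LabeledMatrix

__all__ = [
    "similarity_to_distance",
    "neighbor_joining",
    "patristic_matrix",
    "leaf_labels",
]


def similarity_to_distance(matrix: LabeledMatrix) -> LabeledMatrix:
    """Map percent similarities in [0, 100] to distances in [0, 1]."""
    vals = matrix.values
    if np.any(vals < 0.0) or np.any(vals > 100.0):
        raise ValueError("similarity entries must lie in [0, 100]")
    d = (100.0 - vals) / 100.0
    np.fill_diagonal(d, 0.0)
    return LabeledMatrix(list(matrix.labels), d)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def neighbor_joining(matrix: LabeledMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbour joining.

    Returns an unrooted tree (represented with a trifurcating seed node
    from the final three-taxon closure).  Requires at least three taxa and
    finite, non-negative distances.
    """
    n = len(matrix)
    if n < 3:
        raise ValueError("neighbor_joining requires at least 3 taxa")
    D = np.array(matrix.values, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")

    taxa = dendropy.TaxonNamespace(matrix.labels)
    nodes: list[dendropy.Node] = []
    for label in matrix.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    # representative label per active node, for deterministic tie-breaking
    reps = list(matrix.labels)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0.0, atol=1e-12))
        i, j = min(
            (tuple(sorted((a, b))) for a, b in ties),
            key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))),
        )
        dij = D[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        if vi < 0.0:
            vi, vj = 0.0, dij
        elif vj < 0.0:
            vi, vj = dij, 0.0
        parent = dendropy.Node()
        ci, cj = nodes[i], nodes[j]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = vi
        cj.edge.length = vj
        # distances from the new node to all remaining nodes
        du = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = du[keep]
        newD[:-1, -1] = du[keep]
        D = newD
        nodes = [nodes[x] for x in keep] + [parent]
        reps = [reps[x] for x in keep] + [min(reps[i], reps[j])]

    # final three-taxon closure: join at one (trifurcating) node
    a, b, c = nodes
    va = max(0.0, 0.5 * (D[0, 1] + D[0, 2] - D[1, 2]))
    vb = max(0.0, 0.5 * (D[0, 1] + D[1, 2] - D[0, 2]))
    vc = max(0.0, 0.5 * (D[0, 2] + D[1, 2] - D[0, 1]))
    root = dendropy.Node()
    for node, v in ((a, va), (b, vb), (c, vc)):
        root.add_child(node)
        node.edge.length = v
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def patristic_matrix(tree: dendropy.Tree) -> LabeledMatrix:
    """Pairwise leaf-to-leaf path-length distances of a tree."""
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has a branch without a length")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            vals[i, j] = vals[j, i] = d
    return LabeledMatrix(labels, vals)
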