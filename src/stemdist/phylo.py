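"""Distance-based dendrograms with stem-cell anchor leaves.

Patient samples and the stem-cell reference centroids are placed in one
pairwise distance matrix (same metric and gene mask as the survival analysis)
and agglomerated by neighbor joining, which is consistent on additive
(tree-metric) inputs and deterministic here: ties in the Q criterion break on
the lexicographically smallest label pair. Negative branch-length estimates
are clamped to zero with the deficit moved to the sibling edge. Trees are
unrooted dendropy objects, exported as standard Newick with branch lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .distance import METRICS, ReferenceProfile, profile_distance
from .filtering import FilterMask
from .io_core import ExpressionMatrix

logger = logging.getLogger("stemdist")

__all__ = [
    "DistanceMatrix",
    "pairwise_distance_matrix",
    "build_nj_tree",
    "write_newick",
    "read_newick",
    "tree_path_lengths",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over labelled leaves (samples + references)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate leaf labels")
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.values < -1e-9):
            raise ValueError("negative pairwise distance")


def pairwise_distance_matrix(
    expr: ExpressionMatrix,
    refs: list[ReferenceProfile],
    mask: FilterMask,
    metric: str,
) -> DistanceMatrix:
    """All sample-sample, sample-reference and reference-reference distances.

    Computed on the masked genes shared by the cohort and every reference.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    genes = [g for g in mask.gene_ids if g in set(expr.gene_ids)]
    for ref in refs:
        rg = set(ref.gene_ids)
        genes = [g for g in genes if g in rg]
    if len(genes) < 3:
        raise ValueError(f"only {len(genes)} masked gene(s) shared by cohort and references")
    cols = [expr.subset_genes(genes).values[:, j] for j in range(expr.n_samples)]
    labels = list(expr.sample_ids)
    for ref in refs:
        cols.append(ref.subset_genes(genes).centroid)
        labels.append(ref.label)
    if len(labels) < 3:
        raise ValueError("need >= 3 leaves for a tree")
    n = len(cols)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = profile_distance(cols[i], cols[j], metric)
    return DistanceMatrix(labels, D)


def _clamped_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative estimate to 0, moving the deficit to the sibling edge."""
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def build_nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining over the distance matrix; returns an unrooted tree.

    Classic Saitou-Nei agglomeration with the Studier-Keppler Q criterion:
    join the pair minimizing Q_ij = (n-2) d_ij - r_i - r_j, attach at branch
    lengths l_i = d_ij/2 + (r_i - r_j)/(2(n-2)), and update distances by
    d_uk = (d_ik + d_jk - d_ij)/2. Q ties break on the lexicographically
    smallest sorted label pair; internal nodes carry the smallest leaf label
    beneath them for that purpose.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 leaves")
    tns = dendropy.TaxonNamespace(dm.labels)
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab)
        nodes.append(node)
    keys = list(dm.labels)  # tie-break key per active node
    D = dm.values.astype(float).copy()

    def join(i_pos: int, j_pos: int) -> np.ndarray:
        """Join active positions i_pos < j_pos into a new internal node."""
        m = len(nodes)
        r = D.sum(axis=1)
        dij = D[i_pos, j_pos]
        if m > 2:
            li = 0.5 * dij + (r[i_pos] - r[j_pos]) / (2.0 * (m - 2))
        else:
            li = 0.5 * dij
        lj = dij - li
        li, lj = _clamped_pair(li, lj)
        parent = dendropy.Node()
        ci, cj = nodes[i_pos], nodes[j_pos]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = li
        cj.edge.length = lj
        newd = 0.5 * (D[i_pos, :] + D[j_pos, :] - dij)
        newd = np.maximum(newd, 0.0)
        keep = [p for p in range(m) if p not in (i_pos, j_pos)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = newd[keep]
        D2[:-1, -1] = newd[keep]
        D2[-1, -1] = 0.0
        nodes[:] = [nodes[p] for p in keep] + [parent]
        keys[:] = [keys[p] for p in keep] + [min(keys[i_pos], keys[j_pos])]
        return D2

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            ((i, j) for i, j in cand if i < j),
            key=lambda p: tuple(sorted((keys[p[0]], keys[p[1]]))),
        )
        D = join(*best)

    # final three nodes: closed-form three-point branch lengths
    a, b, c = 0, 1, 2
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for node, length in zip(nodes, (la, lb, lc)):
        if length < 0:
            logger.info("clamping negative terminal branch length %.3g to 0", length)
            length = 0.0
        root.add_child(node)
        node.edge.length = float(length)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write standard Newick with branch lengths; labels needing it are quoted."""
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("tree has duplicate leaf labels")
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def tree_path_lengths(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (labels sorted)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, M)
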