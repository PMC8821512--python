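"""Pairwise codon-usage distance and hierarchical clustering of genes.

The distance between genes 1 and 2 is

    d12 = sum_j sum_i (f1_ij - f2_ij)^2 / Na

where f^x_ij is the frequency in gene x of codon i among the codons of
amino acid j, the outer sum runs over the degenerate amino acids (Met and
Trp excluded) represented at least once in each gene, and Na is the number
of those shared amino acids. Sixfold amino acids are single 6-codon
families here. Genes are clustered agglomeratively (complete linkage by
default) and the dendrogram can be serialized as Newick with branch lengths
equal to merge heights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .codonstats import FAMILY_MATRIX, CodonUsageTable, _as_counts


def codon_usage_distance(g1, g2) -> float:
    """Mean squared within-family frequency difference over shared families."""
    c1 = _as_counts(g1)
    c2 = _as_counts(g2)
    n1 = FAMILY_MATRIX @ c1
    n2 = FAMILY_MATRIX @ c2
    shared = (n1 > 0) & (n2 > 0)
    n_shared = int(shared.sum())
    if n_shared == 0:
        raise ValueError("genes share no degenerate amino acid")
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(n1 > 0, 1.0 / n1, 0.0)[:, None] * FAMILY_MATRIX * c1[None, :]
        f2 = np.where(n2 > 0, 1.0 / n2, 0.0)[:, None] * FAMILY_MATRIX * c2[None, :]
    sq = ((f1 - f2) ** 2 * FAMILY_MATRIX)[shared]
    return float(sq.sum() / n_shared)


@dataclass
class GeneDistanceMatrix:
    gene_ids: tuple[str, ...]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        n = len(self.gene_ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape must match gene count")
        if not np.allclose(d, d.T) or (np.diag(d) != 0).any() or (d < 0).any():
            raise ValueError("distances must be symmetric, non-negative, zero diagonal")
        self.distances = d


def distance_matrix(usages: list[CodonUsageTable]) -> GeneDistanceMatrix:
    n = len(usages)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = codon_usage_distance(usages[i], usages[j])
    return GeneDistanceMatrix(tuple(u.gene_id for u in usages), d)


def cluster_genes(distances: GeneDistanceMatrix, linkage: str = "complete") -> np.ndarray:
    """Agglomerative clustering; returns a scipy linkage matrix."""
    if len(distances.gene_ids) < 2:
        raise ValueError("need at least 2 genes to cluster")
    condensed = squareform(distances.distances, checks=True)
    return hierarchy.linkage(condensed, method=linkage)


def to_newick(link: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as Newick; branch lengths are the
    differences between a node's merge height and its parent's."""
    tree = hierarchy.to_tree(link)

    def rec(node, parent_height) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = rec(tree.left, tree.dist)
    right = rec(tree.right, tree.dist)
    return f"({left},{right});"
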