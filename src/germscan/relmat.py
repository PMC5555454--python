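"""Pairwise relatedness: allele-sharing distance, IBS, genomic kinship,
Ward dendrograms and thresholded IBS networks.

Distance and IBS are frequency-free: over the markers called in both
accessions, each marker contributes ``2 - |g_i - g_j|`` shared alleles out
of 2, so ``distance = 1 - IBS`` exactly on the same marker set.  Kinship is
the frequency-aware genomic relationship matrix: the cross-product of the
centered, standardized genotype matrix (VanRaden-style), with missing
entries mean-imputed (zero after centering).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .gio import GenotypeMatrix

__all__ = [
    "PairwiseMatrix",
    "allele_sharing_distance",
    "ibs_matrix",
    "kinship",
    "ward_tree",
    "tree_to_newick",
    "ibs_network",
    "network_edge_list",
]


@dataclass
class PairwiseMatrix:
    """Symmetric accession × accession matrix of kind distance, ibs or kinship."""

    accession_ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if self.kind not in ("distance", "ibs", "kinship"):
            raise ValueError(f"unknown kind {self.kind!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accession_ids, columns=self.accession_ids)

    def write(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f", index_label="accession")


def _shared_allele_sums(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (sum over joint-called markers of |g_i - g_j|, joint call counts)."""
    called = (~np.isnan(d)).astype(float)
    ind = [(d == v).astype(float) for v in (0.0, 1.0, 2.0)]
    # |a-b| weights over dosage categories: (0,1)=1, (1,2)=1, (0,2)=2
    n01 = ind[0] @ ind[1].T
    n12 = ind[1] @ ind[2].T
    n02 = ind[0] @ ind[2].T
    diff = (n01 + n01.T) + (n12 + n12.T) + 2.0 * (n02 + n02.T)
    n_shared = called @ called.T
    return diff, n_shared


def allele_sharing_distance(genotypes: GenotypeMatrix) -> PairwiseMatrix:
    """Proportion of non-shared alleles over pairwise-complete markers.

    For accessions i, j: distance = sum |g_i - g_j| / (2 * n shared markers).
    Pairs sharing no called marker get NaN.
    """
    if genotypes.n_accessions < 2:
        raise ValueError("need at least two accessions")
    diff, n_shared = _shared_allele_sums(genotypes.dosage)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = diff / (2.0 * n_shared)
    dist[n_shared == 0] = np.nan
    np.fill_diagonal(dist, 0.0)
    return PairwiseMatrix(list(genotypes.accession_ids), dist, "distance")


def ibs_matrix(genotypes: GenotypeMatrix) -> PairwiseMatrix:
    """Identity-by-state: shared-allele fraction, the complement of the distance."""
    dist = allele_sharing_distance(genotypes)
    vals = 1.0 - dist.values
    np.fill_diagonal(vals, 1.0)
    return PairwiseMatrix(dist.accession_ids, vals, "ibs")


def kinship(genotypes: GenotypeMatrix) -> PairwiseMatrix:
    """Genomic relationship matrix from centered, standardized genotypes.

    x_il = (g_il - 2 p_l) / sqrt(2 p_l (1 - p_l)); missing entries are set to
    zero after centering (mean imputation); K = X X^T / m over the m markers
    polymorphic on the panel.  For fully inbred lines the diagonal approaches
    1 + f = 2.
    """
    d = genotypes.dosage
    n_called = (~np.isnan(d)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * np.maximum(n_called, 1))
    usable = (n_called > 0) & (p > 0.0) & (p < 1.0)
    if not usable.any():
        raise ValueError("all markers monomorphic; kinship standardization undefined")
    d = d[:, usable]
    p = p[usable]
    x = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    x = np.nan_to_num(x, nan=0.0)
    k = (x @ x.T) / x.shape[1]
    return PairwiseMatrix(list(genotypes.accession_ids), k, "kinship")


def ward_tree(distance: PairwiseMatrix) -> np.ndarray:
    """Agglomerative Ward clustering of a precomputed distance matrix.

    Uses the Lance–Williams Ward update on the given dissimilarities and
    returns a scipy linkage matrix (merge list with heights); leaves are in
    ``distance.accession_ids`` order.
    """
    if distance.kind != "distance":
        raise ValueError("ward_tree expects a distance matrix")
    if np.isnan(distance.values).any():
        raise ValueError("distance matrix has undefined pairs; cannot cluster")
    condensed = squareform(distance.values, checks=False)
    return sch.linkage(condensed, method="ward")


def tree_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a linkage matrix as a newick string with merge-height branch lengths."""
    tree = sch.to_tree(linkage)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6f}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return rec(tree, tree.dist) + ";"


def ibs_network(
    ibs: PairwiseMatrix | None = None,
    threshold: float = 0.8,
    genotypes: GenotypeMatrix | None = None,
    marker_subset=None,
    node_attrs: pd.Series | None = None,
) -> nx.Graph:
    """Graph of accessions with an edge wherever IBS strictly exceeds ``threshold``.

    If ``marker_subset`` is given the IBS matrix is recomputed on that subset
    (requires ``genotypes``); isolated nodes are retained.  ``node_attrs``
    (e.g. group labels) become a ``group`` node attribute.
    """
    if marker_subset is not None:
        marker_subset = list(marker_subset)
        if not marker_subset:
            raise ValueError("marker_subset is empty")
        if genotypes is None:
            raise ValueError("recomputing IBS on a marker subset requires genotypes")
        ibs = ibs_matrix(genotypes.subset_markers(marker_subset))
    if ibs is None:
        if genotypes is None:
            raise ValueError("provide an IBS matrix or genotypes")
        ibs = ibs_matrix(genotypes)
    g = nx.Graph(threshold=threshold)
    ids = ibs.accession_ids
    for a in ids:
        g.add_node(a)
    vals = ibs.values
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if not np.isnan(vals[i, j]) and vals[i, j] > threshold:
                g.add_edge(ids[i], ids[j], ibs=float(vals[i, j]))
    if node_attrs is not None:
        for a in ids:
            if a in node_attrs.index:
                g.nodes[a]["group"] = node_attrs.loc[a]
    return g


def network_edge_list(graph: nx.Graph) -> pd.DataFrame:
    rows = [{"acc1": u, "acc2": v, "ibs": d["ibs"]} for u, v, d in graph.edges(data=True)]
    return pd.DataFrame(rows, columns=["acc1", "acc2", "ibs"])
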