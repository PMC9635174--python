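"""Sparse Spearman-correlation network and module detection.

Each analyte proposes an edge to its k strongest partners by |Spearman rho|;
the network is the symmetric union of proposals.  Connected components are
then clustered independently by average-linkage hierarchical clustering on
the dense dissimilarity d = 1 - |rho| (recomputed within each component so
linkage heights are defined for all pairs), the tree is cut at a fixed
height, and clusters below the minimum size fall into the background module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .datatypes import AnalyteMatrix, ModulePartition, OmodError, BACKGROUND


@dataclass
class SparseNetwork:
    """Undirected |rho|-weighted analyte network (deduplicated edge list)."""

    nodes: list[str]
    edges: list[tuple[int, int, float]]  # (i, j, weight), i < j

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.nodes[i], self.nodes[j], w) for i, j, w in self.edges],
            columns=["analyte_i", "analyte_j", "weight"],
        )


def spearman_corr(values: np.ndarray) -> np.ndarray:
    """Dense Spearman correlation across columns (average ranks for ties)."""
    ranks = np.apply_along_axis(rankdata, 0, values)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    return np.nan_to_num(rho, nan=0.0)


def spearman_network(m: AnalyteMatrix, edges_per_node: int = 20) -> SparseNetwork:
    """Symmetric union of each analyte's ``edges_per_node`` strongest
    |Spearman| partners; ties broken by analyte position (deterministic)."""
    if edges_per_node < 1:
        raise OmodError("edges_per_node must be >= 1")
    if m.values.shape[0] < 3:
        raise OmodError("need at least 3 samples to rank correlations")
    rho = spearman_corr(m.values.to_numpy())
    p = rho.shape[0]
    k = min(edges_per_node, p - 1)
    a = np.abs(rho).copy()
    np.fill_diagonal(a, -np.inf)
    edge_set: set[tuple[int, int]] = set()
    order = np.arange(p)
    for i in range(p):
        # sort by (-|rho|, partner index): deterministic under ties
        idx = np.lexsort((order, -a[i]))[:k]
        for j in idx:
            edge_set.add((min(i, j), max(i, j)))
    edges = sorted(edge_set)
    return SparseNetwork(
        nodes=list(m.values.columns),
        edges=[(i, j, float(abs(rho[i, j]))) for i, j in edges],
    )


def cluster_modules(
    net: SparseNetwork,
    m: AnalyteMatrix,
    cut_height: float = 0.75,
    min_module_size: int = 2,
) -> ModulePartition:
    """Partition analytes into modules via per-component average linkage.

    Module ids are assigned in decreasing size order (ties by the
    lexicographically smallest member id), starting at 1; background is 0.
    """
    if not 0 < cut_height <= 1:
        raise OmodError("cut_height must be in (0, 1]")
    if not net.edges and len(net.nodes) > 1:
        raise OmodError("network has no edges")
    nodes = net.nodes
    p = len(nodes)
    ii = [e[0] for e in net.edges]
    jj = [e[1] for e in net.edges]
    adj = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(p, p))
    n_comp, labels = connected_components(adj, directed=False)

    values = m.values[nodes].to_numpy()
    clusters: list[list[int]] = []
    for c in range(n_comp):
        comp = np.flatnonzero(labels == c)
        if len(comp) == 1:
            clusters.append([int(comp[0])])
            continue
        rho = spearman_corr(values[:, comp])
        d = 1.0 - np.abs(rho)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
        link = average(squareform(d, checks=False))
        assign = fcluster(link, t=cut_height, criterion="distance")
        for lab in np.unique(assign):
            clusters.append([int(comp[i]) for i in np.flatnonzero(assign == lab)])

    keep = [cl for cl in clusters if len(cl) >= min_module_size]
    keep.sort(key=lambda cl: (-len(cl), min(nodes[i] for i in cl)))
    assignment = pd.Series(BACKGROUND, index=pd.Index(nodes, name="analyte_id"))
    for mid, cl in enumerate(keep, start=1):
        assignment.iloc[cl] = mid
    return ModulePartition(assignment=assignment)


def summarize_partition(part: ModulePartition) -> dict:
    """Counts a run log reports: modules, assigned/unassigned analytes,
    mean assigned analytes per module."""
    sizes = [len(v) for v in part.modules().values()]
    n_unassigned = len(part.background())
    n_total = len(part.assignment)
    return {
        "n_analytes": n_total,
        "n_modules": len(sizes),
        "n_unassigned": n_unassigned,
        "mean_module_size": (n_total - n_unassigned) / len(sizes) if sizes else np.nan,
        "largest_module": max(sizes) if sizes else 0,
    }
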