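"""Mutual-information co-expression networks and core-gene calling.

The estimator follows the ARACNE recipe: estimate pairwise mutual
information (MI) for all gene pairs, then apply the data-processing
inequality (DPI) — in every triangle the weakest edge is presumed an
indirect interaction and pruned.  Hubs of the pruned network that keep
at least ``min_degree`` co-expressed partners whose average MI exceeds
``mean_mi_min`` are called core genes.

MI estimator
------------
Each expression vector is rank-transformed (making the estimate invariant
under strictly monotone transforms, so linear FPKM and log-FPKM give the
same network) and discretized into B equal-frequency bins,
B = floor(sqrt(n/2)) by default.  The plug-in estimate

    I = sum_{a,b} p(a,b) ln [ p(a,b) / (p(a) p(b)) ]     (nats)

is debiased with the Miller–Madow correction
(m_xy - m_x - m_y + 1) / (2n), where m are the counts of occupied cells
and bins, and floored at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class NetworkError(ValueError):
    pass


# ---------------------------------------------------------------------------
# MI estimation

def _auto_bins(n: int) -> int:
    return max(2, int(np.floor(np.sqrt(n / 2))))


def _rank_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Ordinal ranks (stable on ties) cut into equal-frequency bins."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(x.size)
    return (ranks * n_bins) // x.size


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def mutual_information(x, y, bins: int | str = "auto") -> float:
    """Bias-corrected binned MI between two vectors, in nats.

    A constant vector carries no information; it yields 0.0 with a
    warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise NetworkError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 8:
        raise NetworkError(f"need at least 8 observations, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise NetworkError("missing or non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: MI undefined, returning 0",
                      stacklevel=2)
        return 0.0
    b = _auto_bins(n) if bins == "auto" else int(bins)
    if b < 2:
        raise NetworkError("bins must be at least 2")
    bx = _rank_bins(x, b)
    by = _rank_bins(y, b)
    joint = np.bincount(bx * b + by, minlength=b * b)
    cx = np.bincount(bx, minlength=b)
    cy = np.bincount(by, minlength=b)
    i_plugin = _entropy(cx, n) + _entropy(cy, n) - _entropy(joint, n)
    m_xy = int((joint > 0).sum())
    m_x = int((cx > 0).sum())
    m_y = int((cy > 0).sum())
    correction = (m_xy - m_x - m_y + 1) / (2.0 * n)
    return max(0.0, i_plugin - correction)


# ---------------------------------------------------------------------------
# network container

@dataclass
class MINetwork:
    """Symmetric weighted gene graph with per-edge pruned flags.

    ``mi`` is the dense symmetric MI matrix (zero diagonal); ``pruned``
    marks edges removed by the DPI step.
    """

    genes: list[str]
    mi: np.ndarray
    pruned: np.ndarray = field(default=None)

    def __post_init__(self):
        k = len(self.genes)
        if self.mi.shape != (k, k):
            raise NetworkError("MI matrix shape does not match gene list")
        if not np.allclose(self.mi, self.mi.T):
            raise NetworkError("MI matrix must be symmetric")
        if self.pruned is None:
            self.pruned = np.zeros((k, k), dtype=bool)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def edge_frame(self, min_mi: float = 0.0,
                   include_pruned: bool = True) -> pd.DataFrame:
        """Upper-triangle edge list with columns gene_a, gene_b, mi, pruned."""
        iu, ju = np.triu_indices(self.n_genes, k=1)
        keep = self.mi[iu, ju] > min_mi
        if not include_pruned:
            keep &= ~self.pruned[iu, ju]
        iu, ju = iu[keep], ju[keep]
        return pd.DataFrame(
            {"gene_a": [self.genes[i] for i in iu],
             "gene_b": [self.genes[j] for j in ju],
             "mi": self.mi[iu, ju],
             "pruned": self.pruned[iu, ju]})

    def n_edges(self, min_mi: float = 0.0, include_pruned: bool = True) -> int:
        return len(self.edge_frame(min_mi, include_pruned))


def mi_matrix(m, genes=None, bins: int | str = "auto") -> MINetwork:
    """All-pairs MI network over replicate-level expression columns.

    ``m`` is an ExpressionMatrix (or any object with a ``values``
    DataFrame); ``genes`` restricts to a subset (typically the highly
    variable genes).  Implemented as one joint-histogram matrix product
    over the one-hot binned data, so the full pairwise computation is a
    single BLAS call.
    """
    values = m if isinstance(m, pd.DataFrame) else m.values
    if genes is not None:
        missing = [g for g in genes if g not in values.index]
        if missing:
            raise NetworkError(f"genes not in matrix: {missing[:5]}")
        values = values.loc[list(genes)]
    gene_ids = list(values.index)
    k, n = values.shape
    if k < 2:
        raise NetworkError("need at least 2 genes")
    if n < 8:
        raise NetworkError(f"need at least 8 samples, got {n}")
    b = _auto_bins(n) if bins == "auto" else int(bins)
    if b < 2:
        raise NetworkError("bins must be at least 2")

    arr = values.to_numpy(dtype=float)
    constant = np.ptp(arr, axis=1) == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene(s): "
                      "their MI set to 0", stacklevel=2)

    bin_idx = np.empty((k, n), dtype=np.int64)
    for i in range(k):
        bin_idx[i] = _rank_bins(arr[i], b)

    onehot = np.zeros((k, b, n))
    rows = np.repeat(np.arange(k), n)
    onehot[rows, bin_idx.ravel(), np.tile(np.arange(n), k)] = 1.0

    flat = onehot.reshape(k * b, n)
    joint = (flat @ flat.T).reshape(k, b, k, b)          # counts per pair

    counts = onehot.sum(axis=2)                          # (k, b) marginals
    h_marg = np.array([_entropy(c, n) for c in counts])
    m_marg = (counts > 0).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        p = joint / n
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h_joint = -plogp.sum(axis=(1, 3))
    m_joint = (joint > 0).sum(axis=(1, 3))

    mi = h_marg[:, None] + h_marg[None, :] - h_joint
    mi -= (m_joint - m_marg[:, None] - m_marg[None, :] + 1) / (2.0 * n)
    mi = np.maximum(mi, 0.0)
    mi = (mi + mi.T) / 2.0
    np.fill_diagonal(mi, 0.0)
    if constant.any():
        mi[constant, :] = 0.0
        mi[:, constant] = 0.0
    return MINetwork(gene_ids, mi)


# ---------------------------------------------------------------------------
# DPI pruning

def dpi_prune(net: MINetwork, tolerance: float = 0.0) -> MINetwork:
    """Mark the weakest edge of every triangle as pruned.

    For each edge (i, j) present in the *input* graph, the edge is pruned
    if some third gene k forms a triangle in which (i, j) is strictly the
    weakest edge: mi_ij < (1 - tolerance) * min(mi_ik, mi_jk).  Decisions
    are evaluated on the input graph, so the result is independent of any
    triangle processing order and the operation is idempotent.
    """
    if tolerance < 0:
        raise NetworkError("tolerance must be non-negative")
    mi = np.where(net.pruned, 0.0, net.mi)
    k = net.n_genes
    # maxmin[i, j] = max over k of min(mi_ik, mi_jk); absent edges (mi 0)
    # never support a triangle
    maxmin = np.zeros((k, k))
    for t in range(k):
        np.maximum(maxmin, np.minimum.outer(mi[:, t], mi[t, :]), out=maxmin)
    newly = (mi > 0) & (mi < (1.0 - tolerance) * maxmin)
    return MINetwork(net.genes, net.mi, net.pruned | newly)


# ---------------------------------------------------------------------------
# core genes

def call_core_genes(net: MINetwork, edge_mi_min: float = 0.4,
                    min_degree: int = 20,
                    mean_mi_min: float = 0.4) -> pd.DataFrame:
    """Degree / mean-MI hub statistics and the core-gene call.

    A gene's co-expressed partners are its unpruned neighbours with edge
    MI strictly above ``edge_mi_min``.  A gene is core when it has at
    least ``min_degree`` partners (non-strict) and the mean MI over those
    partner edges strictly exceeds ``mean_mi_min``.
    """
    if edge_mi_min < 0 or mean_mi_min < 0:
        raise NetworkError("MI thresholds must be non-negative")
    if min_degree < 0:
        raise NetworkError("min_degree must be non-negative")
    adj = (~net.pruned) & (net.mi > edge_mi_min)
    np.fill_diagonal(adj, False)
    degree = adj.sum(axis=1)
    mi_sum = np.where(adj, net.mi, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_mi = np.where(degree > 0, mi_sum / np.maximum(degree, 1), 0.0)
    out = pd.DataFrame(
        {"degree": degree,
         "mean_mi": mean_mi,
         "is_core": (degree >= min_degree) & (mean_mi > mean_mi_min)},
        index=pd.Index(net.genes, name="gene_id"))
    return out


def export_network(net: MINetwork, path, display_mi_min: float = 0.5,
                   format: str = "edge_list_tsv") -> None:
    """Write the displayed network: unpruned edges with MI above cutoff.

    ``edge_list_tsv`` writes gene_a/gene_b/mi columns; ``gml`` writes a
    networkx GML graph whose nodes carry their displayed degree (the
    connectivity used to colour network figures).
    """
    edges = net.edge_frame(min_mi=display_mi_min, include_pruned=False)
    if format == "edge_list_tsv":
        edges.drop(columns="pruned").to_csv(path, sep="\t", index=False)
    elif format == "gml":
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(net.genes)
        for row in edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, mi=float(row.mi))
        nx.set_node_attributes(g, dict(g.degree()), "degree")
        nx.write_gml(g, path)
    else:
        raise NetworkError(f"unknown export format {format!r}")
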