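"""Expression-pattern clustering and heatmap ordering.

Genes are row-standardized (z-scored) and partitioned into k expression
patterns with Euclidean k-means (the canonical six patterns across the
15 aphid types use k = 6).  Hierarchical ordering of genes and samples
provides the dendrogram leaf orders used for heatmap display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .data import TypeMatrix


class PatternError(ValueError):
    pass


def zscore_rows(m: TypeMatrix) -> TypeMatrix:
    """Standardize each gene row to mean 0, sample sd 1.

    Zero-variance rows carry no pattern and are dropped with a warning.
    """
    values = m.values
    sd = values.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"dropping {int(flat.sum())} zero-variance gene(s)",
                      stacklevel=2)
        values = values.loc[~flat]
        sd = sd[~flat]
    z = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    return TypeMatrix(z, m.types, scale="zscore")


@dataclass
class PatternAssignment:
    """k-means result: per-gene cluster labels (1..k, largest first)."""

    labels: pd.Series                 # gene_id -> cluster
    centroids: pd.DataFrame           # cluster x type centroid profiles
    inertia: float

    @property
    def k(self) -> int:
        return len(self.centroids)

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def kmeans_patterns(m: TypeMatrix, k: int = 6, n_init: int = 50,
                    seed: int = 0) -> PatternAssignment:
    """Euclidean k-means on (z-scored) type profiles.

    Best of ``n_init`` random initializations by within-cluster sum of
    squares; deterministic for a given seed.  Cluster labels are
    re-indexed by descending size so reports are stable across runs.
    """
    if k < 1:
        raise PatternError("k must be positive")
    if k > m.values.shape[0]:
        raise PatternError(f"k={k} exceeds gene count {m.values.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(m.values.to_numpy(dtype=float))
    # relabel by descending cluster size, ties by original label
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    labels = pd.Series(remap[raw], index=m.values.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_[order],
                             index=pd.Index(np.arange(1, k + 1),
                                            name="cluster"),
                             columns=m.values.columns)
    return PatternAssignment(labels, centroids, float(km.inertia_))


def hierarchical_order(m: TypeMatrix, distance: str = "correlation",
                       linkage: str = "average"):
    """Dendrogram leaf orders for genes (rows) and samples (columns).

    Returns ``(gene_order, sample_order)`` as lists of labels.
    Deterministic for fixed input.  A constant matrix has no defined
    correlation structure and raises.
    """
    if distance not in ("correlation", "euclidean"):
        raise PatternError(f"unknown distance {distance!r}")
    if linkage not in ("average", "complete"):
        raise PatternError(f"unknown linkage {linkage!r}")
    values = m.values.to_numpy(dtype=float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise PatternError("need at least 2 rows and 2 columns")

    def leaf_order(mat):
        if distance == "correlation" and (np.ptp(mat, axis=1) == 0).any():
            raise PatternError(
                "constant row/column: correlation distance undefined")
        d = pdist(mat, metric=distance)
        if not np.isfinite(d).all():
            raise PatternError("degenerate matrix: undefined distances")
        return sch.leaves_list(sch.linkage(d, method=linkage))

    gene_order = [m.gene_ids[i] for i in leaf_order(values)]
    sample_order = [m.values.columns[i] for i in leaf_order(values.T)]
    return gene_order, sample_order


def linkage_matrix(m: TypeMatrix, axis: str = "columns",
                   distance: str = "correlation",
                   linkage: str = "average") -> np.ndarray:
    """Raw scipy linkage for one axis (for dendrogram plotting/tests)."""
    values = m.values.to_numpy(dtype=float)
    mat = values.T if axis == "columns" else values
    return sch.linkage(pdist(mat, metric=distance), method=linkage)
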