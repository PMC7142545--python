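"""Morph-marker ranking with a random-forest classifier.

Replicate-level samples are the observations (labelled by morph, or by
the full 15-way type), genes are the features.  The forest is grown as
an explicit bootstrap loop over CART trees so that out-of-bag (OOB)
permutation importance can be computed per tree:

* **mean decrease Gini** — total Gini-impurity reduction attributed to a
  gene, averaged over trees; the score used to pick the top-30 markers;
* **mean decrease accuracy** — drop in a tree's OOB accuracy when the
  gene's OOB values are permuted, averaged over trees.

Both scores are the standard random-forest importances; ranking is by
mean decrease Gini with ties broken by gene order.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .data import ExpressionMatrix


class MarkerError(ValueError):
    pass


def rank_markers(m: ExpressionMatrix, label: str = "morph",
                 n_trees: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Rank every gene by random-forest importance for the given label.

    Each of ``n_trees`` CART trees is fit to a bootstrap resample with
    floor(sqrt(p)) candidate features per split and the Gini criterion.
    Returns a DataFrame indexed by gene with columns
    ``mean_decrease_gini``, ``mean_decrease_accuracy`` and ``rank_gini``
    (1 = most important).  Deterministic for a given seed.
    """
    if label == "morph":
        y = m.morph_labels()
    elif label == "type":
        y = np.array(["_".join(t) for t in m.type_labels()])
    else:
        raise MarkerError(f"label must be 'morph' or 'type', got {label!r}")
    if n_trees < 1:
        raise MarkerError("n_trees must be positive")

    X = m.values.to_numpy(dtype=float).T          # samples x genes
    n, p = X.shape
    if p == 0:
        raise MarkerError("no genes in matrix")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise MarkerError("need at least 2 label classes")
    small = classes[counts < 2]
    if small.size:
        raise MarkerError(f"class {small[0]!r} has fewer than 2 samples")

    rng = np.random.default_rng(seed)
    gini = np.zeros(p)
    mda = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            criterion="gini", max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)))
        tree.fit(X[boot], y[boot])
        gini += tree.tree_.compute_feature_importances(normalize=False)
        if oob.size == 0:
            continue
        X_oob, y_oob = X[oob], y[oob]
        acc = float(np.mean(tree.predict(X_oob) == y_oob))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for f in used:
            perm = rng.permutation(oob.size)
            X_perm = X_oob.copy()
            X_perm[:, f] = X_oob[perm, f]
            acc_perm = float(np.mean(tree.predict(X_perm) == y_oob))
            mda[f] += acc - acc_perm

    gini /= n_trees
    mda /= n_trees
    # rank by gini, stable so ties fall back to gene order
    order = np.argsort(-gini, kind="stable")
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    return pd.DataFrame(
        {"mean_decrease_gini": gini,
         "mean_decrease_accuracy": mda,
         "rank_gini": rank},
        index=pd.Index(m.gene_ids, name="gene_id"))


def top_markers(rankings: pd.DataFrame, top_n: int = 30) -> list[str]:
    """The ``top_n`` genes by mean decrease Gini, best first."""
    if top_n < 1:
        raise MarkerError("top_n must be positive")
    if top_n > len(rankings):
        warnings.warn(f"top_n={top_n} exceeds gene count {len(rankings)}; "
                      "returning all genes", stacklevel=2)
        top_n = len(rankings)
    ordered = rankings.sort_values("rank_gini")
    return list(ordered.index[:top_n])
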