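"""The tau type-specificity index.

For a gene with expression v_1..v_N across N types,

    tau = sum_i (1 - x_i) / (N - 1),   x_i = v_i / max_j v_j.

tau is 0 for perfectly uniform expression and 1 for expression confined
to a single type; it depends only on each value relative to the gene's
maximum, so it is invariant to positive rescaling of a gene's row.
Genes with tau strictly above the cutoff (default 0.8) are called
type-specifically expressed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import TypeMatrix, type_column_name


class SpecificityError(ValueError):
    pass


def compute_tau(m: TypeMatrix) -> pd.DataFrame:
    """Per-gene tau over the type columns of ``m``.

    Returns a DataFrame indexed by gene with columns ``tau``,
    ``max_genotype``, ``max_morph``, ``max_type`` (the argmax column,
    first-in-order on ties) and ``max_tied`` (tie flag).

    Every gene must have a positive maximum (run the expressed-gene
    filter first); N must be at least 2.
    """
    n = m.n_types
    if n < 2:
        raise SpecificityError("tau needs at least 2 type columns")
    v = m.values.to_numpy(dtype=float)
    vmax = v.max(axis=1)
    zero = vmax <= 0
    if zero.any():
        gene = m.gene_ids[int(np.flatnonzero(zero)[0])]
        raise SpecificityError(
            f"gene {gene!r} has no positive expression; filter first")
    x = v / vmax[:, None]
    tau = (1.0 - x).sum(axis=1) / (n - 1)
    argmax = v.argmax(axis=1)
    tied = (v == vmax[:, None]).sum(axis=1) > 1
    types = [m.types[j] for j in argmax]
    return pd.DataFrame(
        {"tau": tau,
         "max_genotype": [t[0] for t in types],
         "max_morph": [t[1] for t in types],
         "max_type": [type_column_name(*t) for t in types],
         "max_tied": tied},
        index=pd.Index(m.gene_ids, name="gene_id"))


def call_specific(results: pd.DataFrame, tau_cutoff: float = 0.8) -> pd.DataFrame:
    """Flag genes with tau strictly above ``tau_cutoff``.

    A gene at exactly the cutoff is not called.  Returns a copy with an
    ``is_specific`` column.
    """
    if not 0 <= tau_cutoff <= 1:
        raise SpecificityError("tau_cutoff must lie in [0, 1]")
    out = results.copy()
    out["is_specific"] = out["tau"] > tau_cutoff
    return out


def specific_tally_by_morph(results: pd.DataFrame) -> pd.Series:
    """Count specific genes per morph of their argmax type."""
    if "is_specific" not in results:
        raise SpecificityError("run call_specific first")
    spec = results[results["is_specific"]]
    return spec.groupby("max_morph").size().sort_values(ascending=False)
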