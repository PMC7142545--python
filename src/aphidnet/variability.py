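"""Highly-variable-gene selection by standard deviation.

Variability is measured as the per-gene sample standard deviation
(N - 1 denominator) across columns, on the scale of the matrix passed
in; the default pipeline passes linear FPKM, where the conventional
cutoff of 6 is meaningful.  Selection is strict: sd must exceed the
cutoff.
"""

from __future__ import annotations

import pandas as pd

from .data import TypeMatrix


class VariabilityError(ValueError):
    pass


def select_hvg(m: TypeMatrix, sd_cutoff: float = 6.0) -> pd.DataFrame:
    """Per-gene sd and a strict ``sd > sd_cutoff`` selection flag."""
    if sd_cutoff < 0:
        raise VariabilityError("sd_cutoff must be non-negative")
    if m.values.shape[1] < 2:
        raise VariabilityError("need at least 2 columns to compute sd")
    sd = m.values.std(axis=1, ddof=1)
    out = pd.DataFrame({"sd": sd, "selected": sd > sd_cutoff})
    out.index.name = "gene_id"
    return out


def hvg_ids(selection: pd.DataFrame) -> list[str]:
    return list(selection.index[selection["selected"]])
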