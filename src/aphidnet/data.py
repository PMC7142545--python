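"""Expression-matrix data model and IO.

The unit of observation is an RNA-seq library from one pea aphid *type*:
a (genotype, morph) combination.  Three genotypes (F1, I18, BK11) crossed
with five morphs (WF winged asexual female, UWF wingless asexual female,
SF wingless sexual female, WM winged male, UWM wingless male) give the 15
types of the study design; each type may carry several replicate libraries.

Matrices are FPKM-scale, genes in rows, samples (or types, after
aggregation) in columns, held as pandas DataFrames.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GENOTYPES = ("F1", "I18", "BK11")
MORPHS = ("WF", "UWF", "SF", "WM", "UWM")

#: morph -> (sex, wing state); derivable, never stored
MORPH_SEX = {"WF": "female", "UWF": "female", "SF": "female",
             "WM": "male", "UWM": "male"}
MORPH_WING = {"WF": "winged", "WM": "winged",
              "UWF": "wingless", "UWM": "wingless", "SF": "wingless"}


class DataError(ValueError):
    """Raised on malformed matrices or metadata."""


def _check_values(values: pd.DataFrame, nonnegative: bool = True) -> None:
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise DataError(f"duplicate gene ID: {dup!r}")
    if values.columns.duplicated().any():
        dup = values.columns[values.columns.duplicated()][0]
        raise DataError(f"duplicate sample ID: {dup!r}")
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        # locate first offending cell for the error message
        for j, col in enumerate(values.columns):
            coerced = pd.to_numeric(values[col], errors="coerce")
            bad = coerced.isna() & values[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise DataError(
                    f"non-numeric value at gene {values.index[i]!r}, "
                    f"sample {col!r}: {values.iloc[i, j]!r}")
        raise DataError("non-numeric values in matrix")
    if not np.isfinite(arr).all():
        raise DataError("matrix contains non-finite values")
    if nonnegative and (arr < 0).any():
        raise DataError("matrix contains negative values (FPKM must be >= 0)")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one library."""

    sample_id: str
    genotype: str
    morph: str
    replicate: int

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise DataError(f"unknown genotype {self.genotype!r} "
                            f"for sample {self.sample_id!r}")
        if self.morph not in MORPHS:
            raise DataError(f"unknown morph {self.morph!r} "
                            f"for sample {self.sample_id!r}")
        if int(self.replicate) < 1:
            raise DataError(f"replicate must be >= 1 for {self.sample_id!r}")

    @property
    def type_label(self) -> tuple[str, str]:
        return (self.genotype, self.morph)

    @property
    def sex(self) -> str:
        return MORPH_SEX[self.morph]

    @property
    def wing(self) -> str:
        return MORPH_WING[self.morph]


@dataclass
class ExpressionMatrix:
    """Replicate-level gene x sample FPKM matrix with sample metadata."""

    values: pd.DataFrame
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self):
        _check_values(self.values)
        ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != ids:
            raise DataError("sample metadata order does not match columns")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": [s.sample_id for s in self.samples],
             "genotype": [s.genotype for s in self.samples],
             "morph": [s.morph for s in self.samples],
             "replicate": [s.replicate for s in self.samples]})

    def morph_labels(self) -> np.ndarray:
        return np.array([s.morph for s in self.samples])

    def type_labels(self) -> list[tuple[str, str]]:
        return [s.type_label for s in self.samples]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.samples)


@dataclass
class TypeMatrix:
    """Gene x type matrix; one column per (genotype, morph) pair.

    ``N`` (the number of type columns) is the N of the tau statistic.
    ``scale`` records the current value scale; non-negativity is only
    enforced on the FPKM scale (log2/z-scored values may be negative).
    """

    values: pd.DataFrame
    types: list[tuple[str, str]] = field(default_factory=list)
    scale: str = "fpkm"

    def __post_init__(self):
        _check_values(self.values, nonnegative=self.scale == "fpkm")
        if len(self.types) != self.values.shape[1]:
            raise DataError("type labels do not match column count")
        if len(self.types) > 15:
            raise DataError("more than 15 (genotype, morph) types")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_types(self) -> int:
        return len(self.types)

    def subset_genes(self, gene_ids) -> "TypeMatrix":
        return TypeMatrix(self.values.loc[list(gene_ids)], self.types)


def type_column_name(genotype: str, morph: str) -> str:
    return f"{genotype}_{morph}"


def _delimiter_for(path: str) -> str:
    return "," if os.path.splitext(str(path))[1].lower() == ".csv" else "\t"


def read_matrix(matrix_path, meta_path) -> ExpressionMatrix:
    """Read a delimited expression matrix plus its sample-metadata table.

    The matrix file has gene IDs in the first column and a header row of
    sample IDs; the metadata file has columns sample_id, genotype, morph,
    replicate and must cover every sample column.  Column order in the
    returned matrix follows metadata order.
    """
    raw = pd.read_csv(matrix_path, sep=_delimiter_for(matrix_path),
                      index_col=0, dtype=str)
    meta = pd.read_csv(meta_path, sep=_delimiter_for(meta_path), dtype=str)
    required = {"sample_id", "genotype", "morph", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise DataError(f"metadata missing columns: {sorted(missing)}")
    meta_ids = list(meta["sample_id"])
    for col in raw.columns:
        if col not in meta_ids:
            raise DataError(f"sample column {col!r} has no metadata entry")
    for sid in meta_ids:
        if sid not in raw.columns:
            raise DataError(f"metadata sample {sid!r} not found in matrix")

    values = raw[meta_ids].copy()
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"non-numeric value at gene {values.index[i]!r}, "
                f"sample {col!r}: {values[col].iloc[i]!r}")
        values[col] = coerced
    samples = [SampleMeta(row.sample_id, row.genotype, row.morph,
                          int(row.replicate))
               for row in meta.itertuples(index=False)]
    return ExpressionMatrix(values, samples)


def write_matrix(m: ExpressionMatrix | TypeMatrix, path) -> None:
    """Write matrix as TSV, gene IDs in the first column."""
    out = m.values.copy()
    if isinstance(m, TypeMatrix):
        out.columns = [type_column_name(g, mo) for g, mo in m.types]
    out.index.name = "gene_id"
    out.to_csv(path, sep=_delimiter_for(path))


def write_metadata(m: ExpressionMatrix, path) -> None:
    m.meta_frame.to_csv(path, sep=_delimiter_for(path), index=False)


def filter_expressed(m, fpkm_cutoff: float = 0.5):
    """Retain genes whose maximum value is strictly above ``fpkm_cutoff``.

    The published filter calls a gene expressed at FPKM > 0.5; the
    comparison is strict, so a gene peaking exactly at the cutoff is
    dropped.  Works on either matrix flavour and preserves column set.
    """
    if fpkm_cutoff < 0:
        raise DataError("fpkm_cutoff must be non-negative")
    keep = m.values.max(axis=1) > fpkm_cutoff
    return replace(m, values=m.values.loc[keep])


def aggregate_types(m: ExpressionMatrix, method: str = "mean") -> TypeMatrix:
    """Collapse replicate columns into one column per (genotype, morph) type.

    Types appear in canonical order (genotype-major, morph-minor),
    restricted to the types present in the metadata.
    """
    if method not in ("mean", "median"):
        raise DataError(f"unknown aggregation method {method!r}")
    if m.values.size == 0:
        raise DataError("cannot aggregate an empty matrix")
    present = set(s.type_label for s in m.samples)
    types = [(g, mo) for g in GENOTYPES for mo in MORPHS if (g, mo) in present]
    cols = {}
    for g, mo in types:
        sel = [s.sample_id for s in m.samples if s.type_label == (g, mo)]
        block = m.values[sel]
        cols[type_column_name(g, mo)] = (block.mean(axis=1) if method == "mean"
                                         else block.median(axis=1))
    values = pd.DataFrame(cols, index=m.values.index)
    return TypeMatrix(values, types)


def log_transform(m: TypeMatrix, pseudocount: float = 1.0) -> TypeMatrix:
    """log2(v + pseudocount), elementwise."""
    if pseudocount <= 0:
        raise DataError("pseudocount must be positive")
    return replace(m, values=np.log2(m.values + pseudocount), scale="log2")


def inverse_log_transform(m: TypeMatrix, pseudocount: float = 1.0) -> TypeMatrix:
    if pseudocount <= 0:
        raise DataError("pseudocount must be positive")
    return replace(m, values=np.exp2(m.values) - pseudocount, scale="fpkm")


def mapping_rate(total_reads: int, mapped_reads: int) -> float:
    """Percentage of reads mapped, rounded to the nearest 0.1.

    Reproduces the arithmetic of a read-mapping summary table
    (rate = 100 x mapped / total).
    """
    if total_reads <= 0:
        raise DataError("total_reads must be positive")
    if mapped_reads < 0 or mapped_reads > total_reads:
        raise DataError("mapped_reads must lie in [0, total_reads]")
    return round(100.0 * mapped_reads / total_reads, 1)
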