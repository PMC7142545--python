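"""Synthetic expression matrices with planted structure.

The generator emulates the 15-type study design (3 genotypes x 5 morphs,
each with replicate libraries) and plants the three kinds of signal the
analysis is built to recover:

* **type-specific genes** — elevated by ``specific_fold`` in exactly one
  (genotype, morph) type; the tau-statistic recovery oracle;
* **co-expression modules** — groups of genes sharing a per-sample latent
  factor, with one designated hub loaded more strongly than the members;
  the network/core-gene recovery oracle;
* **morph markers** — elevated by ``marker_fold`` in all three genotypes
  of one morph; the random-forest recovery oracle.

A sex-biased gene block (elevated in all male or all female morphs) can
be planted as well: sex-dimorphic expression is the dominant axis of
variation in morph transcriptomes and is what makes same-sex samples
cluster together at the top of the sample dendrogram.  It is off by
default because such a block is itself a strong co-expression cluster
and would compete with the planted module hubs in network recovery; the
default configuration is the module/hub recovery condition.

Everything is simulated on the log2 scale and exponentiated to FPKM-like
values, which keeps expression non-negative without truncation.  The truth
record is machine-readable so tests can score recovery without downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import (GENOTYPES, MORPHS, ExpressionMatrix, SampleMeta,
                   write_matrix, write_metadata)


class SimulationError(ValueError):
    """Raised on infeasible simulation configurations."""


@dataclass
class SimConfig:
    """Generator settings.

    Planted genes (specific, module, marker) draw their baseline from a
    higher log2-normal than background — signal genes in real data are
    moderately-to-highly expressed — so fold changes and latent factors
    act on plausibly expressed genes.
    """

    n_genes: int = 1000
    n_replicates: int = 4
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.5
    planted_log2_mean: float = 5.0
    planted_log2_sd: float = 1.0
    n_specific_genes: int = 40
    specific_fold: float = 16.0
    n_modules: int = 5
    module_size: int = 25
    module_rho: float = 0.85
    hub_rho: float = 0.95
    n_markers_per_morph: int = 6
    marker_fold: float = 8.0
    n_sex_genes: int = 0
    sex_fold: float = 3.0
    noise_log2_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise SimulationError("n_genes and n_replicates must be positive")
        planted = (self.n_specific_genes
                   + self.n_modules * self.module_size
                   + len(MORPHS) * self.n_markers_per_morph
                   + self.n_sex_genes)
        if planted > self.n_genes:
            raise SimulationError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})")
        for name in ("baseline_log2_sd", "planted_log2_sd", "noise_log2_sd"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be strictly positive")
        for name in ("specific_fold", "marker_fold", "sex_fold"):
            if getattr(self, name) <= 1:
                raise SimulationError(f"{name} must exceed 1")
        for name in ("module_rho", "hub_rho"):
            if not 0 < getattr(self, name) < 1:
                raise SimulationError(f"{name} must lie in (0, 1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth; the recovery oracle for every stage."""

    specific_genes: dict = field(default_factory=dict)   # gene -> "GEN_MORPH"
    module_members: dict = field(default_factory=dict)   # module -> [genes]
    module_hubs: dict = field(default_factory=dict)      # module -> hub gene
    marker_genes: dict = field(default_factory=dict)     # morph -> [genes]
    sex_genes: dict = field(default_factory=dict)        # sex -> [genes]

    def all_marker_ids(self) -> list[str]:
        return [g for genes in self.marker_genes.values() for g in genes]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _loading(rho: float, noise_sd: float) -> float:
    # variance share of a unit-variance factor: a^2 / (a^2 + noise^2) = rho
    return noise_sd * np.sqrt(rho / (1.0 - rho))


def generate_dataset(cfg: SimConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate an FPKM matrix plus its planted-truth record.

    Reproducible bit-for-bit from ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    types = [(g, m) for g in GENOTYPES for m in MORPHS]
    samples = [SampleMeta(f"{g}_{m}_r{r}", g, m, r)
               for g, m in types for r in range(1, cfg.n_replicates + 1)]
    n_samp = len(samples)
    gene_ids = [f"g{i:05d}" for i in range(1, cfg.n_genes + 1)]

    # role assignment: leading blocks are planted, remainder is background
    truth = SyntheticTruth()
    cursor = 0
    specific_idx = list(range(cursor, cursor + cfg.n_specific_genes))
    cursor += cfg.n_specific_genes
    module_idx: list[list[int]] = []
    for _ in range(cfg.n_modules):
        module_idx.append(list(range(cursor, cursor + cfg.module_size)))
        cursor += cfg.module_size
    marker_idx: dict[str, list[int]] = {}
    for morph in MORPHS:
        marker_idx[morph] = list(range(cursor, cursor + cfg.n_markers_per_morph))
        cursor += cfg.n_markers_per_morph
    n_male_biased = cfg.n_sex_genes // 2
    sex_idx = {"male": list(range(cursor, cursor + n_male_biased)),
               "female": list(range(cursor + n_male_biased,
                                    cursor + cfg.n_sex_genes))}
    cursor += cfg.n_sex_genes
    planted = set(specific_idx)
    planted.update(i for mod in module_idx for i in mod)
    planted.update(i for idx in marker_idx.values() for i in idx)
    planted.update(i for idx in sex_idx.values() for i in idx)

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                          cfg.n_genes)
    if planted:
        pl = np.fromiter(sorted(planted), dtype=int)
        baseline[pl] = rng.normal(cfg.planted_log2_mean, cfg.planted_log2_sd,
                                  pl.size)

    log2 = baseline[:, None] + rng.normal(0.0, cfg.noise_log2_sd,
                                          (cfg.n_genes, n_samp))

    # type-specific genes, round-robin over the 15 types
    morph_cols = {m: np.array([j for j, s in enumerate(samples)
                               if s.morph == m]) for m in MORPHS}
    for k, gi in enumerate(specific_idx):
        g, m = types[k % len(types)]
        cols = [j for j, s in enumerate(samples) if s.type_label == (g, m)]
        log2[gi, cols] += np.log2(cfg.specific_fold)
        truth.specific_genes[gene_ids[gi]] = f"{g}_{m}"

    # co-expression modules: shared per-sample latent factor; first member
    # is the hub with the larger loading
    a_member = _loading(cfg.module_rho, cfg.noise_log2_sd)
    a_hub = _loading(cfg.hub_rho, cfg.noise_log2_sd)
    for mod_no, members in enumerate(module_idx, start=1):
        factor = rng.normal(0.0, 1.0, n_samp)
        hub = members[0]
        log2[hub] += a_hub * factor
        for gi in members[1:]:
            log2[gi] += a_member * factor
        name = f"module{mod_no}"
        truth.module_members[name] = [gene_ids[i] for i in members]
        truth.module_hubs[name] = gene_ids[hub]

    # morph markers: elevated in all three genotypes of one morph
    for morph, idx in marker_idx.items():
        if idx:
            truth.marker_genes[morph] = [gene_ids[i] for i in idx]
        for gi in idx:
            log2[gi, morph_cols[morph]] += np.log2(cfg.marker_fold)

    # sex-biased genes: elevated in every morph of one sex
    from .data import MORPH_SEX
    sex_cols = {sex: np.array([j for j, s in enumerate(samples)
                               if MORPH_SEX[s.morph] == sex])
                for sex in ("male", "female")}
    for sex, idx in sex_idx.items():
        if idx:
            truth.sex_genes[sex] = [gene_ids[i] for i in idx]
        for gi in idx:
            log2[gi, sex_cols[sex]] += np.log2(cfg.sex_fold)

    values = pd.DataFrame(np.exp2(log2), index=gene_ids,
                          columns=[s.sample_id for s in samples])
    return ExpressionMatrix(values, samples), truth


def write_dataset(matrix: ExpressionMatrix, truth: SyntheticTruth,
                  out_dir) -> dict:
    """Write matrix.tsv, metadata.tsv and truth.json into ``out_dir``."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    paths = {"matrix": os.path.join(out_dir, "matrix.tsv"),
             "metadata": os.path.join(out_dir, "metadata.tsv"),
             "truth": os.path.join(out_dir, "truth.json")}
    write_matrix(matrix, paths["matrix"])
    write_metadata(matrix, paths["metadata"])
    truth.to_json(paths["truth"])
    return paths
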