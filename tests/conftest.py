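import numpy as np
import pandas as pd
import pytest

from aphidnet.data import (GENOTYPES, MORPHS, ExpressionMatrix, SampleMeta,
                           TypeMatrix)
from aphidnet.pipeline import PipelineConfig
from aphidnet.simulate import SimConfig, generate_dataset

ALL_TYPES = [(g, m) for g in GENOTYPES for m in MORPHS]


def make_em(values, gene_ids=None, n_replicates=None, samples=None):
    """ExpressionMatrix from an array; columns default to 15 types x reps."""
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    if samples is None:
        n_replicates = n_replicates or values.shape[1] // 15
        samples = [SampleMeta(f"{g}_{m}_r{r}", g, m, r)
                   for g, m in ALL_TYPES
                   for r in range(1, n_replicates + 1)]
    frame = pd.DataFrame(values, index=gene_ids,
                         columns=[s.sample_id for s in samples])
    return ExpressionMatrix(frame, samples)


def make_tm(values, gene_ids=None, types=None, scale="fpkm"):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    if types is None:
        types = ALL_TYPES[:values.shape[1]]
    frame = pd.DataFrame(values, index=gene_ids,
                         columns=[f"{g}_{m}" for g, m in types])
    return TypeMatrix(frame, types, scale=scale)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 1000 genes, 15 types x 4 replicates."""
    return generate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_results(default_dataset):
    from aphidnet.model import MorphTranscriptomeModel
    matrix, _ = default_dataset
    return MorphTranscriptomeModel(matrix, PipelineConfig(seed=7)).fit()
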