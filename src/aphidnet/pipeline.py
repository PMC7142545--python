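"""End-to-end pipeline configuration and orchestration.

``run_pipeline`` composes the stages in the published order — expressed
-gene filter, tau specificity, HVG selection, MI network with DPI
pruning and core-gene calling, k-means expression patterns, and
random-forest marker ranking — writing every stage table plus a JSON
manifest of configuration, sub-seeds and per-stage counts.

A single seed governs all stochastic stages; per-stage sub-seeds are
derived from it so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, asdict

import numpy as np

from . import __version__
from .data import (ExpressionMatrix, read_matrix, write_matrix,
                   aggregate_types, filter_expressed, log_transform)
from .specificity import compute_tau, call_specific, specific_tally_by_morph
from .variability import select_hvg, hvg_ids
from .network import mi_matrix, dpi_prune, call_core_genes, export_network
from .patterns import zscore_rows, kmeans_patterns
from .markers import rank_markers, top_markers

log = logging.getLogger("aphidnet")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """All pipeline thresholds; defaults are the published values."""

    fpkm_cutoff: float = 0.5
    tau_cutoff: float = 0.8
    sd_cutoff: float = 6.0
    dpi_tolerance: float = 0.0
    edge_mi_min: float = 0.4
    core_min_degree: int = 20
    core_mean_mi: float = 0.4
    display_mi: float = 0.5
    k_patterns: int = 6
    kmeans_n_init: int = 50
    top_n_markers: int = 30
    n_trees: int = 1000
    marker_label: str = "morph"
    aggregate_method: str = "mean"
    filter_before_aggregate: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sub_seeds(self) -> dict:
        ss = np.random.SeedSequence(self.seed)
        kmeans_seed, forest_seed = (int(s) % (2**31 - 1)
                                    for s in ss.generate_state(2))
        return {"kmeans": kmeans_seed, "forest": forest_seed}


def run_pipeline(cfg: PipelineConfig, matrix=None, meta_path=None,
                 out_dir=None, matrix_path=None) -> dict:
    """Run every stage; return the manifest dict.

    ``matrix`` may be an in-memory ExpressionMatrix, or give
    ``matrix_path`` + ``meta_path`` to read from files.  If ``out_dir``
    is set, all stage tables and the manifest are written there.
    """
    from .model import MorphTranscriptomeModel

    if matrix is None:
        if matrix_path is None or meta_path is None:
            raise PipelineError("input", "give matrix or matrix_path+meta_path")
        try:
            matrix = read_matrix(matrix_path, meta_path)
        except Exception as exc:
            raise PipelineError("read_matrix", str(exc)) from exc
    results = MorphTranscriptomeModel(matrix, cfg).fit()
    if out_dir is not None:
        results.write(out_dir)
    return results.manifest


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def build_manifest(cfg: PipelineConfig, counts: dict, extras: dict) -> dict:
    return {"package": "aphidnet", "version": __version__,
            "config": asdict(cfg), "sub_seeds": cfg.sub_seeds(),
            "stage_counts": counts, **extras}
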