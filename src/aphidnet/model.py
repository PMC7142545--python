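"""Model/Results interface over the full analysis.

``MorphTranscriptomeModel`` is built from an expression matrix plus
sample metadata; ``fit()`` runs the stages in the published order and
returns a ``MorphTranscriptomeResults`` carrying every stage table, the
network, per-stage counts, a ``summary()`` report and plot helpers.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .data import (ExpressionMatrix, TypeMatrix, aggregate_types,
                   filter_expressed, log_transform, write_matrix)
from .specificity import compute_tau, call_specific, specific_tally_by_morph
from .variability import select_hvg, hvg_ids
from .network import MINetwork, mi_matrix, dpi_prune, call_core_genes, \
    export_network
from .patterns import zscore_rows, kmeans_patterns, PatternAssignment
from .markers import rank_markers, top_markers


class MorphTranscriptomeModel:
    """Morph-resolved co-expression analysis of an FPKM matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Replicate-level gene x sample FPKM matrix with metadata.
    config : PipelineConfig, optional
        Thresholds and seed; defaults are the published values.
    """

    def __init__(self, matrix: ExpressionMatrix, config=None):
        from .pipeline import PipelineConfig
        self.matrix = matrix
        self.config = config if config is not None else PipelineConfig()

    @classmethod
    def from_files(cls, matrix_path, meta_path, config=None):
        from .data import read_matrix
        return cls(read_matrix(matrix_path, meta_path), config)

    def fit(self, seed: int | None = None) -> "MorphTranscriptomeResults":
        """Run all stages; ``seed`` overrides the config seed."""
        import dataclasses
        from .pipeline import PipelineError
        cfg = self.config
        if seed is not None:
            cfg = dataclasses.replace(cfg, seed=int(seed))
        seeds = cfg.sub_seeds()

        def stage(name, fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        em = self.matrix
        if cfg.filter_before_aggregate:
            em = stage("filter", lambda: filter_expressed(em, cfg.fpkm_cutoff))
            tm = stage("aggregate",
                       lambda: aggregate_types(em, cfg.aggregate_method))
            tm_f = tm
        else:
            tm = stage("aggregate",
                       lambda: aggregate_types(em, cfg.aggregate_method))
            tm_f = stage("filter",
                         lambda: filter_expressed(tm, cfg.fpkm_cutoff))
        if tm_f.values.shape[0] == 0:
            raise PipelineError(
                "specificity", "no genes pass the expressed-gene filter; "
                "nothing to analyse")

        tau = stage("specificity",
                    lambda: call_specific(compute_tau(tm_f), cfg.tau_cutoff))
        hvg = stage("variability", lambda: select_hvg(tm_f, cfg.sd_cutoff))
        hv_ids = hvg_ids(hvg)

        net = pruned = core = None
        if len(hv_ids) >= 2:
            net = stage("network", lambda: mi_matrix(em, hv_ids))
            pruned = stage("network",
                           lambda: dpi_prune(net, cfg.dpi_tolerance))
            core = stage("network",
                         lambda: call_core_genes(pruned, cfg.edge_mi_min,
                                                 cfg.core_min_degree,
                                                 cfg.core_mean_mi))

        zs = stage("patterns",
                   lambda: zscore_rows(log_transform(tm_f)))
        k = min(cfg.k_patterns, zs.values.shape[0])
        pats = stage("patterns",
                     lambda: kmeans_patterns(zs, k, cfg.kmeans_n_init,
                                             seeds["kmeans"]))

        em_f = stage("markers",
                     lambda: em.subset_genes(tm_f.gene_ids))
        rankings = stage("markers",
                         lambda: rank_markers(em_f, cfg.marker_label,
                                              cfg.n_trees, seeds["forest"]))
        top = top_markers(rankings, min(cfg.top_n_markers, len(rankings)))
        return MorphTranscriptomeResults(
            model=self, config=cfg, type_matrix=tm, filtered=tm_f,
            tau_table=tau, hvg_table=hvg, network=net, pruned_network=pruned,
            core_table=core, zscored=zs, patterns=pats,
            marker_table=rankings, top_marker_ids=top)


class MorphTranscriptomeResults:
    """Fitted analysis: stage tables, network, counts and reporting."""

    def __init__(self, model, config, type_matrix, filtered, tau_table,
                 hvg_table, network, pruned_network, core_table, zscored,
                 patterns, marker_table, top_marker_ids):
        self.model = model
        self.config = config
        self.type_matrix = type_matrix
        self.filtered = filtered
        self.tau_table = tau_table
        self.hvg_table = hvg_table
        self.network = network
        self.pruned_network = pruned_network
        self.core_table = core_table
        self.zscored = zscored
        self.patterns = patterns
        self.marker_table = marker_table
        self.top_marker_ids = top_marker_ids

    # ------------------------------------------------------------------
    @property
    def specific_genes(self) -> list[str]:
        t = self.tau_table
        return list(t.index[t["is_specific"]])

    @property
    def core_genes(self) -> list[str]:
        if self.core_table is None:
            return []
        return list(self.core_table.index[self.core_table["is_core"]])

    @property
    def stage_counts(self) -> dict:
        cfg = self.config
        counts = {
            "n_genes_input": self.model.matrix.n_genes,
            "n_samples": len(self.model.matrix.samples),
            "n_types": self.type_matrix.n_types,
            "n_genes_expressed": self.filtered.values.shape[0],
            "n_specific": len(self.specific_genes),
            "n_hvg": int(self.hvg_table["selected"].sum()),
            "n_core": len(self.core_genes),
            "n_pattern_clusters": self.patterns.k,
            "pattern_sizes": {str(c): int(s) for c, s in
                              self.patterns.cluster_sizes().items()},
            "n_top_markers": len(self.top_marker_ids),
        }
        if self.pruned_network is not None:
            net = self.pruned_network
            counts["n_edges_total"] = net.n_edges()
            counts["n_edges_unpruned"] = net.n_edges(include_pruned=False)
            counts["n_edges_display"] = net.n_edges(
                min_mi=cfg.display_mi, include_pruned=False)
        return counts

    @property
    def manifest(self) -> dict:
        from .pipeline import build_manifest
        return build_manifest(
            self.config, self.stage_counts,
            {"top_markers": list(self.top_marker_ids),
             "specific_by_morph": {str(k): int(v) for k, v in
                                   specific_tally_by_morph(
                                       self.tau_table).items()}})

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable run report."""
        c = self.stage_counts
        cfg = self.config
        lines = [
            "Morph transcriptome analysis",
            "=" * 60,
            f"genes x samples          {c['n_genes_input']} x {c['n_samples']}"
            f"  ({c['n_types']} types)",
            f"expressed (FPKM > {cfg.fpkm_cutoff})"
            f"      {c['n_genes_expressed']}",
            f"tau-specific (tau > {cfg.tau_cutoff})  {c['n_specific']}",
            f"highly variable (sd > {cfg.sd_cutoff:g})  {c['n_hvg']}",
        ]
        if "n_edges_total" in c:
            lines += [
                f"MI edges (pre/post DPI)  {c['n_edges_total']} / "
                f"{c['n_edges_unpruned']}"
                f"  (display MI > {cfg.display_mi}: {c['n_edges_display']})",
            ]
        lines += [
            f"core genes (deg >= {cfg.core_min_degree}, "
            f"mean MI > {cfg.core_mean_mi})  {c['n_core']}",
            f"expression patterns (k)  {c['n_pattern_clusters']}"
            f"  sizes {list(c['pattern_sizes'].values())}",
            f"top markers (Gini)       {c['n_top_markers']}",
        ]
        tally = specific_tally_by_morph(self.tau_table)
        if len(tally):
            lines.append("specific genes by morph  "
                         + ", ".join(f"{m}: {n}" for m, n in tally.items()))
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def write(self, out_dir) -> dict:
        """Write every stage table plus the JSON manifest."""
        from .pipeline import write_manifest
        os.makedirs(out_dir, exist_ok=True)
        cfg = self.config
        p = lambda name: os.path.join(out_dir, name)
        write_matrix(self.filtered, p("filtered_matrix.tsv"))
        self.tau_table.to_csv(p("tau.tsv"), sep="\t")
        self.hvg_table.to_csv(p("hvg.tsv"), sep="\t")
        if self.pruned_network is not None:
            self.pruned_network.edge_frame().to_csv(
                p("edges_all.tsv"), sep="\t", index=False)
            export_network(self.pruned_network, p("network_display.tsv"),
                           cfg.display_mi, "edge_list_tsv")
            export_network(self.pruned_network, p("network_display.gml"),
                           cfg.display_mi, "gml")
            self.core_table.to_csv(p("core_genes.tsv"), sep="\t")
        self.patterns.labels.to_csv(p("patterns.tsv"), sep="\t")
        self.patterns.centroids.to_csv(p("pattern_centroids.tsv"), sep="\t")
        self.marker_table.to_csv(p("markers.tsv"), sep="\t")
        write_manifest(self.manifest, p("manifest.json"))
        return self.manifest

    # ------------------------------------------------------------------
    def plot_patterns(self, ax=None):
        """Line plot of the k pattern centroids across types."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        for cluster, row in self.patterns.centroids.iterrows():
            ax.plot(row.values, label=f"pattern {cluster}")
        ax.set_xticks(range(len(self.patterns.centroids.columns)))
        ax.set_xticklabels(self.patterns.centroids.columns, rotation=90,
                           fontsize=7)
        ax.set_ylabel("z-scored expression")
        ax.legend(fontsize=7)
        return ax

    def plot_marker_importance(self, top_n: int = 30, ax=None):
        """Horizontal bar plot of the top marker Gini importances."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 7))
        sub = self.marker_table.sort_values("rank_gini").head(top_n)
        ax.barh(sub.index[::-1], sub["mean_decrease_gini"][::-1])
        ax.set_xlabel("mean decrease Gini")
        ax.tick_params(axis="y", labelsize=6)
        return ax
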