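# aphidnet

Morph-resolved transcriptome analysis for the pea aphid *Acyrthosiphon
pisum*. The pea aphid produces discrete morphs — winged/wingless asexual
females (WF/UWF), wingless sexual females (SF), and winged/wingless males
(WM/UWM) — from the same genotype, and expression profiling of the 15
genotype × morph types (3 genotypes × 5 morphs) is a standard route to the
genes behind this polyphenism. `aphidnet` packages that analysis for any
FPKM-scale gene × sample matrix with genotype/morph/replicate metadata:

* **tau specificity** — per gene, over the N type columns,
  `tau = Σᵢ (1 − xᵢ) / (N − 1)` with `xᵢ = vᵢ / maxⱼ vⱼ`; genes with
  `tau > 0.8` are called type-specifically expressed;
* **highly variable genes (HVGs)** — per-gene sample SD across types on the
  linear FPKM scale, cutoff `sd > 6`;
* **MI co-expression network** — ARACNE-style: rank-based equal-frequency
  binned mutual information (nats, Miller–Madow corrected) for all HVG
  pairs, pruned by the data-processing inequality (the weakest edge of
  every triangle is presumed indirect); **core genes** have ≥ 20
  co-expressed partners with mean edge MI > 0.4;
* **expression patterns** — row z-scored profiles clustered by k-means
  (k = 6 by default);
* **morph markers** — random-forest importance (mean decrease Gini and
  out-of-bag mean decrease accuracy) of every gene for classifying morphs,
  reporting the top 30 by Gini.

A synthetic-data generator reproduces the 15-type design with planted
type-specific genes, co-expression modules with designated hubs, and morph
markers, plus a machine-readable truth record — so the whole pipeline is
testable end-to-end without any download.

## Worked example

```python
from aphidnet import (MorphTranscriptomeModel, PipelineConfig,
                      SimConfig, generate_dataset)

matrix, truth = generate_dataset(SimConfig(seed=1))   # 1000 genes, 15x4
results = MorphTranscriptomeModel(matrix, PipelineConfig(seed=7)).fit()
print(results.summary())
```

```
Morph transcriptome analysis
============================================================
genes x samples          1000 x 60  (15 types)
expressed (FPKM > 0.5)      999
tau-specific (tau > 0.8)  49
highly variable (sd > 6)  254
MI edges (pre/post DPI)  22066 / 1008  (display MI > 0.5: 180)
core genes (deg >= 20, mean MI > 0.4)  0
expression patterns (k)  6  sizes [194, 172, 170, 158, 154, 151]
top markers (Gini)       30
specific genes by morph  WM: 11, SF: 10, UWF: 10, UWM: 9, WF: 9
```

Reading this: 999 of 1000 genes pass the expressed filter; the 49
tau-specific calls contain all 40 planted specific genes (the extras are
planted markers whose morph-restricted expression also scores high); 254
HVGs enter the network; strict DPI collapses the 22 066 candidate edges to
a 1 008-edge backbone in which the five planted module hubs are the five
highest-degree genes. No gene reaches 20 partners at this desk scale —
with 25-gene modules the DPI backbone keeps hub degrees near 10 — so the
core-gene rule, written for transcriptome-scale networks, calls zero genes
here and hub recovery is read from the degree ranking instead.
`results.top_marker_ids` recovers the 30 planted morph markers;
`results.tau_table`, `.core_table`, `.marker_table`, `.patterns` hold the
full per-gene tables, `results.write(out_dir)` exports them as TSV/GML
with a JSON manifest, and `results.plot_patterns()` /
`.plot_marker_importance()` draw the standard figures.

The same stages are available as a CLI (`aphidnet simulate`, `tau`,
`hvg`, `network`, `patterns`, `markers`, `run`) and the bundled
read-mapping summary of the 15 real libraries
(`aphidnet.datasets.read_mapping_summary()`) supports the mapping-rate
arithmetic (e.g. library F1_WF: 79 389 596 / 93 097 593 mapped → 85.3%).

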