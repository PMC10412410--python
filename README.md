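# rareclust

Silhouette-guided iterative reclustering for rare cell type discovery in
single-cell RNA-seq.

## The problem

Single-pass clustering of scRNA-seq data has to pick one neighborhood size
*k* and one resolution *r* for the whole dataset. Settings that keep large,
homogeneous cell types intact will merge rare subpopulations (a percent or
less of cells) into their nearest neighbors; settings aggressive enough to
isolate rare cells shred homogeneous clusters into spurious pieces. No
single (k, r) serves both scales, because the expression divergence between
broad cell types and the divergence between closely related subtypes are
not comparable.

`rareclust` resolves this with a multi-step, optionally semi-supervised
procedure:

1. **Conservative broad pass** — SNN-graph community detection
   (Leiden/Louvain, default k=20, r=0.3) that deliberately under-splits.
2. **Heterogeneity estimation** — per-cell silhouette scores under cosine
   distance on the PCA embedding. For cell *i* in cluster *C_m*:

   a(i) = (1/(|C_m|−1)) Σ_{j∈C_m, j≠i} d(i,j),
   b(i) = min_{l≠m} (1/|C_l|) Σ_{j∈C_l} d(i,j),
   s(i) = (b(i) − a(i)) / max(a(i), b(i)),

   with d(i,j) = 1 − cos(x_i, x_j). A cluster's *coefficient* is the mean
   of s(i) over its cells; its *median* s(i) flags heterogeneity: clusters
   whose median falls below a threshold (default 0.4) become reclustering
   candidates, and `force_include` / `force_exclude` let biological
   knowledge override the statistic in either direction.
3. **Local reclustering** — inside each candidate, highly variable genes
   and the PCA subspace are recomputed *from that cluster's cells only*,
   so genes that distinguish subtypes but are invisible dataset-wide drive
   the split. A grid of (k, r) values is swept; each resulting
   sub-partition is scored by its mean per-cell silhouette on the local
   embedding and the argmax wins. The winning split is applied only if it
   scores at least `accept_min_coef` (default 0.25) — homogeneous clusters
   fail this bar and are left untouched, which is the overclustering
   guard. Cells outside candidates keep their labels bit-identically.
4. **Marker genes** — a two-step test for each (sub)cluster: Wilcoxon
   rank-sum against a *chosen* background (typically the closely related
   clusters), then removal of any candidate that is among the top-10%
   expressed genes of an unrelated cluster. The filter kills genes that
   look enriched only because the background happens to lack them.

A negative-binomial simulator with planted broad + rare cluster structure
(and ground-truth labels, fold-changes and marker sets) makes the whole
loop testable without any downloads, and ARI/NMI utilities quantify
recovery.

## Worked example

```bash
python examples/02_full_pipeline.py
```

```
broad pass: 6 clusters  ->  final: 7 clusters
ARI broad  = 0.9939
ARI final  = 1.0000
NMI final  = 1.0000

pipeline log:
  depth 0: 3: best split scores 0.170 < accept_min_coef; kept intact
  depth 0: 0: best split scores 0.147 < accept_min_coef; kept intact
  ...
  candidate 5: best local silhouette 0.328 (accepted)
```

The simulated benchmark has seven true clusters; two of them are ~3% rare
clusters sharing >80% of their expression program, so the conservative
broad pass merges them into one 60-cell community (6 clusters, ARI
0.994). The pipeline flags low-silhouette clusters, rejects splits of the
five homogeneous ones (local silhouettes ≈ 0.15), accepts the one genuine
split (0.328), and recovers all seven clusters exactly (ARI = NMI = 1.0).

The other examples walk the individual stages: `01` the broad pass and
silhouette summary, `03` two-step marker identification, `04` a benchmark
against k-means, hierarchical clustering and single-pass Louvain.

## Command line

Every stage is also a subcommand of the `rareclust` CLI — `simulate`,
`cluster`, `silhouette`, `recluster`, `markers`, `pipeline`, `benchmark` —
reading 10x-style MTX triplets or dense TSV matrices, driven by a YAML
config with flag overrides, and writing TSV outputs plus a `manifest.json`
that makes each run reproducible from its recorded config and seed.

```bash
rareclust simulate --seed 1 --out sim/
rareclust pipeline --input sim/ --seed 1 --out run/
rareclust markers --input sim/ --labels run/labels.tsv \
    --target 5.0 --background 5.1 --out markers/
```

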