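# Methods

## Model and procedure

`rareclust` treats rare cell type discovery as a two-scale clustering
problem. The broad pass clusters all cells on a global embedding; a
per-cluster heterogeneity statistic then decides where a second, locally
re-featurized clustering pass is warranted; winning sub-partitions are
integrated back without touching any other cell. The pipeline iterates
(default two rounds) so accepted subclusters can themselves be examined.

**Preprocessing.** Counts are library-size normalized to a fixed scale
factor (default 1e4) and log1p-transformed, making each cell's profile
invariant to sequencing depth; all-zero cells are dropped with a warning.
Highly variable genes are ranked by the residual of log10 gene variance
around a lowess trend in log10 mean (span 0.3), standardized by the
residual spread — a variance-stabilizing-style score that corrects for the
mean–variance relationship; a plain dispersion score (variance/mean on the
de-logged scale) is available as a simpler alternative. The selected
submatrix is z-scored per gene with values clipped at ±10 to bound outlier
leverage, then reduced by exact full-SVD PCA (default 30 components),
which is deterministic for fixed input.

**Silhouette under cosine distance.** Distances are cosine on the PCA
embedding (cosine is scale-free and behaves better than Euclidean in high
dimension; computing it in PCA space keeps the cost O(n²d) with d ≪
genes). The per-cell silhouette uses the standard form s = (b−a)/max(a,b),
so +1 means "far from everything else", 0 "on a cluster boundary". Cells
in singleton clusters get the conventional sentinel s = 0; a single
cluster overall is a domain error (b is undefined). The implementation
reduces the pairwise computation to one matmul against per-cluster sums
of unit rows and is verified against a brute-force double loop at 1e-10
and scikit-learn's cosine silhouette at 1e-8. Above a configurable cap
(default 10 000 cells) the score is estimated on a seeded per-cluster
subsample (≥50 cells per cluster); exact mode is always available.

**Graph clustering.** The SNN graph connects cells by the Jaccard overlap
of their k-nearest-neighbor sets (Euclidean in the embedding, self
included), pruned at 1/15. Community detection is Leiden (RB-configuration
modularity) by default, or igraph's multilevel Louvain; labels are
canonicalized 0..K−1 by decreasing size with ties broken by the smallest
member index, so runs are reproducible for a fixed seed.

**Flag liberally, split conservatively.** Candidates are clusters whose
median per-cell silhouette falls below a threshold, plus/minus the
semi-supervised `force_include`/`force_exclude` sets. Two numerical
observations shaped the defaults. First, the scale of cosine-PCA
silhouettes is data-dependent, and a merged rare pair sits near its
parent cluster: by the time its median drops to very low values, the
broad pass itself would already have split it — so a tight flagging
threshold almost never fires. Second, forcing a split on a homogeneous
cluster yields a *local* silhouette far below that of a genuine split
(≈0.15 vs ≈0.3+ on the benchmark), because a single blob re-centered by
its own PCA has near-random cosine angles. The defaults therefore flag
liberally (threshold 0.4) and let the acceptance bar on the winning local
score (`accept_min_coef` = 0.25) discriminate: homogeneous candidates are
examined and kept intact; genuinely structured ones are split. Both knobs
are config keys.

**Local reclustering.** Within a candidate (or an explicit union of
related candidates, e.g. two T-cell clusters combined by the user), HVGs
are re-selected from all genes using only the candidate's cells — genes
flat globally but bimodal inside the candidate now rank highly — and a
fresh PCA is computed. Defaults for this local stage are 500 HVGs and 10
components (`recluster.n_hvgs`, `recluster.n_pcs`): a subset holds fewer
distinct populations than the full dataset, so a tighter feature space
raises the signal-to-noise of the split. Each grid point (k ∈ {10, 20,
30, 50} × r ∈ {0.4, 0.6, 0.8, 1.0, 1.2} by default) is clustered and
scored by the mean per-cell silhouette of the sub-partition on the local
embedding (median scoring is config-selectable); partitions with one
community or any subcluster below 5 cells are discarded. Ties break
toward the most conservative split: fewest subclusters, then smallest k,
then smallest r. Candidates below 50 cells are not reclustered.

**Markers.** Step 1 is a per-gene two-sided Wilcoxon rank-sum test
(asymptotic, tie-corrected) of the target versus a chosen background on
normalized expression, BH-corrected, with candidates requiring
p_adj < 0.05 and log2 fold-change > 0.25 (fold-change of expm1-scale means
with pseudocount 1). Step 2 removes candidates present in the
top-expressed set (ceil(pct·n_genes) genes by mean normalized expression,
default pct = 0.10) of any cluster outside the target and the exempt set.
Exempt defaults to the step-1 background — those clusters were contrasted
directly, so high expression there is evidence *for* the contrast, not
against specificity; `strict` mode exempts nothing. Final tables are
ranked by log2 fold-change (some conventions rank by raw fold-change; the
ordering is identical).

## The simulator: what it emulates and what it does not

The generator draws per-gene baseline rates from a log-normal (long tail
of high expressors), gives each broad cluster a random program of
`de_frac` of genes with log2 fold-changes ~ N(lfc_mean, lfc_sd) of random
sign, scales by per-cell log-normal library sizes, and draws counts from a
negative binomial with shared dispersion θ (variance m + m²/θ). A *rare
pair* is two small clusters that inherit a fraction of a parent broad
cluster's program, share an extra program, and differ only in small
private marker sets.

The shipped benchmark (`fig2d_like.yaml`): 1000 cells × 2000 genes, five
broad clusters of 18.8% and two rare clusters of 3%, programs of 100
genes at lfc ≈ 2, θ = 2, libraries ≈ 2500 counts. The pair inherits 60%
of the parent program, shares a 45-gene extra program (lfc ≈ 2) and
carries 25 private markers each (lfc ≈ 2.6), so 81% of each rare program
is shared with its sibling. The partial inheritance matters: a pair that
inherits the *full* parent program lies farther from the origin along the
parent's own direction, which under cosine distance makes it look
artificially tight and far; real related subtypes overlap with, rather
than extend, their parent's program. Effect sizes are at the strong end
of realistic so that the planted structure is unambiguous: under these
conditions the conservative broad pass merges the rare pair into one
60-cell community in ~9 of 10 seeds, and the local stage separates it
cleanly — the regime the method is designed for.

What the simulation does **not** reproduce: dropout beyond NB sampling,
per-gene dispersion variation, correlated gene modules, batch effects,
doublets, or continuous (trajectory-like) structure. Passing tests on it
certify the machinery — statistic correctness, argmax exactness,
integration safety, recovery in the planted regime — not performance on
any particular tissue.

Problem sizes throughout the tests and the acceptance script (1000 cells,
2000 genes, 10 replicate seeds) were chosen as the smallest at which the
rare-pair regime is stable; clustering-agreement metrics are validated
against scikit-learn and hand enumeration at 1e-10.

## Numerical choices and degenerate inputs

- Cosine distance of a zero vector is a domain error, never NaN; zero
  embedding rows cannot occur after PCA except for exact duplicates of
  the mean, and are reported by cell id.
- Pairwise distances are computed blockwise (bounded peak memory),
  clipped to [0, 2], exactly symmetrized, zero diagonal.
- HVG ranking is a stable sort (score desc, then gene order), so results
  do not depend on sort internals; zero-variance genes score −inf.
- n_pcs is clamped to min(n_cells−1, n_hvgs−1) inside the pipeline
  (explicit calls raise instead).
- Grid evaluation is pure per point and merged deterministically; the
  edge-less SNN graph yields singletons with a warning.
- Cluster labels are strings end to end; hierarchical labels are
  "<parent>.<sub>" (unions join parents with "+").

## Known limitations

- Flagging uses the median per-cell silhouette; a rare subpopulation
  hidden inside a much larger parent barely moves that median, so fully
  merged parent+rare clusters are mostly caught by the liberal threshold
  plus the local acceptance bar, or by `force_include` — this is why the
  semi-supervised surface is first-class.
- Silhouette scale depends on the embedding dimension and noise level;
  thresholds are comparable across runs of one dataset, not across
  datasets.
- Cross-sample batch integration inside candidates is out of scope; the
  pipeline assumes one batch.
- External-data checks (e.g. the classic 3k PBMC dataset) require
  downloads and are not part of the test suite; the simulation benchmark
  is the self-contained acceptance surface.
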