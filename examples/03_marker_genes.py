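"""Two-step marker identification for one rare cluster.

Step 1 contrasts the target against its closest relative (its rare
sibling) with a Wilcoxon rank-sum test; step 2 removes candidates that
are among the top-10% expressed genes of unrelated clusters.  Genes that
pass are specific markers; genes removed by the filter looked enriched
only because the background happened to lack them."""

from rareclust import (
    ClusterLabels,
    candidate_markers,
    default_spec,
    filter_markers,
    normalize,
    simulate_counts,
    top_expressed_sets,
)

matrix, truth = simulate_counts(default_spec(seed=1))
norm = normalize(matrix)
labels = ClusterLabels(truth.labels.astype(object), norm.cell_ids)

target, background = "rare0", {"rare1"}
candidates = candidate_markers(norm, labels, target, background)
tops = top_expressed_sets(norm, labels, pct=0.10)
table = filter_markers(candidates, tops, target, exempt=background)

passed = table[table["passed_filter"]]
true_markers = set(truth.marker_genes[target])
print(f"{len(candidates)} step-1 candidates for {target} vs {background}; "
      f"{len(passed)} pass the specificity filter")
print(f"planted private markers recovered: "
      f"{len(set(passed['gene_id']) & true_markers)}/{len(true_markers)}")
print("\ntop 5 markers by log2 fold-change:")
cols = ["gene_id", "log2_fc", "p_adj", "pct_target", "pct_background"]
print(passed.head(5)[cols].round(3).to_string(index=False))
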