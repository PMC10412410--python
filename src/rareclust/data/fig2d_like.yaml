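# Default rare-pair benchmark: 1000 cells, 2000 genes, five broad clusters
# (~19% each) and one pair of ~3% rare clusters.  The pair inherits 60% of
# broad0's 100-gene program, adds a shared 45-gene program, and each member
# carries 25 private marker genes (so >80% of each rare cluster's program
# is shared with its sibling).  The partial inheritance plus shared program
# place the pair adjacent to each other and near broad0 in embedding space,
# where a conservative clustering pass merges the two rare clusters into
# one community.
n_cells: 1000
n_genes: 2000
proportions:
  broad0: 0.188
  broad1: 0.188
  broad2: 0.188
  broad3: 0.188
  broad4: 0.188
  rare0: 0.03
  rare1: 0.03
de_frac: 0.05
lfc_mean: 2.0
lfc_sd: 0.3
nb_dispersion: 2.0
baseline_log_mean: 0.0
baseline_log_sd: 1.2
library_log_mean: 7.824
library_log_sd: 0.35
rare_pairs:
  - parent: broad0
    members: [rare0, rare1]
    shared_extra: 45
    private: 25
    private_lfc_mean: 2.6
    shared_lfc_mean: 2.0
    inherit_frac: 0.6
seed: 0
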