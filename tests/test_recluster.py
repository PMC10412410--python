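import numpy as np
import pandas as pd
import pytest

from rareclust.config import RunConfig
from rareclust.errors import DomainError, ParameterError, ValidationError
from rareclust.io import ExpressionMatrix
from rareclust.recluster import (
    ReclusterParams,
    ReclusterResult,
    flag_candidates,
    integrate_labels,
    recluster_one,
    run_pipeline,
)
from rareclust.silhouette import ClusterLabels
from rareclust.simulate import (
    SimSpec,
    adjusted_rand_index,
    default_spec,
    simulate_counts,
)

GRID = [
    ReclusterParams(k=k, r=r, n_pcs=10, n_hvgs=200)
    for k in (10, 20) for r in (0.4, 0.8, 1.2)
]


def _summary(medians):
    return pd.DataFrame(
        {
            "cluster": list(medians),
            "n": [100] * len(medians),
            "coef": list(medians.values()),
            "median": list(medians.values()),
        }
    )


class TestFlagCandidates:
    def test_threshold_rule(self):
        out = flag_candidates(_summary({"A": 0.6, "B": 0.1}), threshold=0.25)
        assert out == ["B"]

    def test_force_include_appended(self):
        out = flag_candidates(
            _summary({"A": 0.6, "B": 0.1}), threshold=0.25,
            force_include={"A"},
        )
        assert out == ["B", "A"]

    def test_nothing_flagged(self):
        assert flag_candidates(
            _summary({"A": 0.6, "B": 0.5}), threshold=0.25
        ) == []

    def test_force_exclude_wins_over_threshold(self):
        out = flag_candidates(
            _summary({"A": 0.1, "B": 0.05}), threshold=0.25,
            force_exclude={"A"},
        )
        assert out == ["B"]

    def test_unknown_force_cluster_rejected(self):
        with pytest.raises(ValidationError):
            flag_candidates(
                _summary({"A": 0.6}), force_include={"nope"}
            )


@pytest.fixture(scope="module")
def hidden_pair_sim():
    """Three well-separated populations; the test merges two of them into
    one 'broad' cluster so reclustering has something real to find."""
    spec = SimSpec(
        n_cells=400,
        n_genes=600,
        proportions={"A": 0.5, "B0": 0.25, "B1": 0.25},
        de_frac=0.05,
        lfc_mean=2.5,
        lfc_sd=0.2,
        rare_pairs=[],
        seed=21,
    )
    matrix, truth = simulate_counts(spec)
    merged = np.where(
        np.isin(truth.labels, ["B0", "B1"]), "B", "A"
    ).astype(object)
    return matrix, truth, ClusterLabels(merged, matrix.cell_ids)


class TestReclusterOne:
    def test_splits_hidden_subpopulations(self, hidden_pair_sim):
        matrix, truth, merged = hidden_pair_sim
        res = recluster_one(matrix, merged, "B", GRID, seed=0)
        assert res.best is not None
        mask = merged.labels.astype(str) == "B"
        ari = adjusted_rand_index(
            truth.labels[mask], res.sub_labels.labels
        )
        assert ari == pytest.approx(1.0)

    def test_best_is_grid_argmax(self, hidden_pair_sim):
        matrix, _, merged = hidden_pair_sim
        res = recluster_one(matrix, merged, "B", GRID, seed=0)
        kept = res.grid[res.grid["kept"]]
        assert res.best_coef == pytest.approx(kept["coef"].max())

    def test_homogeneous_cluster_scores_low_or_none(self):
        spec = SimSpec(
            n_cells=200, n_genes=400,
            proportions={"only": 1.0}, de_frac=0.0,
            rare_pairs=[], seed=22,
        )
        matrix, _ = simulate_counts(spec)
        labels = ClusterLabels(
            np.repeat("only", 200).astype(object), matrix.cell_ids
        )
        res = recluster_one(matrix, labels, "only", GRID, seed=0)
        assert res.best is None or res.best_coef < 0.25

    def test_single_element_grid(self, hidden_pair_sim):
        matrix, _, merged = hidden_pair_sim
        res = recluster_one(matrix, merged, "B", [GRID[2]], seed=0)
        assert res.best == GRID[2] or res.best is None

    def test_small_subset_is_domain_error(self, hidden_pair_sim):
        matrix, _, merged = hidden_pair_sim
        with pytest.raises(DomainError):
            recluster_one(matrix, merged, "B", GRID, seed=0,
                          min_subset=10_000)

    def test_empty_grid_rejected(self, hidden_pair_sim):
        matrix, _, merged = hidden_pair_sim
        with pytest.raises(ParameterError):
            recluster_one(matrix, merged, "B", [], seed=0)

    def test_union_candidate_covers_both_clusters(self, hidden_pair_sim):
        matrix, truth, _ = hidden_pair_sim
        labels = ClusterLabels(truth.labels.astype(object),
                               matrix.cell_ids)
        res = recluster_one(matrix, labels, {"B0", "B1"}, GRID, seed=0)
        assert len(res.sub_labels) == int(
            np.isin(truth.labels, ["B0", "B1"]).sum()
        )


class TestIntegrateLabels:
    def _labels(self):
        lab = np.array(["A"] * 3 + ["B"] * 4, dtype=object)
        ids = np.array([f"c{i}" for i in range(7)], dtype=object)
        return ClusterLabels(lab, ids)

    def _result(self, candidate, sub):
        glob = self._labels()
        mask = np.isin(glob.labels.astype(str), list(candidate))
        sub_labels = ClusterLabels(
            np.asarray(sub, dtype=object), glob.cell_ids[mask]
        )
        return ReclusterResult(
            tuple(sorted(candidate)), pd.DataFrame(),
            ReclusterParams(k=5, r=0.5), 0.9, sub_labels,
        )

    def test_no_results_identity(self):
        glob = self._labels()
        out = integrate_labels(glob, [])
        assert np.array_equal(out.labels, glob.labels)

    def test_split_renames_only_candidate(self):
        glob = self._labels()
        out = integrate_labels(
            glob, [self._result({"B"}, ["0", "1", "0", "1"])]
        )
        assert list(out.labels[:3]) == ["A", "A", "A"]
        assert list(out.labels[3:]) == ["B.0", "B.1", "B.0", "B.1"]

    def test_overlapping_candidates_rejected(self):
        glob = self._labels()
        res = self._result({"B"}, ["0", "1", "0", "1"])
        with pytest.raises(ValidationError):
            integrate_labels(glob, [res, res])

    def test_cell_count_conserved_over_two_candidates(self):
        glob = self._labels()
        out = integrate_labels(
            glob,
            [self._result({"A"}, ["0", "0", "1"]),
             self._result({"B"}, ["0", "1", "1", "0"])],
        )
        assert len(out) == len(glob)
        assert set(out.labels) == {"A.0", "A.1", "B.0", "B.1"}


@pytest.fixture(scope="module")
def pipeline_run():
    spec = default_spec(seed=2)
    matrix, truth = simulate_counts(spec)
    result = run_pipeline(matrix, RunConfig(), seed=2)
    return matrix, truth, result


class TestRunPipeline:
    def test_recovers_all_seven_clusters(self, pipeline_run):
        _, truth, result = pipeline_run
        assert len(set(result.final_labels.labels.astype(str))) == 7
        ari = adjusted_rand_index(truth.labels, result.final_labels.labels)
        assert ari > adjusted_rand_index(
            truth.labels, result.broad_labels.labels
        )

    def test_non_candidate_labels_bit_identical(self, pipeline_run):
        _, _, result = pipeline_run
        changed_parents = set()
        for res in result.recluster_results:
            if res.best is not None and res.best_coef >= 0.25:
                changed_parents |= set(res.candidate)
        broad = result.broad_labels.labels.astype(str)
        final = result.final_labels.labels.astype(str)
        outside = ~np.isin(broad, sorted(changed_parents))
        assert np.array_equal(broad[outside], final[outside])

    def test_grid_argmax_holds_for_every_run(self, pipeline_run):
        _, _, result = pipeline_run
        assert result.recluster_results  # the pipeline did recluster
        for res in result.recluster_results:
            kept = res.grid[res.grid["kept"]]
            if res.best is None:
                assert kept.empty
            else:
                assert res.best_coef == pytest.approx(kept["coef"].max())

    def test_deterministic_under_fixed_seed(self, pipeline_run):
        matrix, _, result = pipeline_run
        again = run_pipeline(matrix, RunConfig(), seed=2)
        assert np.array_equal(
            result.final_labels.labels, again.final_labels.labels
        )

    def test_single_cluster_input_reports_nothing_to_do(self):
        spec = SimSpec(
            n_cells=150, n_genes=300, proportions={"only": 1.0},
            de_frac=0.0, rare_pairs=[], seed=3,
        )
        matrix, _ = simulate_counts(spec)
        cfg = RunConfig()
        cfg.cluster.r = 1e-3  # force a single broad community
        result = run_pipeline(matrix, cfg, seed=0)
        assert len(set(result.final_labels.labels.astype(str))) == 1
        assert any("nothing to do" in m for m in result.messages)

    def test_empty_grid_config_rejected(self):
        with pytest.raises(Exception):
            cfg = RunConfig()
            cfg.recluster.grid_k = []

    def test_lognorm_distance_space_runs(self, hidden_pair_sim):
        """Silhouette flagging can run on the log-normalized HVG matrix
        instead of the PCA embedding (config-selectable space)."""
        matrix, _, _ = hidden_pair_sim
        cfg = RunConfig()
        cfg.preprocess.distance_space = "hvg_lognorm"
        result = run_pipeline(matrix, cfg, seed=0)
        assert len(result.final_labels) == matrix.n_cells
        assert result.summaries  # flagging stage ran in the chosen space
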