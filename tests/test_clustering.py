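"""Variable-matrix construction, correlation distance, linkage, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from dmndyn import clustering
from dmndyn.errors import ValidationError
from dmndyn.spectral import N_BINS


def toy_power_table(n_subjects=2, n_elec_per_cell=2, seed=0):
    """Small long-format table with both subsystems for every subject."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for band in ("theta", "gamma"):
            for task in ("MW", "AUT"):
                for subsys in ("dorsomedial-DMN", "lateral-DMN"):
                    for e in range(n_elec_per_cell):
                        for stage in ("stimulus", "response"):
                            for b in range(1, N_BINS + 1):
                                rows.append((f"S{s:02d}", f"S{s:02d}{subsys[:3]}e{e}",
                                             "default", subsys, task, stage, b,
                                             0.5 * b, band, rng.normal()))
    return pd.DataFrame(rows, columns=[
        "subject", "electrode", "network", "subsystem", "task", "stage",
        "bin_index", "bin_center_s", "band", "pct_change"])


class TestVariableMatrix:
    def test_observation_count_is_subjects_by_stages_by_bins(self):
        vm = clustering.build_variable_matrix(toy_power_table(n_subjects=3))
        assert vm.n_obs == 3 * 2 * N_BINS
        assert vm.var_names == clustering.VARIABLE_ORDER

    def test_single_subject_has_58_rows(self):
        vm = clustering.build_variable_matrix(toy_power_table(n_subjects=1))
        assert vm.n_obs == 58

    def test_subject_missing_subsystem_dropped(self):
        table = toy_power_table(n_subjects=3)
        table = table[~((table["subject"] == "S01")
                        & (table["subsystem"] == "lateral-DMN"))]
        vm = clustering.build_variable_matrix(table)
        assert vm.dropped_subjects == ["S01"]
        assert vm.n_obs == 2 * 2 * N_BINS

    def test_values_match_hand_computed_electrode_means(self):
        table = toy_power_table(n_subjects=1, n_elec_per_cell=2, seed=1)
        vm = clustering.build_variable_matrix(table)
        cell = table[(table["band"] == "theta") & (table["task"] == "MW")
                     & (table["subsystem"] == "dorsomedial-DMN")
                     & (table["stage"] == "response") & (table["bin_index"] == 4)]
        expected = cell["pct_change"].mean()
        row = vm.obs_index[(vm.obs_index["stage"] == "response")
                           & (vm.obs_index["bin_index"] == 4)].index[0]
        col = vm.var_names.index("theta_MW_dorsomedial")
        assert vm.values[row, col] == pytest.approx(expected)

    def test_overall_variables_are_mean_of_band_variables(self):
        vm = clustering.build_variable_matrix(toy_power_table())
        theta_cols = [vm.var_names.index(v) for v in vm.var_names[:8]
                      if v.startswith("theta")]
        np.testing.assert_allclose(
            vm.values[:, vm.var_names.index("theta_overall")],
            vm.values[:, theta_cols].mean(axis=1))


class TestCorrelationDistance:
    def test_self_distance_zero_antiparallel_two(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        X = np.column_stack([x, x, -x])
        D = clustering.correlation_distance(X)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert D[0, 2] == pytest.approx(2.0, abs=1e-12)
        assert np.all(np.diag(D) == 0)

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 5))
        D = clustering.correlation_distance(X)
        for i in range(5):
            for j in range(5):
                r = np.corrcoef(X[:, i], X[:, j])[0, 1]
                assert D[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_constant_variable_named_in_error(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValidationError, match="flatvar"):
            clustering.correlation_distance(X, ["flatvar", "ok"])


class TestCompleteLinkage:
    def test_closest_pair_merges_first(self):
        D = np.array([[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]])
        dend = clustering.complete_linkage(D, ["a", "b", "c"])
        assert dend.clusters()[0] == frozenset({"a", "b"})
        assert dend.heights()[0] == pytest.approx(0.1)

    def test_heights_non_decreasing_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            X = rng.normal(size=(40, 8))
            D = clustering.correlation_distance(X)
            dend = clustering.complete_linkage(D, [f"v{i}" for i in range(8)])
            h = dend.heights()
            assert np.all(np.diff(h) >= -1e-12)

    def test_two_variables_single_merge(self):
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        dend = clustering.complete_linkage(D, ["a", "b"])
        assert len(dend.clusters()) == 1

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 0.5], [0.2, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            clustering.complete_linkage(D, ["a", "b"])

    def test_invariant_to_variable_ordering(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 6))
        names = [f"v{i}" for i in range(6)]
        D = clustering.correlation_distance(X)
        base = set(clustering.complete_linkage(D, names).clusters())
        perm = rng.permutation(6)
        Dp = D[np.ix_(perm, perm)]
        permuted = set(clustering.complete_linkage(
            Dp, [names[i] for i in perm]).clusters())
        assert base == permuted


def _vm(X, names=None):
    names = names or [f"v{i}" for i in range(X.shape[1])]
    return clustering.VariableMatrix(values=X, var_names=names,
                                     obs_index=pd.DataFrame())


class TestBootstrap:
    def test_duplicated_pair_has_bp_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=200)
        X = np.column_stack([x + 1e-6 * rng.normal(size=200),
                             x + 1e-6 * rng.normal(size=200),
                             rng.normal(size=200), rng.normal(size=200)])
        dend = clustering.bootstrap_cluster_probability(_vm(X), n_boot=100, seed=0)
        assert clustering.cluster_bp(dend, {"v0", "v1"}) == 1.0

    def test_single_replicate_bp_binary(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 4))
        dend = clustering.bootstrap_cluster_probability(_vm(X), n_boot=1, seed=0)
        assert set(np.unique(dend.bp)) <= {0.0, 1.0}

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValidationError):
            clustering.bootstrap_cluster_probability(
                _vm(np.random.default_rng(8).normal(size=(20, 3))), n_boot=0)

    def test_planted_anticorrelated_blocks_recovered(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=300)
        noise = lambda: 0.3 * rng.normal(size=300)
        X = np.column_stack([base + noise(), base + noise(),
                             -base + noise(), -base + noise()])
        dend = clustering.bootstrap_cluster_probability(_vm(X), n_boot=500, seed=1)
        assert clustering.cluster_bp(dend, {"v0", "v1"}) >= 0.9
        assert clustering.cluster_bp(dend, {"v2", "v3"}) >= 0.9

    def test_missing_cluster_bp_zero(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 4))
        dend = clustering.bootstrap_cluster_probability(_vm(X), n_boot=10, seed=0)
        assert clustering.cluster_bp(dend, {"v0", "nonexistent"}) == 0.0


class TestNewick:
    def test_serialization_parses_and_preserves_leaves(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(11)
        X = rng.normal(size=(80, 5))
        names = [f"v{i}" for i in range(5)]
        dend = clustering.bootstrap_cluster_probability(_vm(X, names), n_boot=20, seed=0)
        nwk = clustering.to_newick(dend)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == names
        assert nwk.endswith(";")

    def test_internal_labels_are_bootstrap_probabilities(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=100)
        X = np.column_stack([x, x + 1e-8 * rng.normal(size=100),
                             rng.normal(size=100)])
        dend = clustering.bootstrap_cluster_probability(_vm(X), n_boot=50, seed=0)
        assert "1.0000" in clustering.to_newick(dend)
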