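import itertools
import math

import numpy as np
import pandas as pd
import pytest

from aphidnet.network import (MINetwork, NetworkError, call_core_genes,
                              dpi_prune, export_network, mi_matrix,
                              mutual_information)

from conftest import make_em


def brute_force_dpi(mi, tolerance=0.0):
    """Exhaustive triangle scan; the oracle for dpi_prune."""
    k = mi.shape[0]
    pruned = np.zeros((k, k), dtype=bool)
    for i, j, t in itertools.combinations(range(k), 3):
        edges = [(i, j), (i, t), (j, t)]
        vals = [mi[e] for e in edges]
        if min(vals) <= 0:
            continue
        for idx, e in enumerate(edges):
            others = [vals[x] for x in range(3) if x != idx]
            if vals[idx] < (1 - tolerance) * min(others):
                pruned[e] = pruned[e[::-1]] = True
    return pruned


def star_network(n_leaves, hub_mi, leaf_leaf_mi=0.0):
    genes = ["hub"] + [f"leaf{i}" for i in range(n_leaves)]
    k = len(genes)
    mi = np.full((k, k), leaf_leaf_mi)
    mi[0, 1:] = mi[1:, 0] = hub_mi
    np.fill_diagonal(mi, 0.0)
    return MINetwork(genes, mi)


class TestMutualInformation:
    def test_symmetry_exact(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 200))
        assert mutual_information(x, y) == mutual_information(y, x)

    def test_independence_near_zero(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 2000))
        n, b = 2000, int(np.sqrt(1000))
        assert mutual_information(x, y) <= 2 * (b - 1) ** 2 / (2 * n)

    def test_perfect_dependence_value(self):
        # equal-frequency grid: diagonal joint, I = ln B, then the
        # Miller-Madow term (B - 2B + 1)/(2n) is subtracted
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        b = 5  # floor(sqrt(60/2))
        expected = math.log(b) - (b - 2 * b + 1) / (2 * 60)
        assert mutual_information(x, np.exp(x)) == pytest.approx(expected)

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_gaussian_closed_form(self, rho):
        cov = [[1, rho], [rho, 1]]
        truth = -0.5 * math.log(1 - rho ** 2)
        z = np.random.default_rng(33).multivariate_normal([0, 0], cov, 2000)
        est = mutual_information(z[:, 0], z[:, 1])
        assert est == pytest.approx(truth, abs=0.1)

    def test_monotone_in_correlation(self):
        rng = np.random.default_rng(5)
        ests = []
        for rho in (0.0, 0.5, 0.9):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 2000)
            ests.append(mutual_information(z[:, 0], z[:, 1]))
        assert ests[0] < ests[1] < ests[2]

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=(2, 300))
        base = mutual_information(x, y)
        assert mutual_information(np.exp(x), y ** 3) == base
        assert mutual_information(-x, y) == base

    def test_constant_vector_warns_and_returns_zero(self):
        x = np.ones(50)
        y = np.arange(50.0)
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information(x, y) == 0.0

    def test_input_validation(self):
        with pytest.raises(NetworkError):
            mutual_information(np.ones(5), np.ones(5))
        with pytest.raises(NetworkError):
            mutual_information(np.ones(10), np.ones(9))


class TestMiMatrix:
    def test_pair_counts(self):
        em = make_em(np.random.default_rng(7).uniform(1, 9, (4, 60)),
                     n_replicates=4)
        net = mi_matrix(em, ["g0", "g1"])
        assert net.n_edges() <= 1 and net.mi.shape == (2, 2)
        full = mi_matrix(em)
        iu = np.triu_indices(4, k=1)
        assert len(iu[0]) == 6  # k(k-1)/2 potential edges

    def test_matches_pairwise_estimator(self):
        em = make_em(np.random.default_rng(8).uniform(1, 9, (6, 60)),
                     n_replicates=4)
        net = mi_matrix(em)
        arr = em.values.to_numpy()
        for i in range(6):
            for j in range(i + 1, 6):
                assert net.mi[i, j] == pytest.approx(
                    mutual_information(arr[i], arr[j]), abs=1e-12)

    def test_shuffled_columns_break_module_mi(self, default_dataset):
        matrix, truth = default_dataset
        members = truth.module_members["module1"]
        net = mi_matrix(matrix, members)
        observed = net.mi[np.triu_indices(len(members), k=1)]
        rng = np.random.default_rng(9)
        shuffled = matrix.values.loc[members].to_numpy().copy()
        for row in shuffled:
            rng.shuffle(row)
        null_net = mi_matrix(pd.DataFrame(shuffled, index=members,
                                          columns=matrix.values.columns))
        null = null_net.mi[np.triu_indices(len(members), k=1)]
        assert np.percentile(null, 95) < np.percentile(observed, 5)

    def test_too_few_genes(self):
        em = make_em(np.ones((3, 60)) + np.arange(60), n_replicates=4)
        with pytest.raises(NetworkError):
            mi_matrix(em, ["g0"])


class TestDpiPrune:
    def test_hand_worked_triangle(self):
        mi = np.array([[0.0, 0.9, 0.8],
                       [0.9, 0.0, 0.5],
                       [0.8, 0.5, 0.0]])
        net = dpi_prune(MINetwork(["a", "b", "c"], mi))
        assert net.pruned[1, 2] and net.pruned[2, 1]
        assert not net.pruned[0, 1] and not net.pruned[0, 2]

    def test_tied_triangle_keeps_all_edges(self):
        mi = np.full((3, 3), 0.6)
        np.fill_diagonal(mi, 0.0)
        net = dpi_prune(MINetwork(["a", "b", "c"], mi))
        assert not net.pruned.any()

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force(self, trial):
        rng = np.random.default_rng(trial)
        k = 10
        mi = rng.uniform(0.05, 1.0, (k, k))
        mi = (mi + mi.T) / 2
        if trial % 2:  # coarse values exercise the tie semantics
            mi = np.round(mi, 1)
        np.fill_diagonal(mi, 0.0)
        net = dpi_prune(MINetwork([f"g{i}" for i in range(k)], mi))
        np.testing.assert_array_equal(net.pruned, brute_force_dpi(mi))

    def test_idempotent(self):
        rng = np.random.default_rng(13)
        mi = rng.uniform(0.05, 1.0, (8, 8))
        mi = (mi + mi.T) / 2
        np.fill_diagonal(mi, 0.0)
        once = dpi_prune(MINetwork([f"g{i}" for i in range(8)], mi))
        twice = dpi_prune(once)
        np.testing.assert_array_equal(once.pruned, twice.pruned)

    def test_tolerance_relaxes_pruning(self):
        mi = np.array([[0.0, 0.9, 0.8],
                       [0.9, 0.0, 0.75],
                       [0.8, 0.75, 0.0]])
        strict = dpi_prune(MINetwork(["a", "b", "c"], mi), 0.0)
        loose = dpi_prune(MINetwork(["a", "b", "c"], mi), 0.2)
        assert strict.pruned.any() and not loose.pruned.any()

    def test_negative_tolerance_rejected(self):
        with pytest.raises(NetworkError):
            dpi_prune(star_network(3, 0.5), -0.1)


class TestCoreGenes:
    def test_star_hub_is_core_leaves_are_not(self):
        net = star_network(25, hub_mi=0.5)
        core = call_core_genes(net)
        assert core.loc["hub", "is_core"]
        assert core.loc["hub", "degree"] == 25
        assert not core.drop(index="hub")["is_core"].any()

    def test_degree_boundary_is_non_strict(self):
        core20 = call_core_genes(star_network(20, 0.5))
        core19 = call_core_genes(star_network(19, 0.5))
        assert core20.loc["hub", "is_core"]
        assert not core19.loc["hub", "is_core"]

    def test_low_mean_mi_fails(self):
        core = call_core_genes(star_network(25, hub_mi=0.41),
                               edge_mi_min=0.3, mean_mi_min=0.45)
        assert not core.loc["hub", "is_core"]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(21)
        mi = rng.uniform(0.0, 1.0, (40, 40))
        mi = (mi + mi.T) / 2
        np.fill_diagonal(mi, 0.0)
        net = MINetwork([f"g{i}" for i in range(40)], mi)
        base = set(call_core_genes(net, 0.4, 10, 0.4).query("is_core").index)
        harder_deg = set(call_core_genes(net, 0.4, 15, 0.4)
                         .query("is_core").index)
        harder_mi = set(call_core_genes(net, 0.4, 10, 0.6)
                        .query("is_core").index)
        assert harder_deg <= base and harder_mi <= base

    def test_hub_recovery_on_default_dataset(self, default_results,
                                             default_dataset):
        _, truth = default_dataset
        core = default_results.core_table
        top5 = set(core.sort_values("degree", ascending=False).head(5).index)
        for hub in truth.module_hubs.values():
            assert core.loc[hub, "is_core"] or hub in top5


class TestExport:
    def test_empty_display_network(self, tmp_path):
        net = star_network(3, hub_mi=0.3)
        export_network(net, tmp_path / "e.tsv", display_mi_min=0.5)
        out = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        assert len(out) == 0

    def test_edge_list_round_trip(self, tmp_path):
        net = star_network(3, hub_mi=0.7)
        export_network(net, tmp_path / "e.tsv", display_mi_min=0.5)
        out = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        assert len(out) == 3
        assert set(out["gene_a"]) == {"hub"}
        np.testing.assert_allclose(out["mi"], 0.7)

    def test_gml_round_trip(self, tmp_path):
        import networkx as nx
        net = star_network(4, hub_mi=0.8)
        export_network(net, tmp_path / "n.gml", display_mi_min=0.5,
                       format="gml")
        g = nx.read_gml(tmp_path / "n.gml")
        assert set(g.nodes) == set(net.genes)
        assert g.number_of_edges() == 4
        assert g.nodes["hub"]["degree"] == 4
        for _, _, d in g.edges(data=True):
            assert d["mi"] == pytest.approx(0.8)
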