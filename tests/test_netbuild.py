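"""Network construction: correlation, baselines, thresholding, admission."""

import numpy as np
import pytest
from scipy import stats

from olfnet import netbuild as nb
from olfnet import simulate as sim
from olfnet.containers import BinaryNetwork, ConnectivityMatrix, RoiTimeseries


def ts_from(values, tr=0.72):
    values = np.asarray(values, dtype=float)
    return RoiTimeseries(values, [f"r{i}" for i in range(values.shape[1])],
                         np.zeros(values.shape[0], dtype=int), tr)


def conn(names, mat, level="group"):
    return ConnectivityMatrix(list(names), np.asarray(mat, dtype=float),
                              level=level)


class TestCorrelationMatrix:
    def test_fisher_z_closed_form(self, rng):
        # plant r = 0.5 between two series via a shared component
        n = 400_000
        shared = rng.standard_normal(n)
        a = shared + rng.standard_normal(n)
        b = shared + rng.standard_normal(n)
        m = nb.correlation_matrix(ts_from(np.column_stack([a, b])))
        assert m.values[0, 1] == pytest.approx(np.arctanh(0.5), abs=0.01)

    def test_exact_atanh_on_known_r(self):
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_independent_noise_gives_null_z(self, rng):
        m = nb.correlation_matrix(ts_from(rng.standard_normal((100_000, 3))))
        off = m.values[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.02

    def test_duplicated_roi_capped_not_infinite(self, rng):
        x = rng.standard_normal(100)
        with pytest.warns(UserWarning, match="capped"):
            m = nb.correlation_matrix(ts_from(np.column_stack([x, x])))
        assert np.isfinite(m.values).all()

    def test_zero_variance_roi_flagged(self, rng):
        vals = rng.standard_normal((50, 2))
        vals[:, 1] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            m = nb.correlation_matrix(ts_from(vals))
        assert m.values[0, 1] == 0.0

    def test_too_few_scans_rejected(self, rng):
        with pytest.raises(ValueError, match="retained scans"):
            nb.correlation_matrix(ts_from(rng.standard_normal((2, 3))))


class TestGlobalBaseline:
    def test_uncorrelated_node_has_zero_baseline(self):
        z = np.zeros((4, 4))
        base = nb.global_baseline(conn("abcd", z))
        assert base["a"] == 0.0

    def test_constant_connectivity_baseline(self):
        z = np.full((5, 5), 0.3)
        np.fill_diagonal(z, 0)
        base = nb.global_baseline(conn("abcde", z))
        assert base["c"] == pytest.approx(0.3)

    def test_toy_matrix_hand_mean(self):
        z = np.array([[0.0, 0.1, 0.2, 0.6],
                      [0.1, 0.0, 0.4, 0.0],
                      [0.2, 0.4, 0.0, 0.3],
                      [0.6, 0.0, 0.3, 0.0]])
        base = nb.global_baseline(conn("abcd", z))
        assert base["a"] == pytest.approx((0.1 + 0.2 + 0.6) / 3)
        assert nb.pair_baseline(base, "a", "b") == pytest.approx(
            ((0.9 / 3) + (0.5 / 3)) / 2)


class TestEdgeTtest:
    def make_subjects(self, rng, n_subj, shift=0.0, n=6):
        mats, bases = [], []
        names = [f"r{i}" for i in range(n)]
        for _ in range(n_subj):
            upper = np.triu(rng.standard_normal((n, n)) * 0.1 + shift, 1)
            mats.append(conn(names, upper + upper.T, level="subject"))
            bases.append({k: 0.0 for k in names})
        return mats, bases

    def test_equal_to_baseline_gives_t_zero(self):
        names = list("abc")
        mats = [conn(names, np.full((3, 3), 0.2) - 0.2 * np.eye(3))
                for _ in range(4)]
        bases = [{k: 0.2 for k in names} for _ in range(4)]
        t, p = nb.edge_ttest(mats, bases)
        assert np.allclose(t[np.triu_indices(3, 1)], 0.0)
        assert np.allclose(p[np.triu_indices(3, 1)], 0.5)

    def test_zero_variance_shift_capped(self):
        names = list("abc")
        mats = [conn(names, np.full((3, 3), 1.0) - np.eye(3))
                for _ in range(5)]
        bases = [{k: 0.0 for k in names} for _ in range(5)]
        t, p = nb.edge_ttest(mats, bases)
        assert np.isposinf(t[0, 1])
        assert p[0, 1] == 0.0

    def test_null_pvalues_uniform(self, rng):
        ps = []
        for _ in range(8):
            mats, bases = self.make_subjects(rng, 10, n=20)
            _, p = nb.edge_ttest(mats, bases)
            ps.append(p[np.triu_indices(20, 1)])
        ks = stats.kstest(np.concatenate(ps), "uniform")
        assert ks.pvalue > 0.01

    def test_single_subject_rejected(self, rng):
        mats, bases = self.make_subjects(rng, 1)
        with pytest.raises(ValueError):
            nb.edge_ttest(mats, bases)


class TestProportionalThreshold:
    def test_whole_brain_retention_count(self):
        # 626-region context at 5%: floor(0.05 * 625) = 31 per node
        assert nb.per_node_retention(626, 0.05) == 31

    def test_density_one_approaches_complete_graph(self, rng):
        # at p -> 1 each node omits a single weakest edge, so only
        # reciprocally-omitted edges (at most n/2) can be missing
        n = 8
        upper = np.triu(rng.standard_normal((n, n)), 1)
        m = conn([f"r{i}" for i in range(n)], upper + upper.T)
        net = nb.threshold_proportional(m, 0.999)
        assert net.n_edges >= n * (n - 1) // 2 - n // 2

    def test_matches_brute_force_ranking(self, rng):
        for _ in range(25):
            n = 6
            upper = np.triu(rng.standard_normal((n, n)), 1)
            m = conn([f"r{i}" for i in range(n)], upper + upper.T)
            density = 0.4
            k = int(np.floor(density * (n - 1)))
            marked = np.zeros((n, n), dtype=bool)
            for i in range(n):
                order = sorted((j for j in range(n) if j != i),
                               key=lambda j: -m.values[i, j])
                for j in order[:k]:
                    marked[i, j] = True
            expect = marked | marked.T
            net = nb.threshold_proportional(m, density)
            assert np.array_equal(net.adjacency.astype(bool), expect)

    def test_and_rule_is_subset_of_union(self, rng):
        n = 10
        upper = np.triu(rng.standard_normal((n, n)), 1)
        m = conn([f"r{i}" for i in range(n)], upper + upper.T)
        u = nb.threshold_proportional(m, 0.3, rule="union")
        a = nb.threshold_proportional(m, 0.3, rule="and")
        assert (a.adjacency <= u.adjacency).all()

    def test_nested_densities_give_nested_edge_sets(self, rng):
        n = 30
        upper = np.triu(rng.standard_normal((n, n)), 1)
        m = conn([f"r{i}" for i in range(n)], upper + upper.T)
        prev = None
        for d in (0.05, 0.10, 0.15):
            net = nb.threshold_proportional(m, d)
            if prev is not None:
                assert (prev.adjacency <= net.adjacency).all()
            prev = net

    def test_too_small_density_rejected(self, rng):
        m = conn("abcd", np.zeros((4, 4)))
        with pytest.raises(ValueError):
            nb.threshold_proportional(m, 0.01)


class TestSeededAdmission:
    def star_adjacency(self, edges, names):
        lookup = {n: i for i, n in enumerate(names)}
        adj = np.zeros((len(names), len(names)), dtype=int)
        for a, b in edges:
            adj[lookup[a], lookup[b]] = adj[lookup[b], lookup[a]] = 1
        return BinaryNetwork(list(names), adj)

    def test_candidate_linked_only_to_candidate_rejected(self):
        names = ["k1", "c1", "c2"]
        adj = self.star_adjacency([("c1", "c2")], names)
        net = nb.build_seeded_network(adj, ["k1"], ["c1", "c2"])
        assert net.node_names == ["k1"]
        assert net.rejected_nodes == ["c1", "c2"]

    def test_candidate_linked_to_key_admitted(self):
        names = ["k1", "c1", "c2"]
        adj = self.star_adjacency([("k1", "c1"), ("c1", "c2")], names)
        net = nb.build_seeded_network(adj, ["k1"], ["c1", "c2"])
        assert net.roles == {"k1": "key", "c1": "secondary"}

    def test_roles_partition_node_set(self, planted_runs):
        for run in planted_runs[:3]:
            roles = run["network"].roles
            assert set(roles.values()) <= {"key", "secondary"}
            assert sorted(roles) == sorted(run["network"].node_names)

    def test_empty_key_set_rejected(self):
        adj = self.star_adjacency([], ["a", "b"])
        with pytest.raises(ValueError):
            nb.build_seeded_network(adj, [], ["a", "b"])


class TestCrossModalityControl:
    def test_independent_planted_modules_have_zero_cross_edges(self, planted_runs):
        visual = list(sim.STUDY_MODULES["visual"])
        for run in planted_runs[:5]:
            olf = run["network"].node_names
            counts = nb.cross_modality_control(run["whole"], olf, visual,
                                               densities=(0.05,))
            assert counts[0.05] == 0

    def test_counts_monotone_in_density(self, planted_runs):
        run = planted_runs[0]
        visual = list(sim.STUDY_MODULES["visual"])
        counts = nb.cross_modality_control(run["whole"],
                                           run["network"].node_names, visual)
        assert counts[0.05] <= counts[0.10] <= counts[0.15]

    def test_identical_sets_rejected(self):
        m = conn("abcd", np.zeros((4, 4)))
        with pytest.raises(ValueError, match="disjoint"):
            nb.cross_modality_control(m, ["a", "b"], ["b", "c"])

    def test_mirrored_sets_give_maximal_cross_edges(self):
        # cross-set coupling stronger than within-set: every cross pair
        # is within each node's strongest connections
        names = [f"r{i}" for i in range(8)]
        z = np.full((8, 8), 0.5)
        z[:4, 4:] = 1.0
        z[4:, :4] = 1.0
        np.fill_diagonal(z, 0.0)
        counts = nb.cross_modality_control(conn(names, z), names[:4], names[4:],
                                           densities=(0.6,))
        assert counts[0.6] == 16


class TestNetworkDensity:
    def test_reported_network_density_worked_example(self):
        rng = np.random.default_rng(0)
        g = np.zeros((22, 22), dtype=int)
        pairs = [(i, j) for i in range(22) for j in range(i + 1, 22)]
        chosen = rng.choice(len(pairs), size=66, replace=False)
        for c in chosen:
            i, j = pairs[c]
            g[i, j] = g[j, i] = 1
        net = BinaryNetwork([f"n{i}" for i in range(22)], g)
        assert nb.network_density(net) == pytest.approx(100 * 66 / 231)

    def test_complete_and_empty_graphs(self):
        full = BinaryNetwork(list("abcd"), 1 - np.eye(4, dtype=int))
        empty = BinaryNetwork(list("abcd"), np.zeros((4, 4), dtype=int))
        assert nb.network_density(full) == 100.0
        assert nb.network_density(empty) == 0.0


def test_network_serialization_round_trips(tmp_path, rng):
    n = 7
    upper = np.triu(rng.random((n, n)) < 0.5, 1)
    net = BinaryNetwork([f"r{i}" for i in range(n)],
                        (upper + upper.T).astype(int))
    net.to_json(tmp_path / "net.json")
    assert np.array_equal(BinaryNetwork.from_json(tmp_path / "net.json").adjacency,
                          net.adjacency)
    net.to_edgelist_tsv(tmp_path / "net.tsv")
    back = BinaryNetwork.from_edgelist_tsv(tmp_path / "net.tsv",
                                           node_names=net.node_names)
    assert np.array_equal(back.adjacency, net.adjacency)


def test_group_mean_matrix_averages_fisher_z(rng):
    names = list("abc")
    mats = []
    for s in range(3):
        upper = np.triu(rng.standard_normal((3, 3)), 1)
        mats.append(conn(names, upper + upper.T, level="subject"))
    group = nb.group_mean_matrix(mats)
    assert group.level == "group"
    expect = np.mean([m.values for m in mats], axis=0)
    assert np.allclose(group.values, expect)
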