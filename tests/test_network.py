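import itertools

import numpy as np
import pandas as pd
import pytest

from rhizoclim.community import ClrMatrix
from rhizoclim.io_tables import AsvCountTable, ValidationError
from rhizoclim.network import (ClusterPartition, SignedNetwork, _mb_edges,
                               cluster_abundances, cluster_climate_model,
                               cluster_density_test, intercluster_correlations,
                               mb_lambda_path, signed_hamiltonian,
                               spinglass_cluster, stars_select,
                               summarize_partition)


def clr_from(X):
    return ClrMatrix(pd.DataFrame(
        X, index=[f"s{i}" for i in range(X.shape[0])],
        columns=[f"a{j}" for j in range(X.shape[1])]))


def make_net(edge_list, nodes=None):
    rows = [{"node_a": a, "node_b": b, "sign": s, "weight": w}
            for a, b, s, w in edge_list]
    if nodes is None:
        nodes = sorted({e[0] for e in edge_list} | {e[1] for e in edge_list})
    return SignedNetwork(node_ids=list(nodes), edges=pd.DataFrame(
        rows, columns=["node_a", "node_b", "sign", "weight"]))


class TestNeighbourhoodSelection:
    def test_largest_penalty_gives_empty_graph(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 8))
        lambdas, edges, _ = mb_lambda_path(clr_from(X), n_lambda=10)
        assert edges[0].sum() == 0

    def test_tiny_penalty_saturates_when_n_exceeds_p(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 6))
        lambdas, edges, _ = mb_lambda_path(clr_from(X), n_lambda=20,
                                           lambda_min_ratio=1e-4)
        p = 6
        off_diag = p * (p - 1)
        assert edges[-1].sum() == off_diag      # every ordered pair linked

    def test_chain_precision_matrix_recovered_on_path(self):
        rng = np.random.default_rng(2)
        p, n = 10, 500
        Omega = np.eye(p)
        for i in range(p - 1):
            Omega[i, i + 1] = Omega[i + 1, i] = 0.4
        L = np.linalg.cholesky(np.linalg.inv(Omega))
        X = rng.normal(size=(n, p)) @ L.T
        lambdas, edges, _ = mb_lambda_path(clr_from(X), n_lambda=30)
        chain = {(i, i + 1) for i in range(p - 1)}
        hit = False
        for l in range(len(lambdas)):
            got = {(i, j) for i, j in zip(*np.triu_indices(p, 1))
                   if edges[l, i, j]}
            if got == chain:
                hit = True
                break
        assert hit

    def test_kernel_agrees_with_reference_lasso(self):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(3)
        n, p = 60, 12
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        lambdas = np.geomspace(0.6, 0.01, 15)
        _, coefs = _mb_edges(X, lambdas)
        for j in (0, 5):
            mask = np.arange(p) != j
            _, ref, _ = sklearn_linear.lasso_path(
                X[:, mask], X[:, j], alphas=lambdas, tol=1e-10)
            assert np.allclose(coefs[:, j, mask], ref.T, atol=1e-4)
            assert ((coefs[:, j, mask] != 0) == (np.abs(ref.T) > 1e-12)).all()

    def test_constant_column_rejected(self):
        X = np.ones((20, 3))
        with pytest.raises(ValidationError):
            mb_lambda_path(clr_from(X))


class TestStars:
    def test_strong_two_block_structure_is_stable(self):
        rng = np.random.default_rng(8)
        n = 60
        z1, z2 = rng.normal(size=(2, n))
        X = np.column_stack([z1 + 0.1 * rng.normal(size=n) for _ in range(3)]
                            + [z2 + 0.1 * rng.normal(size=n) for _ in range(3)])
        net = stars_select(clr_from(X), n_lambda=15, n_replications=40, seed=0)
        assert net.threshold_met
        assert net.instability_at_selection <= 0.05
        mono = net.instability_path
        assert (np.diff(mono) >= -1e-12).all()   # monotonized curve

    def test_edge_instability_identity(self):
        # an edge selected in exactly half the subsamples contributes 2*0.5*0.5
        theta = 0.5
        assert 2 * theta * (1 - theta) == 0.5


class TestSpinglass:
    def two_cliques(self):
        edges = []
        for base in (0, 6):
            for i, j in itertools.combinations(range(6), 2):
                edges.append((f"n{base + i}", f"n{base + j}", 1, 1.0))
        for i in range(6):
            edges.append((f"n{i}", f"n{6 + i}", -1, 1.0))
        return make_net(edges)

    def test_two_positive_cliques_split_by_negative_links(self):
        part = spinglass_cluster(self.two_cliques(), seed=0)
        groups = part.assignments.groupby(part.assignments).size()
        assert sorted(groups.tolist()) == [6, 6]
        left = {part.assignments[f"n{i}"] for i in range(6)}
        right = {part.assignments[f"n{i}"] for i in range(6, 12)}
        assert len(left) == len(right) == 1 and left != right

    def test_single_positive_clique_is_one_cluster(self):
        edges = [(f"n{i}", f"n{j}", 1, 1.0)
                 for i, j in itertools.combinations(range(6), 2)]
        part = spinglass_cluster(make_net(edges), seed=1)
        assert part.assignments.nunique() == 1

    @staticmethod
    def all_partitions(items):
        if not items:
            yield []
            return
        head, *rest = items
        for sub in TestSpinglass.all_partitions(rest):
            for k in range(len(sub)):
                yield sub[:k] + [[head] + sub[k]] + sub[k + 1:]
            yield [[head]] + sub

    def test_eight_node_exhaustive_minimum(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(8)]
        edges = []
        for i, j in itertools.combinations(range(8), 2):
            if rng.random() < 0.5:
                sign = 1 if rng.random() < 0.6 else -1
                edges.append((nodes[i], nodes[j], sign,
                              float(rng.uniform(0.2, 1.0))))
        net = make_net(edges, nodes)
        part = spinglass_cluster(net, seed=2)
        best = np.inf
        for blocks in self.all_partitions(nodes):   # Bell(8) = 4140 partitions
            labels = np.empty(8, dtype=int)
            for k, block in enumerate(blocks):
                for v in block:
                    labels[nodes.index(v)] = k
            best = min(best, signed_hamiltonian(net, labels))
        assert part.hamiltonian == pytest.approx(best, abs=1e-9)

    def test_fixed_seed_reproducible_and_bounded(self):
        net = self.two_cliques()
        a = spinglass_cluster(net, seed=9)
        b = spinglass_cluster(net, seed=9)
        assert a.assignments.equals(b.assignments)
        assert a.hamiltonian == b.hamiltonian
        n = len(net.node_ids)
        singles = signed_hamiltonian(net, np.arange(n))
        lumped = signed_hamiltonian(net, np.zeros(n, dtype=int))
        assert a.hamiltonian <= singles + 1e-9
        assert a.hamiltonian <= lumped + 1e-9

    def test_empty_network_rejected(self):
        with pytest.raises(ValidationError):
            spinglass_cluster(SignedNetwork(node_ids=[], edges=pd.DataFrame(
                columns=["node_a", "node_b", "sign", "weight"])), seed=0)


class TestDensityTest:
    def test_singleton_partition_has_zero_statistic(self):
        net = TestSpinglass().two_cliques()
        part = ClusterPartition(
            assignments=pd.Series([f"c{i + 1}" for i in range(12)],
                                  index=net.node_ids),
            hamiltonian=0.0)
        res = cluster_density_test(net, part, n_random=99, seed=0)
        assert res["statistic"] == 0.0
        assert res["p_value"] > 0.9

    def test_planted_partition_minimal_p(self):
        net = TestSpinglass().two_cliques()
        part = spinglass_cluster(net, seed=0)
        res = cluster_density_test(net, part, n_random=99, seed=1)
        assert res["p_value"] == pytest.approx(1 / 100)

    def test_type_i_rate_for_random_labels(self):
        rng = np.random.default_rng(77)
        n_sims = 500
        rejections = 0
        for s in range(n_sims):
            nodes = [f"n{i}" for i in range(16)]
            pairs = list(itertools.combinations(range(16), 2))
            chosen = rng.choice(len(pairs), size=40, replace=False)
            edges = [(nodes[pairs[k][0]], nodes[pairs[k][1]], 1, 1.0)
                     for k in chosen]
            net = make_net(edges, nodes)
            labels = rng.integers(0, 3, size=16)
            part = ClusterPartition(
                assignments=pd.Series([f"c{k + 1}" for k in labels],
                                      index=nodes), hamiltonian=0.0)
            res = cluster_density_test(net, part, n_random=99,
                                       seed=int(rng.integers(2 ** 31)),
                                       swaps_per_edge=5)
            rejections += res["p_value"] <= 0.05
        assert 0.03 <= rejections / n_sims <= 0.07


class TestClusterStatistics:
    def test_cluster_abundance_hand_case(self):
        t = AsvCountTable(counts=pd.DataFrame(
            [[2, 2, 4]], index=["s1"], columns=["a", "b", "c"]))
        part = ClusterPartition(
            assignments=pd.Series(["c1", "c1", "c2"], index=["a", "b", "c"]),
            hamiltonian=0.0)
        ab = cluster_abundances(t, part)
        assert ab.loc["s1"].tolist() == [0.5, 0.5]

    def test_full_coverage_sums_to_one(self, dataset):
        t = dataset.tables["rhizosphere"]
        part = ClusterPartition(
            assignments=pd.Series("c1", index=t.asv_ids), hamiltonian=0.0)
        ab = cluster_abundances(t, part)
        assert np.allclose(ab["c1"], 1.0)
        vals = ab.to_numpy()
        assert ((vals >= 0) & (vals <= 1 + 1e-9)).all()

    def test_missing_node_rejected(self, dataset):
        t = dataset.tables["rhizosphere"]
        part = ClusterPartition(
            assignments=pd.Series("c1", index=["not_a_node"]),
            hamiltonian=0.0)
        with pytest.raises(ValidationError):
            cluster_abundances(t, part)

    def test_partition_summary_fractions(self, dataset):
        t = dataset.tables["rhizosphere"]
        part = ClusterPartition(
            assignments=pd.Series(
                ["c1"] * 25 + ["c2"] * 25, index=t.asv_ids), hamiltonian=0.0)
        summ = summarize_partition(part, t)
        assert np.allclose(
            summ["prokaryote_fraction"] + summ["fungal_fraction"], 1.0)
        assert (summ["relative_size"] > 0).all()
        assert summ["relative_size"].sum() == pytest.approx(1.0)


def _loc_series(n=96, g=12):
    return pd.Series(np.repeat([f"L{k:02d}" for k in range(g)], n // g),
                     index=[f"s{i}" for i in range(n)])


class TestInterclusterCorrelations:
    def test_identical_clusters_give_unit_slope(self):
        rng = np.random.default_rng(0)
        loc = _loc_series()
        v = rng.uniform(0.05, 0.4, size=96)
        ab = pd.DataFrame({"c1": v, "c2": v}, index=loc.index)
        res = intercluster_correlations(ab, loc, auto_transform=False)
        assert res["slope"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert res["p_value"].iloc[0] < 1e-20

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(1)
        loc = _loc_series()
        ab = pd.DataFrame(rng.uniform(0.1, 0.3, size=(96, 7)),
                          columns=[f"c{k}" for k in range(7)], index=loc.index)
        res = intercluster_correlations(ab, loc, auto_transform=False)
        assert len(res) == 21
        ok = ~res["excluded"]
        assert np.allclose(res.loc[ok, "p_adjusted"],
                           np.minimum(res.loc[ok, "p_value"] * ok.sum(), 1.0))

    def test_type_i_rate_for_independent_clusters(self):
        loc = _loc_series()
        rejections = 0
        n_sims = 500
        for s in range(n_sims):
            rng = np.random.default_rng(10_000 + s)
            b = rng.normal(scale=0.3, size=(12, 2))
            grp = np.repeat(np.arange(12), 8)
            ab = pd.DataFrame({
                "c1": 0.2 + 0.05 * (b[grp, 0] + rng.normal(size=96)),
                "c2": 0.2 + 0.05 * (b[grp, 1] + rng.normal(size=96)),
            }, index=loc.index)
            res = intercluster_correlations(ab, loc, auto_transform=False)
            rejections += res["p_value"].iloc[0] < 0.05
        assert 0.03 <= rejections / n_sims <= 0.07


class TestClusterClimateModel:
    def simulate(self, seed, t_slope=0.0, p_slope=0.0, interaction=0.0):
        rng = np.random.default_rng(seed)
        loc = _loc_series()
        t = np.repeat(np.tile([6.5, 8.5, 10.5], 4), 8)
        p = np.repeat(np.tile([600, 1200, 2000, 2700], 3), 8)
        tz = (t - t.mean()) / t.std()
        pz = (p - p.mean()) / p.std()
        grp = np.repeat(np.arange(12), 8)
        b = rng.normal(scale=0.2, size=12)[grp]
        eta = (-1.5 + t_slope * tz + p_slope * pz + interaction * tz * pz
               + b + rng.normal(scale=0.5, size=96))
        ab = pd.Series(1 / (1 + np.exp(-eta)), index=loc.index)
        return (ab, pd.Series(t, index=loc.index),
                pd.Series(p, index=loc.index), loc)

    def test_positive_temperature_slope_recovered(self):
        hits = 0
        for s in range(200):
            ab, t, p, loc = self.simulate(s, t_slope=1.0)
            res = cluster_climate_model(ab, t, p, loc).set_index("term")
            est = res.loc["temperature"]
            hits += (est["estimate"] > 0) and (est["p_value"] < 0.05)
        assert hits / 200 >= 0.90

    def test_type_i_rate_without_climate_effect(self):
        rejections = 0
        n_sims = 500
        for s in range(n_sims):
            ab, t, p, loc = self.simulate(50_000 + s)
            res = cluster_climate_model(ab, t, p, loc).set_index("term")
            rejections += res.loc["temperature", "p_value"] < 0.05
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_null_interaction_estimate_unbiased(self):
        ests, ses = [], []
        for s in range(200):
            ab, t, p, loc = self.simulate(90_000 + s, t_slope=0.8, p_slope=0.5)
            res = cluster_climate_model(ab, t, p, loc).set_index("term")
            ests.append(res.loc["temperature:precipitation", "estimate"])
            ses.append(res.loc["temperature:precipitation", "se"])
        mean_est = np.mean(ests)
        se_of_mean = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(mean_est) < 2 * se_of_mean + 2 * np.mean(ses) / np.sqrt(200)

    def test_degenerate_abundance_rejected(self):
        loc = _loc_series()
        ab = pd.Series(0.2, index=loc.index)
        t = pd.Series(np.repeat(np.tile([6.5, 8.5, 10.5], 4), 8), index=loc.index)
        p = pd.Series(np.repeat(np.tile([600, 1200, 2000, 2700], 3), 8), index=loc.index)
        with pytest.raises(ValidationError):
            cluster_climate_model(ab, t, p, loc)
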