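"""Core filtering, SparCC, network construction, modules, node roles and
natural-connectivity robustness."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from soilcomm import network as net
from soilcomm import simulate as sim


class TestCoreFilter:
    def _table(self):
        """10 samples at depth 10000; three diagnostic taxa plus filler."""
        depth = 10_000
        data = {}
        # kept: 7/10 prevalence, 0.2% when present (mean 0.14% > 0.1%)
        data["keep"] = [20] * 7 + [0] * 3
        # dropped: exactly 6/10 prevalence (not > 60%), abundant
        data["boundary"] = [500] * 6 + [0] * 4
        # dropped: 9/10 prevalence but mean 0.045% < 0.1%
        data["rare"] = [5] * 9 + [0]
        df = pd.DataFrame(data, index=[f"s{i}" for i in range(10)])
        df["filler"] = depth - df.sum(axis=1)
        return df

    def test_threshold_gates(self):
        kept = net.filter_core_asvs(self._table())
        assert "keep" in kept.columns
        assert "boundary" not in kept.columns  # strict > 60%
        assert "rare" not in kept.columns  # strict > 0.1%
        assert list(kept.index) == [f"s{i}" for i in range(10)]

    def test_empty_core_warns(self):
        df = pd.DataFrame({"a": [1, 0, 0, 0], "b": [999, 1000, 1000, 0], "c": [0, 0, 0, 1000]})
        with pytest.warns(UserWarning, match="core"):
            out = net.filter_core_asvs(df, prevalence=0.8, mean_rel_abund=0.001)
        assert out.shape[1] == 0


class TestSparcc:
    def test_algebraic_oracle_zero_covariance(self):
        """When true basis covariances vanish, T_ij = v_i + v_j and the
        basis system must return the exact variances and zero correlations;
        for 3 components this matches the closed form
        v_i = (T_ij + T_ik - T_jk) / 2."""
        v = np.array([0.5, 1.2, 2.0])
        t_mat = v[:, None] + v[None, :]
        np.fill_diagonal(t_mat, 0.0)
        corr, bad = net._basis_correlations(t_mat, exclusion_rounds=0,
                                            exclusion_threshold=1.0)
        closed_form = np.array(
            [
                (t_mat[0, 1] + t_mat[0, 2] - t_mat[1, 2]) / 2,
                (t_mat[0, 1] + t_mat[1, 2] - t_mat[0, 2]) / 2,
                (t_mat[0, 2] + t_mat[1, 2] - t_mat[0, 1]) / 2,
            ]
        )
        assert np.allclose(closed_form, v)
        assert len(bad) == 0
        off = corr - np.eye(3)
        assert np.allclose(off, 0.0, atol=1e-10)

    def test_sparcc_matches_planted_log_correlation(self):
        """End-to-end resampling tolerance check on a known basis
        correlation."""
        cfg = sim.SimulationConfig(
            n_taxa=8, depth=50_000, seed=3, planted_edges=[(0, 1, "+", 0.8)]
        )
        table, _ = sim.generate_correlated_counts(cfg, 400)
        corr = net.sparcc_correlations(table, n_inner_iter=10, seed=1)
        assert corr.iloc[0, 1] == pytest.approx(0.8, abs=0.15)

    def test_symmetry_unit_diagonal_bounds(self):
        cfg = sim.SimulationConfig(n_taxa=12, depth=3000, seed=8)
        table, _ = sim.generate_correlated_counts(cfg, 40)
        corr = net.sparcc_correlations(table, n_inner_iter=4, seed=2)
        arr = corr.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 1.0)
        assert (np.abs(arr) <= 1.0).all()

    def test_null_mean_correlation_small(self):
        cfg = sim.SimulationConfig(n_taxa=50, depth=5000, seed=12)
        table, _ = sim.generate_correlated_counts(cfg, 200)
        corr = net.sparcc_correlations(table, n_inner_iter=5, seed=0)
        iu = np.triu_indices(50, 1)
        assert np.abs(corr.to_numpy()[iu]).mean() < 0.1

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            net.sparcc_correlations(pd.DataFrame(np.ones((5, 3))))


class TestSparccPvalues:
    def test_planted_pair_hits_floor(self):
        cfg = sim.SimulationConfig(
            n_taxa=8, depth=10_000, seed=6, planted_edges=[(0, 1, "+", 0.9)]
        )
        table, _ = sim.generate_correlated_counts(cfg, 100)
        corr = net.sparcc_correlations(table, n_inner_iter=4, seed=1)
        p = net.sparcc_pvalues(table, corr, n_boot=100, seed=1, n_inner_iter=2)
        assert p.iloc[0, 1] == pytest.approx(1 / 101)

    def test_single_bootstrap_two_values(self):
        cfg = sim.SimulationConfig(n_taxa=6, depth=1000, seed=2)
        table, _ = sim.generate_correlated_counts(cfg, 30)
        corr = net.sparcc_correlations(table, n_inner_iter=2, seed=0)
        p = net.sparcc_pvalues(table, corr, n_boot=1, seed=0, n_inner_iter=2)
        iu = np.triu_indices(6, 1)
        assert set(np.round(p.to_numpy()[iu], 6)) <= {0.5, 1.0}


class TestBuildNetwork:
    def _matrices(self, r, p):
        ids = ["t1", "t2"]
        rm = pd.DataFrame([[1.0, r], [r, 1.0]], index=ids, columns=ids)
        pm = pd.DataFrame([[1.0, p], [p, 1.0]], index=ids, columns=ids)
        return rm, pm

    @pytest.mark.parametrize(
        "r,p,present,sign",
        [
            (0.61, 0.005, True, "positive"),
            (0.60, 0.005, False, None),  # strict |r| > 0.6
            (0.61, 0.01, False, None),  # strict p < 0.01
            (-0.7, 0.001, True, "negative"),
        ],
    )
    def test_edge_gates(self, r, p, present, sign):
        rm, pm = self._matrices(r, p)
        with pytest.warns(UserWarning) if not present else _nullcontext():
            g = net.build_network(rm, pm)
        assert g.has_edge("t1", "t2") == present
        if present:
            assert g.edges["t1", "t2"]["sign"] == sign

    def test_negative_edge_ratio(self):
        ids = list("abcd")
        r = np.eye(4)
        r[0, 1] = r[1, 0] = 0.9
        r[2, 3] = r[3, 2] = -0.9
        p = np.full((4, 4), 0.001)
        g = net.build_network(
            pd.DataFrame(r, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids),
        )
        assert g.graph["negative_edge_ratio"] == 0.5


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *args):
        return False


class TestTopologyAndModules:
    def test_triangle_metrics(self):
        g = nx.complete_graph(3)
        nx.set_edge_attributes(g, 1.0, "abs_weight")
        m = net.topology_metrics(g)
        assert m["density"] == 1.0
        assert m["mean_degree"] == 2.0

    def test_path_betweenness(self):
        g = nx.path_graph(3)
        nx.set_edge_attributes(g, 1.0, "abs_weight")
        cent = net.topology_metrics(g)["node_centralities"]
        assert cent.loc[1, "betweenness"] == 1.0
        assert cent.loc[0, "betweenness"] == 0.0

    def test_density_formula_oracle(self):
        g = nx.gnp_random_graph(20, 0.3, seed=4)
        nx.set_edge_attributes(g, 1.0, "abs_weight")
        m = net.topology_metrics(g)
        n, e = g.number_of_nodes(), g.number_of_edges()
        assert m["density"] == pytest.approx(2 * e / (n * (n - 1)))

    def test_two_cliques_two_modules(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        nx.set_edge_attributes(g, 1.0, "abs_weight")
        modules, q = net.detect_modules(g)
        assert len(set(modules.values())) == 2
        assert len({modules[i] for i in range(5)}) == 1
        assert len({modules[i] for i in range(5, 10)}) == 1
        assert q > 0.4

    def test_planted_two_block_recovery(self):
        rng = np.random.default_rng(0)
        g = nx.stochastic_block_model(
            [20, 20], [[0.5, 0.02], [0.02, 0.5]], seed=1
        )
        nx.set_edge_attributes(g, 1.0, "abs_weight")
        modules, _ = net.detect_modules(g)
        block = [0] * 20 + [1] * 20
        # agreement up to label swap
        agree = sum(modules[i] == modules[0] for i in range(20)) + sum(
            modules[i] != modules[0] for i in range(20, 40)
        )
        assert max(agree, 40 - agree) >= 36


class TestNodeRoles:
    @pytest.mark.parametrize(
        "z,c,expected",
        [
            (3.0, 0.7, "network hub"),
            (3.0, 0.5, "module hub"),
            (1.0, 0.7, "connector"),
            (1.0, 0.5, "peripheral"),
        ],
    )
    def test_role_quadrants(self, z, c, expected):
        assert net.classify_role(z, c) == expected

    def test_participation_coefficient(self):
        # hub node 0 in module 0 with 2 edges there and 2 into module 1
        g = nx.Graph()
        g.add_edges_from([(0, 1), (0, 2), (0, 3), (0, 4)])
        modules = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1}
        roles = net.node_roles(g, modules)
        assert roles.loc[0, "C"] == pytest.approx(0.5)  # 1 - (0.5^2 + 0.5^2)
        assert roles.loc[1, "C"] == 0.0  # all edges inside own module

    def test_within_module_degree_zscore(self):
        g = nx.complete_graph(4)
        g.add_edge(0, 4)  # node 0 has one extra within-module neighbour
        modules = {n: 0 for n in g}
        roles = net.node_roles(g, modules)
        k = np.array([4, 3, 3, 3, 1], dtype=float)
        expected = (k - k.mean()) / k.std(ddof=0)
        assert roles["Z"].to_numpy() == pytest.approx(expected)

    def test_degenerate_module_flagged(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        roles = net.node_roles(g, {"a": 0, "b": 1})
        assert roles["z_degenerate"].all()
        assert (roles["Z"] == 0).all()


class TestNaturalConnectivity:
    def test_closed_forms(self):
        empty = nx.empty_graph(5)
        assert net.natural_connectivity(empty) == pytest.approx(0.0, abs=1e-12)
        single = nx.Graph([(0, 1)])
        assert net.natural_connectivity(single) == pytest.approx(
            math.log(math.cosh(1)), abs=1e-9
        )
        k3 = nx.complete_graph(3)
        expected = math.log((math.exp(2) + 2 * math.exp(-1)) / 3)
        assert net.natural_connectivity(k3) == pytest.approx(expected, abs=1e-9)

    def test_nonnegative_and_monotone_under_edge_addition(self):
        rng = np.random.default_rng(11)
        for trial in range(50):
            g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(1 << 30)))
            base = net.natural_connectivity(g)
            assert base >= -1e-12
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            u, v = non_edges[int(rng.integers(len(non_edges)))]
            g.add_edge(u, v)
            assert net.natural_connectivity(g) > base


class TestRobustness:
    def test_fraction_zero_is_intact_value(self):
        g = nx.gnp_random_graph(15, 0.3, seed=2)
        curve = net.robustness_curve(g, fractions=[0.0, 0.2], n_reps=5, seed=0)
        assert curve.loc[0, "mean_nc"] == net.natural_connectivity(g)
        assert curve.loc[0, "sd_nc"] == 0.0

    def test_complete_graph_half_removal_exact(self):
        k10, k5 = nx.complete_graph(10), nx.complete_graph(5)
        curve = net.robustness_curve(k10, fractions=[0.5], n_reps=7, seed=3)
        assert curve.loc[0, "mean_nc"] == pytest.approx(
            net.natural_connectivity(k5), abs=1e-12
        )
        assert curve.loc[0, "sd_nc"] == pytest.approx(0.0, abs=1e-12)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            net.robustness_curve(nx.complete_graph(4), fractions=[1.0])
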