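"""MI estimation, DPI pruning, degree diagnostics, correlation networks
and Markov clustering."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from stemprime.io import GeneNetwork, StemprimeError
from stemprime.netinfer import (
    build_correlation_network,
    build_mi_network,
    degree_stats,
    estimate_mi,
    fit_power_law,
    markov_cluster,
    mi_permutation_p,
    prune_dpi,
)
from stemprime.synth import RegulatoryNetworkSpec, simulate_regulatory_expression
from conftest import make_expression


def gaussian_pair(rho, n, seed):
    r = np.random.default_rng(seed)
    x = r.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho**2) * r.standard_normal(n)
    return x, y


class TestEstimateMI:
    def test_symmetry_exact(self):
        x, y = gaussian_pair(0.6, 500, 0)
        assert estimate_mi(x, y).mi == estimate_mi(y, x).mi

    def test_independent_near_zero(self):
        # bound frozen from the simulated null of this estimator at n=2000
        r = np.random.default_rng(1)
        mi = estimate_mi(r.standard_normal(2000), r.standard_normal(2000)).mi
        assert mi < 0.05

    @pytest.mark.parametrize("rho,target", [(0.0, 0.0), (0.5, 0.1438), (0.9, 0.8304)])
    def test_gaussian_closed_form(self, rho, target):
        x, y = gaussian_pair(rho, 2000, 7)
        assert estimate_mi(x, y).mi == pytest.approx(target, abs=0.08)

    def test_identity_reaches_log_bins(self):
        x = np.random.default_rng(3).standard_normal(1000)
        est = estimate_mi(x, x, bins=8)
        assert est.mi == pytest.approx(np.log(8), abs=0.02)

    def test_constant_vector_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            est = estimate_mi(np.ones(50), np.arange(50.0))
        assert est.mi == 0.0

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(StemprimeError, match="mismatch"):
            estimate_mi(np.arange(10.0), np.arange(9.0))
        with pytest.raises(StemprimeError, match="at least 8"):
            estimate_mi(np.arange(5.0), np.arange(5.0))


class TestPermutationP:
    def test_identity_minimum_attainable_p(self):
        x = np.random.default_rng(0).standard_normal(200)
        assert mi_permutation_p(x, x, n_perm=99, seed=1) == pytest.approx(0.01)

    def test_zero_permutations_error(self):
        x = np.arange(20.0)
        with pytest.raises(StemprimeError):
            mi_permutation_p(x, x, n_perm=0)

    def test_null_p_roughly_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            x = rng.standard_normal(60)
            y = rng.standard_normal(60)
            ps.append(mi_permutation_p(x, y, n_perm=49, seed=int(rng.integers(1 << 30))))
        # attainable grid is {1/50 .. 50/50}; KS against uniform should not reject hard
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestMINetwork:
    def test_independent_genes_no_edges(self):
        rng = np.random.default_rng(11)
        m = make_expression(rng.standard_normal((3, 500)))
        net = build_mi_network(m, seed=0)
        assert net.n_edges == 0

    def test_chain_edges_present(self):
        spec = RegulatoryNetworkSpec(
            n_genes=3, n_edges=2, n_samples=400, n_layers=3,
            noise_sd=0.3, seed=2,
        )
        mat, truth = simulate_regulatory_expression(spec)
        net = build_mi_network(mat, seed=2)
        assert truth.edge_set() <= net.edge_set()

    def test_infinite_cutoff_empty(self):
        rng = np.random.default_rng(1)
        m = make_expression(rng.standard_normal((4, 100)))
        net = build_mi_network(m, mi_cutoff=np.inf, seed=0)
        assert net.n_edges == 0

    def test_single_gene_errors(self):
        m = make_expression(np.random.default_rng(0).standard_normal((1, 50)))
        with pytest.raises(StemprimeError):
            build_mi_network(m)


def brute_force_dpi(net: GeneNetwork, tolerance: float) -> set:
    """Independent oracle: enumerate every node triple."""
    g = net.graph
    doomed = set()
    for i, j, k in itertools.combinations(sorted(g.nodes), 3):
        tri = [(i, j, k), (i, k, j), (j, k, i)]
        for a, b, c in tri:
            if g.has_edge(a, b) and g.has_edge(a, c) and g.has_edge(b, c):
                w_ab = g.edges[a, b]["weight"]
                bound = min(g.edges[a, c]["weight"], g.edges[b, c]["weight"])
                if w_ab < (1 - tolerance) * bound:
                    doomed.add(frozenset((a, b)))
    return {frozenset(e) for e in net.edge_set()} - doomed


class TestDPI:
    def triangle(self, wab, wbc, wac):
        return GeneNetwork.from_edges(
            [("A", "B", wab), ("B", "C", wbc), ("A", "C", wac)], "mi"
        )

    def test_weak_indirect_edge_removed(self):
        out = prune_dpi(self.triangle(0.9, 0.8, 0.3), 0.1)
        assert out.edge_set() == {frozenset("AB"), frozenset("BC")}

    def test_close_triangle_untouched(self):
        out = prune_dpi(self.triangle(0.9, 0.8, 0.75), 0.1)
        assert out.n_edges == 3

    def test_non_mi_weights_rejected(self):
        net = GeneNetwork.from_edges([("A", "B", 0.9)], "pearson")
        with pytest.raises(StemprimeError, match="MI"):
            prune_dpi(net)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 26))
        nodes = [f"n{i:02d}" for i in range(n)]
        edges = [
            (nodes[i], nodes[j], float(rng.uniform(0.05, 1.0)))
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.3
        ]
        net = GeneNetwork.from_edges(edges, "mi", nodes=nodes)
        pruned = prune_dpi(net, 0.1)
        assert pruned.edge_set() == brute_force_dpi(net, 0.1)

    def test_never_adds_and_idempotent(self):
        rng = np.random.default_rng(77)
        nodes = [f"n{i}" for i in range(15)]
        edges = [
            (nodes[i], nodes[j], float(rng.uniform(0.05, 1.0)))
            for i in range(15)
            for j in range(i + 1, 15)
            if rng.random() < 0.4
        ]
        net = GeneNetwork.from_edges(edges, "mi", nodes=nodes)
        once = prune_dpi(net, 0.1)
        assert once.edge_set() <= net.edge_set()
        twice = prune_dpi(once, 0.1)
        assert twice.edge_set() == once.edge_set()


class TestDegreeAndPowerLaw:
    def test_star_graph(self):
        edges = [("hub", f"leaf{i}", 0.5) for i in range(5)]
        net = GeneNetwork.from_edges(edges, "mi")
        deg, e, mean_deg = degree_stats(net)
        assert e == 5 and mean_deg == pytest.approx(2 * 5 / 6)
        assert sorted(deg) == [1, 1, 1, 1, 1, 5]

    def test_exact_line_r2_one(self):
        deg = np.repeat([1, 2, 4, 8], [64, 16, 4, 1])  # N(k) = 64 k^-2
        fit = fit_power_law(pd.Series(deg))
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.gamma == pytest.approx(2.0, abs=1e-9)

    def test_rounded_power_law_constructions(self):
        k_full = np.arange(1, 31)
        counts_full = np.round(1000.0 * k_full**-2.2).astype(int)
        fit_full = fit_power_law(pd.Series(np.repeat(k_full, counts_full)))
        # oracle-computed: rounded-up tail counts flatten the slope
        assert fit_full.gamma == pytest.approx(2.111, abs=0.01)
        # restricted to degrees whose exact count is >= 1 the slope recovers
        k = k_full[1000.0 * k_full**-2.2 >= 1]
        counts = np.round(1000.0 * k**-2.2).astype(int)
        fit = fit_power_law(pd.Series(np.repeat(k, counts)))
        assert fit.gamma == pytest.approx(2.2, abs=0.05)
        assert fit.r_squared >= 0.99

    def test_all_isolated_errors(self):
        net = GeneNetwork.from_edges([], "mi", nodes=["a", "b"])
        with pytest.raises(StemprimeError):
            degree_stats(net)


class TestCorrelationNetwork:
    def test_perfect_correlation_edge(self):
        x = np.arange(10.0)
        m = make_expression(np.vstack([x, 2 * x + 1]))
        net = build_correlation_network(m, 0.9)
        assert net.n_edges == 1

    def test_anticorrelation_no_edge(self):
        x = np.arange(10.0)
        m = make_expression(np.vstack([x, -x]))
        net = build_correlation_network(m, 0.55)
        assert net.n_edges == 0  # signed r: negative correlation excluded

    def test_constant_gene_warned_and_excluded(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning, match="constant"):
            net = build_correlation_network(make_expression(np.vstack([x, np.ones(10)])), 0.5)
        assert net.n_edges == 0

    def test_planted_modules_dense_within(self, rng):
        # two independent latent factors drive two 10-gene modules
        n = 120
        z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
        rows = [z1 + 0.4 * rng.standard_normal(n) for _ in range(10)] + [
            z2 + 0.4 * rng.standard_normal(n) for _ in range(10)
        ]
        net = build_correlation_network(make_expression(np.array(rows)), 0.55)
        within = between = 0
        for u, v in net.graph.edges:
            same = (int(u[1:]) < 10) == (int(v[1:]) < 10)
            within += same
            between += not same
        assert within >= 10 * max(between, 1)


class TestMCL:
    def two_cliques(self, names_a=("A0", "A1", "A2", "A3"), names_b=("B0", "B1", "B2", "B3")):
        g = nx.Graph()
        for grp in (names_a, names_b):
            for u, v in itertools.combinations(grp, 2):
                g.add_edge(u, v, weight=1.0)
        g.add_edge(names_a[0], names_b[0], weight=1.0)
        return GeneNetwork(g, "pearson")

    def test_two_cliques_split(self):
        cl = markov_cluster(self.two_cliques(), inflation=2.0)
        assert cl.n_clusters == 2
        assert cl.members(1) == {"A0", "A1", "A2", "A3"}
        assert cl.members(2) == {"B0", "B1", "B2", "B3"}

    def test_single_edge_one_cluster(self):
        net = GeneNetwork.from_edges([("x", "y", 1.0)], "pearson")
        cl = markov_cluster(net)
        assert cl.n_clusters == 1 and cl.members(1) == {"x", "y"}

    def test_relabeling_invariance(self):
        cl1 = markov_cluster(self.two_cliques())
        relabeled = self.two_cliques(
            names_a=("zz0", "zz1", "zz2", "zz3"), names_b=("aa0", "aa1", "aa2", "aa3")
        )
        cl2 = markov_cluster(relabeled)
        # same partition structure under relabeling
        parts1 = sorted(len(cl1.members(c)) for c in range(1, cl1.n_clusters + 1))
        parts2 = sorted(len(cl2.members(c)) for c in range(1, cl2.n_clusters + 1))
        assert parts1 == parts2 == [4, 4]
        assert cl2.members(1) == {"aa0", "aa1", "aa2", "aa3"}  # ordering convention

    def test_empty_graph_errors(self):
        with pytest.raises(StemprimeError):
            markov_cluster(GeneNetwork(nx.Graph(), "pearson"))


def test_edge_recovery_on_cascade():
    """MI network + DPI at default thresholds recovers the planted
    skeleton within the calibrated precision/recall band."""
    mat, truth = simulate_regulatory_expression(RegulatoryNetworkSpec(seed=0))
    net = build_mi_network(mat, seed=0)
    pruned = prune_dpi(net, 0.1)
    T, F = truth.edge_set(), pruned.edge_set()
    tp = len(T & F)
    assert tp / max(len(F), 1) >= 0.8
    assert tp / len(T) >= 0.6
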