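import itertools

import numpy as np
import pytest
from scipy import stats

from dyadnet.core_data import DataError, TaxaTable
from dyadnet.interkingdom_network import (
    build_network,
    compare_connectedness,
    layout_network,
    prevalence_filter,
    spearman_edge,
)
from dyadnet.synthetic_data import CohortConfig, generate_cohort, null_cohort


def table(counts, kingdom="bacteria", prefix="t"):
    counts = np.asarray(counts, dtype=float)
    taxa = [f"{prefix}{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    return TaxaTable(kingdom, taxa, samples, counts)


class TestPrevalenceFilter:
    def test_boundary_inclusive_3_of_10(self):
        counts = np.zeros((1, 10))
        counts[0, :3] = 1
        t = table(counts)
        assert prevalence_filter(t, 0.30).taxa_ids == ["t0"]

    def test_below_boundary_dropped(self):
        counts = np.vstack([np.ones(10), np.r_[np.ones(2), np.zeros(8)]])
        t = table(counts)
        assert prevalence_filter(t, 0.30).taxa_ids == ["t0"]

    def test_threshold_zero_rejected(self):
        t = table(np.ones((2, 4)))
        with pytest.raises(DataError, match="min_prevalence"):
            prevalence_filter(t, 0.0)

    def test_threshold_one_keeps_only_ubiquitous(self):
        counts = np.vstack([np.ones(5), np.r_[np.ones(4), 0]])
        t = table(counts)
        assert prevalence_filter(t, 1.0).taxa_ids == ["t0"]

    def test_all_removed_errors(self):
        counts = np.zeros((2, 10))
        counts[:, 0] = 1
        t = table(counts)
        with pytest.raises(DataError, match="removed all"):
            prevalence_filter(t, 0.5)


class TestSpearmanEdge:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        rho, p = spearman_edge(x, x**3 + 2)
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_perfect_antitone(self):
        rho, _ = spearman_edge(np.array([1.0, 2, 3, 4, 5]),
                               np.array([5.0, 4, 3, 2, 1]))
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_brute_force_n4(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 1, 4, 3])
        rho, p = spearman_edge(x, y, exact=True)
        assert rho == pytest.approx(0.6)
        # independent oracle: spearman over all 4! orderings via scipy
        rhos = [stats.spearmanr(x, np.array(perm)).statistic
                for perm in itertools.permutations(y)]
        p_oracle = np.mean([abs(r) >= 0.6 - 1e-12 for r in rhos])
        assert p == pytest.approx(p_oracle)

    def test_t_approx_close_to_exact_n7(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        _, p_t = spearman_edge(x, y)
        _, p_exact = spearman_edge(x, y, exact=True)
        assert abs(p_t - p_exact) < 0.06

    def test_constant_vector_rejected(self):
        with pytest.raises(DataError, match="constant"):
            spearman_edge(np.ones(5), np.arange(5.0))

    def test_short_vector_rejected(self):
        with pytest.raises(DataError, match="n >= 4"):
            spearman_edge(np.arange(3.0), np.arange(3.0))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho1, p1 = spearman_edge(x, y)
        rho2, p2 = spearman_edge(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)


class TestBuildNetwork:
    def test_connectedness_definition(self):
        # 5/6 edges per node, the scale of the strongest published contrast
        rng = np.random.default_rng(2)
        n = 30
        z = rng.normal(size=n)
        bact = table(np.exp(rng.normal(size=(3, n)) + z), "bacteria", "b")
        fung = table(np.exp(rng.normal(size=(3, n)) + z), "fungi", "f")
        net = build_network(bact, fung, alpha=1.1, min_prevalence=0.01)
        # alpha > 1 keeps every pair: 9 edges over 6 nodes
        assert net.n_nodes == 6
        assert net.n_edges == 9
        assert net.connectedness == pytest.approx(9 / 6)

    def test_connectedness_matches_independent_recount(self):
        bact, fung = null_cohort(40, 8, 6, seed=3)
        net = build_network(bact, fung)
        recount = sum(1 for _ in net.edges)
        assert net.connectedness == recount / (len(net.bact_nodes)
                                               + len(net.fung_nodes))

    def test_edges_are_interkingdom_and_significant(self):
        bact, fung = null_cohort(50, 10, 8, seed=4)
        net = build_network(bact, fung, alpha=0.05)
        bset, fset = set(net.bact_nodes), set(net.fung_nodes)
        for e in net.edges:
            assert e.bact in bset and e.fung in fset
            assert e.p < 0.05
            assert abs(e.rho) <= 1
            assert e.sign == ("positive" if e.rho > 0 else "negative")

    def test_misaligned_tables_error(self):
        bact, fung = null_cohort(10, 3, 3, seed=5)
        fung2 = fung.select_samples(list(reversed(fung.sample_ids)))
        with pytest.raises(DataError, match="aligned"):
            build_network(bact, fung2)

    def test_planted_edges_recovered(self):
        cfg = CohortConfig(
            n_dyads=30, n_bact=10, n_fung=8, baseline_log_sd=1.0,
            sample_type_log_sd=0.2, latent_log_sd=1.5,
            depth_mean_bact=10000, depth_mean_fung=5000,
            planted_edges=[("bact_001", "fung_001", 0.8),
                           ("bact_002", "fung_002", -0.8)],
            seed=6)
        bact, fung, _, _ = generate_cohort(cfg)
        net = build_network(bact, fung)
        found = {(e.bact, e.fung): e for e in net.edges}
        assert ("bact_001", "fung_001") in found
        assert ("bact_002", "fung_002") in found
        assert found[("bact_001", "fung_001")].sign == "positive"
        assert found[("bact_002", "fung_002")].sign == "negative"

    def test_edge_set_invariant_to_depth_rescaling(self):
        # scaling each sample's counts by a positive constant leaves
        # proportions, hence ranks, hence the edge set unchanged
        bact, fung = null_cohort(30, 6, 5, seed=7)
        net1 = build_network(bact, fung)
        rng = np.random.default_rng(7)
        scales = rng.uniform(1.0, 20.0, bact.n_samples)  # >=1 keeps presence
        bact2 = TaxaTable("bacteria", bact.taxa_ids, bact.sample_ids,
                          bact.counts * scales)
        fung2 = TaxaTable("fungi", fung.taxa_ids, fung.sample_ids,
                          fung.counts * scales)
        net2 = build_network(bact2, fung2)
        assert {(e.bact, e.fung) for e in net1.edges} == {
            (e.bact, e.fung) for e in net2.edges}

    def test_bh_mode_is_sparser(self):
        bact, fung = null_cohort(60, 10, 10, seed=8)
        raw = build_network(bact, fung)
        bh = build_network(bact, fung, bh_correct=True)
        assert bh.n_edges <= raw.n_edges

    def test_node_roster_includes_edgeless_taxa(self):
        bact, fung = null_cohort(40, 6, 6, seed=9)
        net = build_network(bact, fung, alpha=1e-10)
        assert net.n_nodes == len(net.bact_nodes) + len(net.fung_nodes)
        assert net.n_nodes > 0


class TestCompareConnectedness:
    def test_identical_networks(self):
        bact, fung = null_cohort(40, 6, 6, seed=10)
        net = build_network(bact, fung)
        t, p, diff = compare_connectedness(net, net)
        assert t == 0.0
        assert p == 1.0
        assert diff == 0.0

    def test_separated_networks_small_p(self):
        rng = np.random.default_rng(11)
        n = 40
        z = rng.normal(size=n)
        # alternating signs so the shared factor does not cancel in the
        # within-kingdom proportions
        signs = np.array([3.0, -3.0, 3.0, -3.0])[:, None]
        bact = table(np.exp(rng.normal(size=(4, n)) * 0.1 + signs * z),
                     "bacteria", "b")
        fung = table(np.exp(rng.normal(size=(4, n)) * 0.1 + signs * z),
                     "fungi", "f")
        dense = build_network(bact, fung, min_prevalence=0.01)
        assert dense.n_edges > 0
        b2, f2 = null_cohort(40, 4, 4, seed=12)
        empty = build_network(b2, f2, alpha=1e-12)
        assert empty.n_edges == 0
        t, p, diff = compare_connectedness(dense, empty)
        assert p < 0.01
        assert t > 0 and diff > 0

    def test_tiny_network_rejected(self):
        from dyadnet.interkingdom_network import InterkingdomNetwork

        bact, fung = null_cohort(40, 6, 6, seed=13)
        net = build_network(bact, fung)
        tiny = InterkingdomNetwork(bact_nodes=["b0"], fung_nodes=[],
                                   edges=[], n_samples=10, alpha=0.05)
        with pytest.raises(DataError, match="2 nodes"):
            compare_connectedness(net, tiny)


class TestLayout:
    def test_deterministic(self):
        bact, fung = null_cohort(40, 5, 5, seed=14)
        net = build_network(bact, fung)
        pos1 = layout_network(net, seed=3)
        pos2 = layout_network(net, seed=3)
        for n in pos1:
            np.testing.assert_array_equal(pos1[n], pos2[n])

    def test_edgeless_graph_not_collapsed(self):
        bact, fung = null_cohort(40, 4, 4, seed=15)
        net = build_network(bact, fung, alpha=1e-15)
        assert net.n_edges == 0
        pos = layout_network(net, seed=0)
        pts = np.array(list(pos.values()))
        dmin = min(np.linalg.norm(pts[i] - pts[j])
                   for i in range(len(pts)) for j in range(i + 1, len(pts)))
        assert dmin > 0

    def test_coordinates_finite(self):
        bact, fung = null_cohort(30, 6, 5, seed=16)
        net = build_network(bact, fung)
        for xy in layout_network(net, seed=1).values():
            assert np.all(np.isfinite(xy))


class TestExports:
    def test_edge_tsv_and_graphml(self, tmp_path):
        bact, fung = null_cohort(40, 6, 6, seed=17)
        net = build_network(bact, fung)
        edge_path = tmp_path / "edges.tsv"
        net.to_edge_tsv(edge_path)
        lines = edge_path.read_text().splitlines()
        assert lines[0].split("\t") == ["bact", "fung", "rho", "p", "sign"]
        assert len(lines) == net.n_edges + 1

        gml = tmp_path / "net.graphml"
        net.to_graphml(gml)
        import networkx as nx

        g = nx.read_graphml(gml)
        assert g.number_of_nodes() == net.n_nodes
        assert g.number_of_edges() == net.n_edges
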