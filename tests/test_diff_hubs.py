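"""Differential chromatin-interaction hubs: edge selection, clustering,
genomic projection and Wilcoxon significance."""

import itertools

import igraph as ig
import numpy as np
import pandas as pd
import pytest

from chromarch import (
    AnalysisConfig,
    ContactMap,
    GenomicInterval,
    call_diff_hubs,
    cluster_diff_network,
    joint_balance,
    kr_balance,
    project_cluster,
    select_directional_edges,
    test_region_significance,
)
from chromarch.diff_hubs import DiffNetwork
from chromarch.intervals import GeneModel
from chromarch.diff_hubs import associate_genes_to_hubs, DiffHub
from chromarch.simulate import SimulationSpec, pooled_map, simulate_contact_maps


def balanced_map(counts, bin_size=10_000):
    m = ContactMap("chr1", bin_size, counts)
    m.weights = np.ones(counts.shape[0])
    return m


def pair_maps(wt_entries, dko_entries, n=6):
    def build(entries):
        c = np.zeros((n, n))
        for (i, j), v in entries.items():
            c[i, j] = v
            c[j, i] = v
        return balanced_map(c)
    return build(wt_entries), build(dko_entries)


class TestSelectDirectionalEdges:
    def test_weak_sum_boundary_excluded(self):
        wt, dko = pair_maps({(0, 1): 6}, {(0, 1): 4})
        # depth matching rescales; use equal totals so values stay printed
        wt.counts[3, 4] = wt.counts[4, 3] = 10
        dko.counts[3, 4] = dko.counts[4, 3] = 12
        edges = select_directional_edges(wt, dko, "WT-specific")
        assert not ((edges["bin_i"] == 0) & (edges["bin_j"] == 1)).any()

    def test_boundary_plus_one_kept(self):
        wt, dko = pair_maps({(0, 1): 7, (2, 3): 10}, {(0, 1): 4, (2, 3): 13})
        edges = select_directional_edges(wt, dko, "WT-specific")
        assert ((edges["bin_i"] == 0) & (edges["bin_j"] == 1)).any()

    def test_equal_maps_no_edges(self):
        wt, dko = pair_maps({(0, 1): 50}, {(0, 1): 50})
        assert len(select_directional_edges(wt, dko, "WT-specific")) == 0

    def test_direction_disjointness(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(30, (8, 8)).astype(float)
        b = rng.poisson(30, (8, 8)).astype(float)
        wt = balanced_map(((a + a.T) / 2))
        dko = balanced_map(((b + b.T) / 2))
        up = select_directional_edges(wt, dko, "dKO-specific")
        down = select_directional_edges(wt, dko, "WT-specific")
        pairs_up = set(zip(up["bin_i"], up["bin_j"]))
        pairs_down = set(zip(down["bin_i"], down["bin_j"]))
        assert pairs_up.isdisjoint(pairs_down)

    def test_grid_mismatch_error(self):
        wt = balanced_map(np.zeros((4, 4)))
        dko = balanced_map(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            select_directional_edges(wt, dko, "WT-specific")


class TestClusterDiffNetwork:
    def test_disjoint_edge_sets_two_clusters(self):
        edges = pd.DataFrame({"bin_i": [0, 10], "bin_j": [1, 11],
                              "wt": [20.0, 20.0], "dko": [5.0, 5.0]})
        net = cluster_diff_network(edges, "WT-specific", seed=0)
        assert len(net.clusters) == 2

    def test_weighted_chain_grouping_matches_modularity_oracle(self):
        # chain A-B-C with weights 10 and 1: B sides with A
        edges = pd.DataFrame({"bin_i": [0, 1], "bin_j": [1, 2],
                              "wt": [10.0, 1.0], "dko": [1.0, 1.0]})
        net = cluster_diff_network(edges, "WT-specific", seed=0)
        g = ig.Graph(n=3, edges=[(0, 1), (1, 2)])
        best_q, best = -1, None
        for bits in itertools.product([0, 1], repeat=2):
            mem = [0] + list(bits)
            q = g.modularity(mem, weights=[10.0, 1.0])
            if q > best_q:
                best_q, best = q, mem
        oracle = {frozenset(i for i, m in enumerate(best) if m == s)
                  for s in set(best)}
        ours = {frozenset(net.bins[v] for v in c) for c in net.clusters}
        assert ours == oracle

    def test_nodes_exist_only_via_edges(self):
        edges = pd.DataFrame({"bin_i": [3], "bin_j": [9],
                              "wt": [15.0], "dko": [2.0]})
        net = cluster_diff_network(edges, "WT-specific", seed=0)
        assert sorted(net.bins) == [3, 9]


def make_network(bins, degree, pagerank):
    g = ig.Graph(n=len(bins))
    return DiffNetwork(g, np.array(bins), [list(range(len(bins)))],
                       np.array(degree, dtype=float),
                       np.array(pagerank, dtype=float))


class TestProjectCluster:
    def test_singleton(self):
        net = make_network([42], [0], [1.0])
        seed, member, region = project_cluster([0], net, 10_000, "chr1")
        assert seed == 42 and member == [42]
        assert (region.start, region.end) == (420_000, 430_000)

    def test_printed_inequality_evaluation(self):
        # seed bin 100; node at distance 3 with degree 4: 4/9 < 0.5 included;
        # node at distance 2 with degree 4: 1.0 not < 0.5, excluded
        net = make_network([100, 103, 102], [10, 4, 4], [0.9, 0.05, 0.05])
        seed, member, region = project_cluster([0, 1, 2], net, 10_000, "chr1",
                                               comparator="lt")
        assert seed == 100
        assert member == [100, 103]

    def test_inverted_comparator(self):
        net = make_network([100, 103, 102], [10, 4, 4], [0.9, 0.05, 0.05])
        _, member, _ = project_cluster([0, 1, 2], net, 10_000, "chr1",
                                       comparator="ge")
        assert member == [100, 102]

    def test_all_excluded_region_is_seed_bin(self):
        net = make_network([100, 101], [10, 100], [0.9, 0.1])
        _, member, region = project_cluster([0, 1], net, 10_000, "chr1",
                                            comparator="lt")
        assert member == [100]
        assert (region.start, region.end) == (1_000_000, 1_010_000)

    def test_region_contains_seed_and_is_contiguous(self):
        net = make_network([10, 30, 50], [1, 20, 1], [0.1, 0.8, 0.1])
        seed, member, region = project_cluster([0, 1, 2], net, 10_000, "chr1")
        assert region.start <= seed * 10_000 < region.end
        assert region.end - region.start == (max(member) - min(member) + 1) * 10_000

    def test_duplicate_bin_skipped(self):
        net = make_network([5, 5], [3, 3], [0.9, 0.1])
        _, member, _ = project_cluster([0, 1], net, 10_000, "chr1")
        assert member == [5]


class TestRegionSignificance:
    def test_equal_maps_p_one(self):
        wt, dko = pair_maps({(0, 1): 20, (1, 2): 30}, {(0, 1): 20, (1, 2): 30})
        p, _ = test_region_significance(GenomicInterval("chr1", 0, 30_000),
                                        wt, dko)
        assert p == 1.0

    def test_exact_unit_difference_example(self):
        # 5-bin region -> 10 internal pairs, all wt = dko + 1; diagonals
        # compensate so totals match and depth matching is a no-op
        n = 5
        base = np.arange(1, n * n + 1, dtype=float).reshape(n, n)
        base = (base + base.T) / 2
        np.fill_diagonal(base, 50.0)
        wt_counts = base + 1 - np.eye(n) * (1 + (n - 1))
        wt = balanced_map(wt_counts)
        dko = balanced_map(base)
        assert wt.counts.sum() == dko.counts.sum()
        p, npairs = test_region_significance(
            GenomicInterval("chr1", 0, n * 10_000), wt, dko, "WT-specific")
        assert npairs == 10
        assert p == pytest.approx(1 / 2 ** 10)

    def test_direction_flip_not_significant(self):
        n = 8
        rng = np.random.default_rng(1)
        base = rng.poisson(50, (n, n)).astype(float)
        base = (base + base.T) / 2
        wt_counts = base.copy()
        wt_counts[:5, :5] *= 3.0  # elevated only inside the tested region
        wt = balanced_map(wt_counts)
        dko = balanced_map(base)
        region = GenomicInterval("chr1", 0, 5 * 10_000)
        p_right, _ = test_region_significance(region, wt, dko, "WT-specific")
        p_wrong, _ = test_region_significance(region, wt, dko, "dKO-specific")
        assert p_right < 0.05 and p_wrong >= 0.5


@pytest.fixture(scope="module")
def planted():
    spec = SimulationSpec(diff_region=(10_000_000, 10_300_000),
                          diff_fold=3.0, seed=1)
    maps, truth = simulate_contact_maps(spec)
    wt = kr_balance(pooled_map(maps["WT"]))
    dko = kr_balance(pooled_map(maps["dKO"]))
    return wt, dko, truth


class TestCallDiffHubs:
    def test_planted_region_recovered(self, planted):
        wt, dko, truth = planted
        hubs = call_diff_hubs(wt, dko, "WT-specific", seed=1)
        assert len(hubs) == 1
        lo, hi = truth["diff_region"]
        h = hubs[0]
        inter = max(0, min(h.region.end, hi) - max(h.region.start, lo))
        union = max(h.region.end, hi) - min(h.region.start, lo)
        assert inter / union >= 0.6
        assert h.seed_bin in h.member_bins
        assert h.p_value < 1e-7

    def test_label_swap_symmetry(self, planted):
        wt, dko, _ = planted
        fwd = call_diff_hubs(wt, dko, "WT-specific", seed=1)
        rev = call_diff_hubs(dko, wt, "dKO-specific", seed=1)
        assert [(h.region.start, h.region.end) for h in fwd] == \
               [(h.region.start, h.region.end) for h in rev]
        assert all(h.condition == "dKO-specific" for h in rev)

    def test_determinism(self, planted):
        wt, dko, _ = planted
        a = call_diff_hubs(wt, dko, "WT-specific", seed=5)
        b = call_diff_hubs(wt, dko, "WT-specific", seed=5)
        assert [(h.region.start, h.region.end, h.p_value) for h in a] == \
               [(h.region.start, h.region.end, h.p_value) for h in b]

    def test_joint_balance_weights_shared(self, planted):
        wt, dko, _ = planted
        jw, jd = joint_balance(wt, dko)
        ok = ~np.isnan(jw.weights)
        np.testing.assert_array_equal(jw.weights[ok], jd.weights[ok])


class TestGeneAssociation:
    hub = DiffHub("WT-specific", 1000, [1000, 1001],
                  GenomicInterval("chr1", 10_000_000, 10_020_000), 1e-9, 1)

    def test_promoter_inside_hub(self):
        g = GeneModel("gA", "chr1", 10_005_000, 10_009_000, "+")
        t = associate_genes_to_hubs([self.hub], [g])
        assert list(t["gene"]) == ["gA"]

    def test_promoter_past_half_open_end(self):
        # promoter [10_021_000, 10_023_000) starts 1 kb past the region end
        g = GeneModel("gB", "chr1", 10_022_000, 10_030_000, "+")
        t = associate_genes_to_hubs([self.hub], [g], promoter_flank=1_000)
        assert t.empty

    def test_duplicate_tss_two_rows(self):
        g1 = GeneModel("gC", "chr1", 10_001_000, 10_004_000, "+")
        hub2 = DiffHub("WT-specific", 2000, [2000],
                       GenomicInterval("chr1", 10_000_000, 10_002_000),
                       1e-9, 1)
        t = associate_genes_to_hubs([self.hub, hub2], [g1])
        assert len(t) == 2
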