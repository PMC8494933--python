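"""Loop annotation, the anchor network, elbow threshold and hub calling."""

import itertools

import igraph as ig
import numpy as np
import pytest

from chromarch import (
    ContactMap,
    GenomicInterval,
    Loop,
    LoopSet,
    annotate_loops,
    build_loop_graph,
    count_loop_anchor_pairs,
    detect_communities,
    elbow_threshold,
    identify_hubs,
    relative_loop_strength,
)
from chromarch.simulate import simulate_loop_universe


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestAnnotateLoops:
    promoters = [iv(1_000, 3_000), iv(50_000, 52_000)]
    chracc = [iv(2_000, 2_500), iv(20_000, 21_000), iv(60_000, 61_000)]

    def annotate(self, a1, a2):
        loops = LoopSet([Loop(a1, a2)])
        return annotate_loops(loops, self.promoters, self.chracc).loops[0]

    def test_pp_takes_precedence_over_chracc(self):
        # anchor1 overlaps both a promoter and an accessible site
        lp = self.annotate(iv(1_500, 2_200), iv(49_000, 51_000))
        assert lp.annotation == "PP"

    def test_pe(self):
        lp = self.annotate(iv(900, 1_100), iv(20_500, 20_800))
        assert lp.annotation == "PE"

    def test_ee(self):
        lp = self.annotate(iv(20_000, 20_500), iv(60_000, 60_500))
        assert lp.annotation == "EE"

    def test_other(self):
        lp = self.annotate(iv(100_000, 101_000), iv(200_000, 201_000))
        assert lp.annotation == "other"


class TestBuildLoopGraph:
    def test_shared_identical_anchor(self):
        a = iv(0, 10_000)
        loops = LoopSet([Loop(a, iv(50_000, 60_000)),
                         Loop(a, iv(90_000, 100_000))])
        lg = build_loop_graph(loops)
        assert lg.graph.vcount() == 3 and lg.graph.ecount() == 2

    def test_one_bp_overlap_merges(self):
        loops = LoopSet([
            Loop(iv(0, 10_001), iv(50_000, 60_000)),
            Loop(iv(10_000, 20_000), iv(90_000, 100_000)),
        ])
        lg = build_loop_graph(loops)
        assert lg.graph.vcount() == 3
        merged = [a for a in lg.anchors if a.start == 0]
        assert merged and merged[0].end == 20_000

    def test_touching_anchors_stay_separate(self):
        loops = LoopSet([
            Loop(iv(0, 10_000), iv(50_000, 60_000)),
            Loop(iv(10_000, 20_000), iv(90_000, 100_000)),
        ])
        assert build_loop_graph(loops).graph.vcount() == 4

    def test_self_edge_rejected(self):
        loops = LoopSet([Loop(iv(0, 10_000), iv(9_000, 20_000))])
        lg = build_loop_graph(loops)
        assert lg.graph.ecount() == 0 and lg.n_dropped_self == 1

    def test_duplicate_collapsed(self):
        loops = LoopSet([Loop(iv(0, 10_000), iv(50_000, 60_000)),
                         Loop(iv(0, 10_000), iv(50_000, 60_000))])
        lg = build_loop_graph(loops)
        assert lg.graph.ecount() == 1 and lg.n_collapsed == 1


def modularity_best_two_partition(g):
    """Brute-force best modularity over all 2-partitions (and the trivial 1)."""
    n = g.vcount()
    best, best_part = -1.0, None
    for bits in itertools.product([0, 1], repeat=n - 1):
        membership = [0] + list(bits)
        q = g.modularity(membership)
        if q > best:
            best, best_part = q, membership
    return best, best_part


class TestCommunities:
    def test_two_cliques_split(self):
        g = ig.Graph.Full(5) + ig.Graph.Full(5)
        g.add_edges([(0, 5)])
        g.es["weight"] = 1.0
        comms = detect_communities(g, seed=0)
        assert sorted(len(c) for c in comms) == [5, 5]
        # agrees with the exhaustive 2-partition modularity oracle
        _, best = modularity_best_two_partition(g)
        oracle = [set(i for i, m in enumerate(best) if m == s) for s in (0, 1)]
        assert {frozenset(c) for c in comms} == {frozenset(s) for s in oracle}

    def test_edgeless_graph_singletons(self):
        g = ig.Graph(n=4)
        g.es["weight"] = []
        comms = detect_communities(g, seed=0)
        assert sorted(len(c) for c in comms) == [1, 1, 1, 1]

    def test_triangle_single_cluster(self):
        g = ig.Graph(n=3, edges=[(0, 1), (1, 2), (0, 2)])
        g.es["weight"] = 1.0
        assert len(detect_communities(g, seed=0)) == 1

    def test_partition_covers_nodes_once(self):
        loops, _ = simulate_loop_universe(3, (5, 9), 20, seed=4)
        lg = build_loop_graph(loops)
        comms = detect_communities(lg.graph, seed=0)
        flat = sorted(v for c in comms for v in c)
        assert flat == list(range(lg.graph.vcount()))


def tangency_oracle(values):
    """Exhaustive scan for the scaled point farthest below the diagonal."""
    v = np.sort(np.asarray(values, dtype=float))
    x = np.arange(len(v)) / (len(v) - 1)
    y = (v - v[0]) / (v[-1] - v[0])
    gaps = x - y
    best = max(range(len(v)), key=lambda i: (gaps[i], i))
    return float(v[best])


class TestElbowThreshold:
    def test_matches_bruteforce_oracle(self):
        sizes = [1, 1, 1, 2, 2, 3, 5, 9, 20, 40]
        assert elbow_threshold(sizes) == tangency_oracle(sizes)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_curves(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.sort(rng.lognormal(1, 1, 50))
        assert elbow_threshold(vals) == tangency_oracle(vals)

    def test_linear_curve_returns_max(self):
        vals = np.arange(1.0, 11.0)
        assert elbow_threshold(vals) == 10.0

    def test_affine_invariance_of_selected_index(self):
        vals = np.array([1, 1, 2, 3, 5, 9, 20, 40], dtype=float)
        t1 = elbow_threshold(vals)
        t2 = elbow_threshold(3.0 * vals + 7.0)
        assert t2 == pytest.approx(3.0 * t1 + 7.0)

    def test_degenerate_input(self):
        assert elbow_threshold([4.0, 4.0, 4.0]) == 4.0
        assert elbow_threshold([2.0, 5.0]) == 5.0


class TestIdentifyHubs:
    def test_planted_hub_recovery(self):
        loops, truth = simulate_loop_universe(1, (12, 12), 50, seed=1)
        res = identify_hubs(loops, seed=1)
        assert len(res.hubs) == 1
        got = {(a.start, a.end) for a in res.hubs[0].anchors}
        want = {(a.start, a.end) for a in truth[0]}
        jaccard = len(got & want) / len(got | want)
        assert jaccard >= 0.8

    def test_all_isolated_no_hubs(self):
        loops, _ = simulate_loop_universe(0, n_isolated=30, seed=2)
        res = identify_hubs(loops, seed=2)
        assert res.hubs == []
        assert len(res.isolated) == 30

    def test_star_center_has_top_pagerank(self):
        center = iv(0, 10_000)
        sats = [iv(100_000 * (k + 1), 100_000 * (k + 1) + 10_000)
                for k in range(6)]
        isolated = [Loop(iv(10_000_000 + k * 200_000,
                            10_010_000 + k * 200_000),
                         iv(20_000_000 + k * 200_000,
                            20_010_000 + k * 200_000)) for k in range(10)]
        loops = LoopSet([Loop(center, s) for s in sats] + isolated)
        res = identify_hubs(loops, seed=0)
        assert len(res.hubs) == 1
        assert res.hubs[0].top_anchor.start == 0

    def test_pagerank_sums_to_one(self):
        loops, _ = simulate_loop_universe(1, (10, 10), 20, seed=3)
        res = identify_hubs(loops, seed=3)
        assert res.hubs[0].pagerank.sum() == pytest.approx(1.0)

    def test_input_order_invariance(self):
        loops, _ = simulate_loop_universe(2, (8, 10), 30, seed=5)
        rev = LoopSet(list(reversed(loops.loops)))
        a = identify_hubs(loops, seed=7)
        b = identify_hubs(rev, seed=7)
        sets_a = {frozenset((x.start, x.end) for x in h.anchors) for h in a.hubs}
        sets_b = {frozenset((x.start, x.end) for x in h.anchors) for h in b.hubs}
        assert sets_a == sets_b


class TestAnchorPairCounts:
    def make_map(self, entries, n=10):
        m = np.zeros((n, n))
        for (i, j), v in entries.items():
            m[i, j] = v
            m[j, i] = v
        return ContactMap("chr1", 10_000, m)

    def test_single_bin_anchors(self):
        cmap = self.make_map({(2, 7): 7})
        loops = LoopSet([Loop(iv(20_000, 30_000), iv(70_000, 80_000))])
        cm = count_loop_anchor_pairs(loops, {"rep1": cmap})
        assert cm.iloc[0, 0] == 7

    def test_two_bin_anchors_enumeration(self):
        entries = {(2, 6): 1, (2, 7): 2, (3, 6): 4, (3, 7): 8, (4, 7): 99}
        cmap = self.make_map(entries)
        loops = LoopSet([Loop(iv(20_000, 40_000), iv(60_000, 80_000))])
        cm = count_loop_anchor_pairs(loops, {"rep1": cmap})
        # exhaustive enumeration over the 4 covered bin pairs
        assert cm.iloc[0, 0] == 1 + 2 + 4 + 8

    def test_zero_map(self):
        cmap = self.make_map({})
        loops = LoopSet([Loop(iv(0, 10_000), iv(50_000, 60_000))])
        assert count_loop_anchor_pairs(loops, {"r": cmap}).iloc[0, 0] == 0


class TestRelativeLoopStrength:
    def balanced_uniform(self, scale, n=10):
        m = ContactMap("chr1", 10_000, np.full((n, n), scale))
        m.weights = np.ones(n)
        return m

    def test_identical_maps_ratio_one(self):
        lp = Loop(iv(0, 10_000), iv(50_000, 60_000))
        a = self.balanced_uniform(4.0)
        assert relative_loop_strength(lp, a, a) == pytest.approx(1.0)

    def test_halved_map_doubles_ratio(self):
        lp = Loop(iv(0, 10_000), iv(50_000, 60_000))
        wt, dko = self.balanced_uniform(4.0), self.balanced_uniform(2.0)
        assert relative_loop_strength(lp, wt, dko) == pytest.approx(2.0)

    def test_hand_enumerated_ratio(self):
        wt = ContactMap("chr1", 10_000, np.full((4, 4), 1.0))
        wt.counts[0, 2] = wt.counts[2, 0] = 6.0
        wt.weights = np.ones(4)
        dko = ContactMap("chr1", 10_000, np.full((4, 4), 2.0))
        dko.weights = np.ones(4)
        lp = Loop(iv(0, 20_000), iv(20_000, 40_000))
        # anchors cover bins {0,1} x {2,3}: wt 6+1+1+1 = 9, dko 4x2 = 8
        assert relative_loop_strength(lp, wt, dko) == pytest.approx(9.0 / 8.0)
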