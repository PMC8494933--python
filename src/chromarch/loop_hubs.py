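"""Chromatin-loop annotation, the loop-anchor network and its hubs.

Loops are anchor pairs; viewed as a network, anchors are nodes and loops are
edges. Communities found by multilevel modularity optimization (Louvain) are
ranked by size, a tangency ("elbow") threshold is placed on the scaled
rank-size curve, and communities strictly larger than the threshold are hubs.
Within each hub, anchors are ranked by PageRank; the top and bottom anchors
are kept for enrichment comparisons. Size-2 communities (isolated loops) are
reported separately as controls.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd

from .contacts import ContactMap, _interval_bins
from .intervals import GenomicInterval
from .stats import test_differential_counts  # noqa: F401  (shared count test)

log = logging.getLogger(__name__)

PAGERANK_DAMPING = 0.85


@dataclass
class Loop:
    """An intra-chromosomal anchor pair; anchor1 precedes anchor2."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    strength: float | None = None
    annotation: str | None = None  # PP / PE / EE / other
    interchromosomal: bool = False

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            self.interchromosomal = True
        elif self.anchor1.start > self.anchor2.start:
            self.anchor1, self.anchor2 = self.anchor2, self.anchor1

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom


@dataclass
class LoopSet:
    loops: list[Loop]

    def intra(self) -> list[Loop]:
        return [lp for lp in self.loops if not lp.interchromosomal]

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self):
        return iter(self.loops)


def annotate_loops(
    loops: LoopSet,
    promoters: list[GenomicInterval],
    chracc_sites: list[GenomicInterval],
) -> LoopSet:
    """Label each loop PP, PE, EE or other.

    PP: both anchors overlap promoters. PE: one anchor overlaps a promoter,
    the other overlaps an accessible site but no promoter. EE: both anchors
    overlap accessible sites but no promoters. Labels are mutually exclusive
    with that precedence.
    """
    def hits(anchor: GenomicInterval, sites: list[GenomicInterval]) -> bool:
        return any(anchor.overlaps(s) for s in sites)

    for lp in loops:
        p1, p2 = hits(lp.anchor1, promoters), hits(lp.anchor2, promoters)
        a1, a2 = hits(lp.anchor1, chracc_sites), hits(lp.anchor2, chracc_sites)
        if p1 and p2:
            lp.annotation = "PP"
        elif (p1 and a2 and not p2) or (p2 and a1 and not p1):
            lp.annotation = "PE"
        elif a1 and a2 and not p1 and not p2:
            lp.annotation = "EE"
        else:
            lp.annotation = "other"
    return loops


@dataclass
class LoopGraph:
    graph: ig.Graph                       # nodes carry 'anchor'
    anchors: list[GenomicInterval]        # canonical anchor per node
    n_dropped_self: int = 0
    n_collapsed: int = 0


def build_loop_graph(loops: LoopSet) -> LoopGraph:
    """Build the anchor network: anchors sharing >= 1 bp merge into one node
    (canonical anchor = union interval); one edge per loop, weight 1.

    Loops whose two anchors merge into the same node would be self-edges and
    are dropped; duplicate node pairs are collapsed.
    """
    intra = loops.intra()
    raw: list[GenomicInterval] = []
    for lp in intra:
        raw.extend((lp.anchor1, lp.anchor2))
    order = sorted(range(len(raw)), key=lambda i: (raw[i].chrom, raw[i].start,
                                                   raw[i].end))
    node_of: dict[int, int] = {}
    canon: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    members: list[int] = []
    for i in order:
        iv = raw[i]
        if cur is not None and iv.chrom == cur.chrom and iv.start < cur.end:
            cur = cur.union(iv)
            members.append(i)
        else:
            if cur is not None:
                canon.append(cur)
                for m in members:
                    node_of[m] = len(canon) - 1
            cur, members = iv, [i]
    if cur is not None:
        canon.append(cur)
        for m in members:
            node_of[m] = len(canon) - 1

    g = ig.Graph(n=len(canon))
    g.vs["anchor"] = canon
    seen: set[tuple[int, int]] = set()
    edges = []
    dropped = collapsed = 0
    for k, lp in enumerate(intra):
        u, v = node_of[2 * k], node_of[2 * k + 1]
        if u == v:
            dropped += 1
            log.warning("loop at %s:%d collapses to a self-edge; dropped",
                        lp.chrom, lp.anchor1.start)
            continue
        key = (min(u, v), max(u, v))
        if key in seen:
            collapsed += 1
            log.warning("duplicate loop on node pair %s collapsed", key)
            continue
        seen.add(key)
        edges.append(key)
    g.add_edges(edges)
    g.es["weight"] = [1.0] * len(edges)
    return LoopGraph(g, canon, n_dropped_self=dropped, n_collapsed=collapsed)


def detect_communities(graph: ig.Graph, seed: int = 0,
                       weights: str | list | None = "weight") -> list[list[int]]:
    """Louvain (multilevel modularity) partition; final level; deterministic
    for a fixed seed and vertex order."""
    if graph.vcount() == 0:
        return []
    ig.set_random_number_generator(random.Random(seed))
    clustering = graph.community_multilevel(weights=weights, return_levels=False)
    ig.set_random_number_generator(random)
    return [list(c) for c in clustering]


def elbow_threshold(values: np.ndarray | list[float]) -> float:
    """Tangency threshold on a ranked curve.

    Values are sorted ascending and both rank and value are scaled to [0, 1];
    the threshold is the value (on the original scale) at the point where the
    unit-slope line is tangent to the curve, i.e. the point farthest below
    the diagonal (argmax of scaled rank minus scaled value, ties broken to
    the largest index). Degenerate input (< 3 values or all equal) returns
    max(values) so that nothing passes.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 3 or v[0] == v[-1]:
        log.warning("elbow_threshold: degenerate input; threshold = max")
        return float(v[-1]) if v.size else float("nan")
    x = np.arange(v.size) / (v.size - 1)
    y = (v - v[0]) / (v[-1] - v[0])
    gap = x - y
    best = int(np.flatnonzero(gap >= gap.max() - 1e-12)[-1])
    return float(v[best])


@dataclass
class LoopHub:
    anchors: list[GenomicInterval]
    loops: list[tuple[int, int]]          # node index pairs within the hub
    size: int
    pagerank: np.ndarray                  # per member anchor, sums to 1
    top_anchor: GenomicInterval
    bottom_anchor: GenomicInterval


@dataclass
class HubResult:
    hubs: list[LoopHub]
    isolated: list[list[GenomicInterval]]  # size-2 communities (control set)
    threshold: float
    cluster_sizes: list[int]


def identify_hubs(loops: LoopSet, seed: int = 0) -> HubResult:
    """Full hub pipeline: anchor network -> Louvain -> elbow threshold on
    community sizes -> hubs (size strictly greater than the threshold), with
    PageRank-ranked anchors per hub."""
    lg = build_loop_graph(loops)
    comms = detect_communities(lg.graph, seed=seed)
    sizes = [len(c) for c in comms]
    if not sizes:
        return HubResult([], [], float("nan"), [])
    thr = elbow_threshold(sizes)
    hubs: list[LoopHub] = []
    isolated: list[list[GenomicInterval]] = []
    for comm in comms:
        if len(comm) == 2:
            isolated.append([lg.anchors[i] for i in comm])
        if len(comm) <= thr:
            continue
        sub = lg.graph.induced_subgraph(comm)
        pr = np.array(sub.personalized_pagerank(damping=PAGERANK_DAMPING,
                                                weights="weight"))
        anchors = [lg.anchors[i] for i in comm]
        top = anchors[int(np.argmax(pr))]
        bottom = anchors[int(np.argmin(pr))]
        hub_loops = [(comm[e.source], comm[e.target]) for e in sub.es]
        hubs.append(LoopHub(anchors, hub_loops, len(comm), pr, top, bottom))
    hubs.sort(key=lambda h: -h.size)
    return HubResult(hubs, isolated, thr, sizes)


def count_loop_anchor_pairs(
    union_loops: LoopSet,
    replicate_maps: dict[str, ContactMap],
) -> pd.DataFrame:
    """Count matrix (loops x replicates) of raw read pairs on each loop's
    anchor-pair bin block. Anchors off the bin grid are snapped outward."""
    rows = {}
    for name, cmap in replicate_maps.items():
        col = []
        for lp in union_loops.intra():
            if lp.chrom != cmap.chrom:
                col.append(0.0)
                continue
            b1 = _interval_bins(lp.anchor1, cmap.bin_size, cmap.n_bins)
            b2 = _interval_bins(lp.anchor2, cmap.bin_size, cmap.n_bins)
            col.append(float(cmap.counts[np.ix_(b1, b2)].sum()))
        rows[name] = col
    idx = [f"{lp.chrom}:{lp.anchor1.start}-{lp.anchor2.end}"
           for lp in union_loops.intra()]
    return pd.DataFrame(rows, index=idx)


def relative_loop_strength(
    loop: Loop, map_wt: ContactMap, map_dko: ContactMap
) -> float:
    """WT/dKO ratio of balanced anchor-pair sums.

    Both maps must be balanced and already depth-normalized to equal totals;
    a zero dKO sum yields NaN.
    """
    def block_sum(cmap: ContactMap) -> float:
        bal = np.nan_to_num(cmap.balanced())
        b1 = _interval_bins(loop.anchor1, cmap.bin_size, cmap.n_bins)
        b2 = _interval_bins(loop.anchor2, cmap.bin_size, cmap.n_bins)
        return float(bal[np.ix_(b1, b2)].sum())

    wt = block_sum(map_wt)
    dko = block_sum(map_dko)
    if dko == 0:
        return float("nan")
    return wt / dko
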