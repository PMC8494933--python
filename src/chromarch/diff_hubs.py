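"""Differential chromatin-interaction hubs.

Starting from depth-matched, balanced WT and dKO contact maps, bin pairs whose
contact strictly changed in the chosen direction (and whose summed signal
exceeds the weak-interaction floor) form a network: bins are nodes, selected
pairs are edges weighted by the reference condition's balanced value. Louvain
communities of that network are projected back onto the genome: the bin of
the highest-PageRank node seeds the projection, other member bins join it
according to a degree/(distance in bins)^2 rule against the configured ratio,
and the projected region is the contiguous span of the retained bins. A
one-sided paired Wilcoxon signed-rank test on all internal bin pairs of the
region (WT vs dKO balanced values) gives the region's p-value; regions below
the hub significance bar (default 1e-7) are reported as condition-specific
hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .contacts import ContactMap
from .intervals import GeneModel, GenomicInterval
from .loop_hubs import PAGERANK_DAMPING, detect_communities
from .stats import wilcoxon_signed_rank

log = logging.getLogger(__name__)

WT_SPECIFIC = "WT-specific"
DKO_SPECIFIC = "dKO-specific"


@dataclass
class DiffHub:
    condition: str                 # WT-specific / dKO-specific
    seed_bin: int
    member_bins: list[int]
    region: GenomicInterval
    p_value: float
    n_internal_pairs: int


def joint_balance(map_wt: ContactMap, map_dko: ContactMap,
                  min_marginal: float = 10.0,
                  ) -> tuple[ContactMap, ContactMap]:
    """Copies of both maps carrying one shared weight vector, derived by
    balancing the pooled WT + dKO matrix.

    Joint weights are condition-symmetric: they rescale every (i, j) pair
    identically in both conditions, so normalization cannot manufacture a
    directional WT/dKO difference. Used for the hub significance test (the
    per-condition balanced maps feed edge selection, matching the printed
    KR normalization).
    """
    from .contacts import kr_balance

    pooled = ContactMap(map_wt.chrom, map_wt.bin_size,
                        map_wt.counts + map_dko.counts)
    pb = kr_balance(pooled, min_marginal=min_marginal)
    out = []
    for m in (map_wt, map_dko):
        c = m.copy()
        c.weights = pb.weights.copy()
        c.mask = pb.mask.copy()
        out.append(c)
    return out[0], out[1]


def _depth_matched(map_wt: ContactMap, map_dko: ContactMap,
                   balanced: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """WT and dKO matrices with the dKO matrix scaled to the WT total."""
    if map_wt.bin_size != map_dko.bin_size or map_wt.n_bins != map_dko.n_bins:
        raise ValueError("WT and dKO maps must share the bin grid")
    if balanced:
        wt = np.nan_to_num(map_wt.balanced())
        dko = np.nan_to_num(map_dko.balanced())
    else:
        wt, dko = map_wt.counts, map_dko.counts
    t_wt, t_dko = wt.sum(), dko.sum()
    if t_wt <= 0 or t_dko <= 0:
        raise ValueError("empty contact map")
    dko = dko * (t_wt / t_dko)
    return wt, dko


def select_directional_edges(
    map_wt: ContactMap,
    map_dko: ContactMap,
    direction: str = WT_SPECIFIC,
    weak_interaction_sum: float = 10.0,
    max_distance_bins: int | None = None,
) -> pd.DataFrame:
    """Bin pairs changing strictly in ``direction``, as a DataFrame with
    columns bin_i < bin_j, wt, dko.

    Same-bin pairs are excluded, as are weak pairs with wt + dko <= the
    weak-interaction floor. ``max_distance_bins`` optionally caps the pair
    separation (default: whole chromosome).
    """
    wt, dko = _depth_matched(map_wt, map_dko)
    n = wt.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    if max_distance_bins is not None:
        keep = (ju - iu) <= max_distance_bins
        iu, ju = iu[keep], ju[keep]
    w = wt[iu, ju]
    d = dko[iu, ju]
    strong = (w + d) > weak_interaction_sum
    if direction == WT_SPECIFIC:
        sel = strong & (d < w)
    elif direction == DKO_SPECIFIC:
        sel = strong & (d > w)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return pd.DataFrame(
        {"bin_i": iu[sel], "bin_j": ju[sel], "wt": w[sel], "dko": d[sel]}
    )


@dataclass
class DiffNetwork:
    graph: ig.Graph
    bins: np.ndarray               # genomic bin per node
    clusters: list[list[int]]      # node indices
    degree: np.ndarray             # incident edge counts, full graph
    pagerank: np.ndarray           # weighted PageRank, full graph


def cluster_diff_network(
    edges: pd.DataFrame,
    reference_condition: str = WT_SPECIFIC,
    seed: int = 0,
) -> DiffNetwork:
    """Louvain clusters of the directional edge network.

    Edge weight is the reference condition's balanced value (WT values for
    WT-specific hubs, dKO values for dKO-specific). Degree (unweighted count
    of incident edges) and weighted PageRank are computed on the full graph.
    """
    if len(edges) == 0:
        raise ValueError("no edges to cluster")
    col = "wt" if reference_condition == WT_SPECIFIC else "dko"
    bins = np.unique(np.concatenate([edges["bin_i"], edges["bin_j"]]))
    node_of = {b: i for i, b in enumerate(bins)}
    pairs = [(node_of[i], node_of[j])
             for i, j in zip(edges["bin_i"], edges["bin_j"])]
    g = ig.Graph(n=len(bins), edges=pairs)
    g.es["weight"] = edges[col].to_numpy(dtype=float)
    clusters = detect_communities(g, seed=seed)
    degree = np.array(g.degree())
    pr = np.array(g.personalized_pagerank(damping=PAGERANK_DAMPING,
                                          weights="weight"))
    return DiffNetwork(g, bins, clusters, degree, pr)


def project_cluster(
    cluster_nodes: list[int],
    network: DiffNetwork,
    bin_size: int,
    chrom: str,
    projection_ratio: float = 0.5,
    comparator: str = "lt",
) -> tuple[int, list[int], GenomicInterval]:
    """Project one cluster onto the genome.

    The bin of the highest-PageRank node is the seed (ties: smaller bin).
    Every other node's bin is included when its degree over the squared bin
    distance to the seed is below ``projection_ratio`` (comparator "lt", the
    default): within a modularity cluster this reaches the far members whose
    distance already exceeds what their degree alone would justify, so the
    contiguous span extends across the cluster's genomic extent. Comparator
    "ge" applies the inequality in the opposite direction (keeping only
    bins whose connectivity is high relative to distance). The region is the
    contiguous span of the retained bins plus the seed.
    """
    if not cluster_nodes:
        raise ValueError("empty cluster")
    nodes = sorted(cluster_nodes, key=lambda v: network.bins[v])
    prs = network.pagerank[nodes]
    seed_node = nodes[int(np.argmax(prs))]  # argmax takes first => smaller bin
    seed_bin = int(network.bins[seed_node])
    member = [seed_bin]
    for v in nodes:
        if v == seed_node:
            continue
        b = int(network.bins[v])
        dist = abs(b - seed_bin)
        if dist == 0:
            log.warning("node with duplicate bin %d skipped in projection", b)
            continue
        ratio = network.degree[v] / (dist * dist)
        keep = ratio >= projection_ratio if comparator == "ge" \
            else ratio < projection_ratio
        if keep:
            member.append(b)
    lo, hi = min(member), max(member)
    region = GenomicInterval(chrom, lo * bin_size, (hi + 1) * bin_size)
    return seed_bin, sorted(member), region


def test_region_significance(
    region: GenomicInterval,
    map_wt: ContactMap,
    map_dko: ContactMap,
    direction: str = WT_SPECIFIC,
    balanced: bool = True,
) -> tuple[float, int]:
    """One-sided paired Wilcoxon signed-rank p over all internal bin pairs of
    the region (i < j), comparing WT against dKO depth-matched balanced
    values (raw counts with ``balanced=False``)."""
    wt, dko = _depth_matched(map_wt, map_dko, balanced=balanced)
    lo = region.start // map_wt.bin_size
    hi = -(-region.end // map_wt.bin_size)
    bins = np.arange(max(lo, 0), min(hi, map_wt.n_bins))
    if bins.size < 2:
        raise ValueError("region must span at least 2 bins")
    iu, ju = np.triu_indices(bins.size, k=1)
    x = wt[bins[iu], bins[ju]]
    y = dko[bins[iu], bins[ju]]
    alt = "greater" if direction == WT_SPECIFIC else "less"
    p = wilcoxon_signed_rank(x, y, alternative=alt)
    return p, int(iu.size)


test_region_significance.__test__ = False  # not a pytest item


def call_diff_hubs(
    map_wt: ContactMap,
    map_dko: ContactMap,
    direction: str = WT_SPECIFIC,
    seed: int = 0,
    config: AnalysisConfig | None = None,
) -> list[DiffHub]:
    """Full pipeline: directional edge selection -> Louvain -> genomic
    projection -> Wilcoxon significance; regions with p below the hub bar
    are returned as hubs.

    Edge selection and clustering run on the per-condition KR-balanced maps;
    the region significance test runs on the same raw counts under shared
    joint weights (see :func:`joint_balance`), so a strong localized signal
    cannot leak through per-condition weights into neighboring regions.
    """
    cfg = config or AnalysisConfig()
    edges = select_directional_edges(
        map_wt, map_dko, direction,
        weak_interaction_sum=cfg.weak_interaction_sum,
    )
    if len(edges) == 0:
        return []
    test_wt, test_dko = joint_balance(map_wt, map_dko,
                                      min_marginal=cfg.mask_min_marginal)
    network = cluster_diff_network(edges, reference_condition=direction,
                                   seed=seed)
    hubs: list[DiffHub] = []
    n_tested = 0
    for cluster in network.clusters:
        seed_bin, member, region = project_cluster(
            cluster, network, map_wt.bin_size, map_wt.chrom,
            projection_ratio=cfg.projection_ratio,
            comparator=cfg.projection_comparator,
        )
        if len(region) < 2 * map_wt.bin_size:
            continue
        p, npairs = test_region_significance(region, test_wt, test_dko,
                                             direction)
        n_tested += 1
        if p < cfg.hub_pvalue:
            hubs.append(DiffHub(direction, seed_bin, member, region, p, npairs))
    log.info("%s: %d clusters tested, %d hubs at p<%g",
             direction, n_tested, len(hubs), cfg.hub_pvalue)
    hubs.sort(key=lambda h: h.region.start)
    return hubs


def associate_genes_to_hubs(
    hubs: list[DiffHub],
    gene_models: list[GeneModel],
    promoter_flank: int = 1_000,
) -> pd.DataFrame:
    """Gene-hub table: a gene joins every hub whose region overlaps its
    promoter (TSS +/- flank) by at least 1 bp."""
    rows = []
    for hub in hubs:
        for gm in gene_models:
            if gm.promoter(promoter_flank).overlaps(hub.region):
                rows.append({
                    "gene": gm.gene,
                    "hub_region": f"{hub.region.chrom}:{hub.region.start}-"
                                  f"{hub.region.end}",
                    "condition": hub.condition,
                    "p_value": hub.p_value,
                })
    return pd.DataFrame(rows, columns=["gene", "hub_region", "condition",
                                       "p_value"])
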