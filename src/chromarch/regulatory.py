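"""Super-enhancer stitching and ranking, element-to-gene association, and
expression/accessibility concordance classes.

Super enhancers are stitched clusters of acetylation islands: islands whose
gaps are at most the stitch distance merge, stitched regions are ranked by
summed island signal, and those above the tangency threshold of the scaled
rank-signal curve are SEs (the same elbow rule used for loop hubs). The
signal-to-noise ratio of an SE is its island-filtered read fraction.

Regulatory elements are tied to genes by three rules: a strand-aware window
from 50 kb upstream of the TSS to the TES; otherwise the closest gene; plus
additive links through chromatin loops whose far anchor overlaps a promoter.
Differential elements linked to differential genes fall into four
concordance classes: C1 (accessibility up, expression up in dKO), C2 (down,
up), C3 (up, down), C4 (down, down).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .intervals import GeneModel, GenomicInterval
from .loop_hubs import LoopSet, elbow_threshold

log = logging.getLogger(__name__)

RULE_WINDOW = "window"
RULE_CLOSEST = "closest"
RULE_LOOP = "loop"


@dataclass
class SuperEnhancer:
    interval: GenomicInterval
    members: list[GenomicInterval]
    rank_signal: float
    signal_to_noise: float | None = None


def stitch_islands(
    islands: list[GenomicInterval],
    stitch_distance: int = 12_500,
) -> list[SuperEnhancer]:
    """Merge islands whose gaps are <= stitch_distance into stitched regions;
    the rank signal of a region is the sum of its member islands' scores."""
    ivs = sorted(islands, key=lambda iv: (iv.chrom, iv.start))
    stitched: list[SuperEnhancer] = []
    cur: list[GenomicInterval] = []
    for iv in ivs:
        if cur and iv.chrom == cur[-1].chrom and \
                iv.start - max(m.end for m in cur) <= stitch_distance:
            cur.append(iv)
        else:
            if cur:
                stitched.append(_make_region(cur))
            cur = [iv]
    if cur:
        stitched.append(_make_region(cur))
    return stitched


def _make_region(members: list[GenomicInterval]) -> SuperEnhancer:
    span = GenomicInterval(members[0].chrom,
                           min(m.start for m in members),
                           max(m.end for m in members))
    signal = sum((m.score or 0.0) for m in members)
    return SuperEnhancer(span, list(members), signal)


def stitch_superenhancers(
    islands: list[GenomicInterval],
    stitch_distance: int = 12_500,
) -> tuple[list[SuperEnhancer], list[SuperEnhancer], float]:
    """Stitch, rank by summed signal, and keep regions strictly above the
    elbow threshold as super enhancers.

    Returns (super_enhancers, all_stitched, threshold). Empty input gives an
    empty SE list.
    """
    stitched = stitch_islands(islands, stitch_distance)
    if not stitched:
        return [], [], float("nan")
    signals = [se.rank_signal for se in stitched]
    thr = elbow_threshold(signals)
    ses = [se for se in stitched if se.rank_signal > thr]
    ses.sort(key=lambda se: -se.rank_signal)
    log.info("stitched %d regions; %d super enhancers above threshold %.3g",
             len(stitched), len(ses), thr)
    return ses, stitched, thr


def se_signal_to_noise(island_read_count: float, total_read_count: float
                       ) -> float:
    """Island-filtered read fraction of an SE span; NaN when no reads."""
    if island_read_count > total_read_count:
        raise ValueError("island reads cannot exceed total reads")
    if total_read_count == 0:
        return float("nan")
    return island_read_count / total_read_count


@dataclass
class ElementGeneLink:
    element: GenomicInterval
    gene: str
    rule: str           # window / closest / loop
    tied: bool = False  # closest-rule tie reported to all tied genes


def associate_elements_to_genes(
    elements: list[GenomicInterval],
    gene_models: list[GeneModel],
    loops: LoopSet | None = None,
    upstream: int = 50_000,
    promoter_flank: int = 1_000,
) -> list[ElementGeneLink]:
    """Rule precedence: an element inside a gene's [TSS - upstream, TES]
    window (strand-aware) gets window links; elements matching no window get
    one closest-gene link (distance from element midpoint to the nearest
    TSS/TES boundary; ties reported to all tied genes, flagged). Loop links
    are additive: an element overlapping a loop anchor whose partner anchor
    overlaps a promoter links to that promoter's gene."""
    if not gene_models:
        raise ValueError("empty gene set")
    links: list[ElementGeneLink] = []
    windows = [(g, g.association_window(upstream)) for g in gene_models]
    for el in elements:
        hits = [g for g, w in windows if el.overlaps(w)]
        if hits:
            links.extend(ElementGeneLink(el, g.gene, RULE_WINDOW) for g in hits)
        else:
            mid = el.midpoint
            dists = []
            for g in gene_models:
                if g.chrom != el.chrom:
                    continue
                d = min(abs(mid - g.tss), abs(mid - g.tes))
                dists.append((d, g.gene))
            if dists:
                dmin = min(d for d, _ in dists)
                tied = [gene for d, gene in dists if d == dmin]
                for gene in tied:
                    links.append(ElementGeneLink(el, gene, RULE_CLOSEST,
                                                 tied=len(tied) > 1))
    if loops is not None:
        proms = [g.promoter(promoter_flank) for g in gene_models]
        for lp in loops.intra():
            for near, far in ((lp.anchor1, lp.anchor2),
                              (lp.anchor2, lp.anchor1)):
                for el in elements:
                    if not el.overlaps(near):
                        continue
                    for pr in proms:
                        if far.overlaps(pr):
                            links.append(
                                ElementGeneLink(el, pr.name, RULE_LOOP))
    # deduplicate identical (element, gene, rule) rows
    seen = set()
    out = []
    for ln in links:
        key = (ln.element.chrom, ln.element.start, ln.element.end,
               ln.gene, ln.rule)
        if key not in seen:
            seen.add(key)
            out.append(ln)
    return out


CONCORDANCE_CLASSES = {
    ("up", "up"): "C1",      # (expression, accessibility) directions in dKO
    ("up", "down"): "C2",
    ("down", "up"): "C3",
    ("down", "down"): "C4",
}


def classify_concordance(
    diff_elements: dict[tuple[str, int, int], str],
    element_gene_links: list[ElementGeneLink],
    diff_genes: dict[str, str],
) -> pd.DataFrame:
    """Assign every linked (element, gene) pair with both directions defined
    to one concordance class.

    ``diff_elements`` maps (chrom, start, end) to accessibility direction in
    dKO ('up'/'down'); ``diff_genes`` maps gene to expression direction in
    dKO. Returns a table with one row per classified pair.
    """
    rows = []
    for ln in element_gene_links:
        key = (ln.element.chrom, ln.element.start, ln.element.end)
        acc = diff_elements.get(key)
        expr = diff_genes.get(ln.gene)
        if acc is None or expr is None:
            continue
        rows.append({
            "chrom": key[0], "start": key[1], "end": key[2],
            "gene": ln.gene, "rule": ln.rule,
            "expression": expr, "accessibility": acc,
            "concordance": CONCORDANCE_CLASSES[(expr, acc)],
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene",
                                       "rule", "expression", "accessibility",
                                       "concordance"])
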