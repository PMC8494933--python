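"""Seeded synthetic-data generators with planted ground truth.

Every generator is a pure function of its parameters and seed. The Hi-C
generator draws Poisson replicates from an expected matrix built as
depth-scaled distance decay (contact frequency proportional to
``(1 + d)^-alpha``) modulated by a compartment checkerboard, TAD blocks and
focal loop additions, with an optional differential region whose internal
expectations are multiplied by a fold in one condition only. The sequence
generator plants PWM-sampled motif instances near the summits of "direct"
peaks; the expression generator draws negative-binomial counts around
lognormal lineage baselines with planted lineage-enriched genes; the loop
generator plants dense anchor communities among isolated loops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactMap
from .intervals import GenomicInterval
from .lineage import ExpressionMatrix
from .loop_hubs import Loop, LoopSet
from .motifs import BASES, PWM


# ---------------------------------------------------------------------------
# Hi-C contact maps
# ---------------------------------------------------------------------------

@dataclass
class SimulationSpec:
    """Study conditions for the two-condition Hi-C simulation.

    Defaults model a 20-Mb chromosome at 10-kb bins with canonical distance
    decay (alpha = 1), 5e6 expected read pairs per condition pooled over two
    replicates, 2-Mb compartment blocks enriched 1.5-fold within a
    compartment, 3-fold-enriched TADs, and a 300-kb differential region whose
    internal contacts are ``diff_fold``-fold higher in the first condition.
    """

    chrom: str = "chrS"
    chrom_length: int = 20_000_000
    bin_size: int = 10_000
    decay_exponent: float = 1.0
    depth: float = 5_000_000.0          # expected pairs per condition pool
    replicate_count: int = 2
    compartment_block_size: int = 2_000_000
    compartment_enrichment: float = 1.5
    tad_plan: list[tuple[int, int]] = field(default_factory=list)
    tad_enrichment: float = 3.0
    loop_plan: list[tuple[int, int]] = field(default_factory=list)
    loop_intensity: float = 30.0
    diff_region: tuple[int, int] | None = None   # bp coordinates
    diff_fold: float = 1.0
    conditions: tuple[str, str] = ("WT", "dKO")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("decay_exponent", "depth", "compartment_enrichment",
                     "tad_enrichment", "diff_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.diff_region is not None:
            lo, hi = self.diff_region
            if not (0 <= lo < hi <= self.chrom_length):
                raise ValueError("diff_region outside chromosome bounds")

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length // self.bin_size)


def _expected_matrix(spec: SimulationSpec, with_diff: bool) -> np.ndarray:
    n = spec.n_bins
    idx = np.arange(n)
    d = np.abs(np.subtract.outer(idx, idx))
    exp = (1.0 + d) ** (-spec.decay_exponent)
    # compartment checkerboard
    if spec.compartment_block_size:
        block = (idx * spec.bin_size) // spec.compartment_block_size % 2
        same = np.equal.outer(block, block)
        exp = exp * np.where(same, spec.compartment_enrichment,
                             1.0 / spec.compartment_enrichment)
    # TAD blocks
    for lo, hi in spec.tad_plan:
        b0, b1 = lo // spec.bin_size, -(-hi // spec.bin_size)
        exp[b0:b1, b0:b1] *= spec.tad_enrichment
    # focal loops
    for p1, p2 in spec.loop_plan:
        b1, b2 = p1 // spec.bin_size, p2 // spec.bin_size
        exp[b1, b2] += spec.loop_intensity * exp[b1, b2]
        exp[b2, b1] = exp[b1, b2]
    if with_diff and spec.diff_region is not None and spec.diff_fold != 1.0:
        lo, hi = spec.diff_region
        b0, b1 = lo // spec.bin_size, -(-hi // spec.bin_size)
        sub = np.zeros(n, dtype=bool)
        sub[b0:b1] = True
        both = np.outer(sub, sub)
        exp = np.where(both, exp * spec.diff_fold, exp)
    # scale the full matrix so the expected total (upper triangle + diagonal)
    # matches the pooled depth
    total = np.triu(exp).sum()
    return exp * (spec.depth / total)


def simulate_contact_maps(
    spec: SimulationSpec,
) -> tuple[dict[str, list[ContactMap]], dict]:
    """Independent Poisson replicates for each condition plus a truth record.

    Condition 1 (``spec.conditions[0]``) carries the differential fold; the
    per-condition pooled expected totals are depth-matched by construction.
    """
    rng = np.random.default_rng(spec.seed)
    out: dict[str, list[ContactMap]] = {}
    for ci, cond in enumerate(spec.conditions):
        exp = _expected_matrix(spec, with_diff=(ci == 0))
        per_rep = exp / spec.replicate_count
        reps = []
        n = spec.n_bins
        iu, ju = np.triu_indices(n)
        lam = per_rep[iu, ju]
        for _ in range(spec.replicate_count):
            draws = rng.poisson(lam).astype(float)
            counts = np.zeros((n, n))
            counts[iu, ju] = draws
            counts[ju, iu] = draws
            reps.append(ContactMap(spec.chrom, spec.bin_size, counts))
        out[cond] = reps
    block = ((np.arange(spec.n_bins) * spec.bin_size)
             // spec.compartment_block_size % 2
             if spec.compartment_block_size else np.zeros(spec.n_bins, int))
    truth = {
        "compartment_labels": block.tolist(),
        "tads": list(spec.tad_plan),
        "loops": list(spec.loop_plan),
        "diff_region": spec.diff_region,
        "diff_fold": spec.diff_fold,
        "diff_condition": spec.conditions[0],
    }
    return out, truth


def pooled_map(replicates: list[ContactMap]) -> ContactMap:
    counts = sum(r.counts for r in replicates)
    first = replicates[0]
    return ContactMap(first.chrom, first.bin_size, counts)


# ---------------------------------------------------------------------------
# Peaks with planted motif instances
# ---------------------------------------------------------------------------

def consensus_pwm(consensus: str = "ATCAAAG", strength: float = 0.97) -> PWM:
    """A sharp PWM around a consensus sequence (default: the Tcf/Lef core)."""
    probs = np.full((len(consensus), 4), (1 - strength) / 3)
    for i, base in enumerate(consensus):
        probs[i, BASES.index(base)] = strength
    return PWM(probs)


def simulate_peaks_and_sequences(
    n_peaks: int,
    pwm: PWM,
    fraction_direct: float,
    seed: int = 0,
    peak_width: int = 500,
    spacing: int = 2_000,
    chrom: str = "chrS",
    min_instance_score: float | None = 9.0,
) -> tuple[list[GenomicInterval], dict[str, str], list[bool]]:
    """Peaks on one synthetic chromosome; 'direct' peaks get a PWM-sampled
    motif instance within +/-100 bp of the summit, the rest are background.

    Planted instances are consensus-near: sampling is repeated until the
    instance's own log-odds reaches ``min_instance_score`` (default 9, two
    units above the direct-binding threshold), so every planted site is a
    bona fide direct-binding site. Set to None for unconstrained sampling.

    Returns (peaks with summits at their midpoints, genome dict, truth list
    where True marks a planted direct-binding peak).
    """
    from .motifs import score_window
    if not 0 <= fraction_direct <= 1:
        raise ValueError("fraction_direct must be within [0, 1]")
    rng = np.random.default_rng(seed)
    genome_len = n_peaks * spacing + spacing
    seq = rng.choice(list(BASES), size=genome_len,
                     p=[0.25] * 4)
    n_direct = int(round(fraction_direct * n_peaks))
    direct = np.zeros(n_peaks, dtype=bool)
    direct[:n_direct] = True
    rng.shuffle(direct)
    peaks = []
    L = len(pwm)
    for k in range(n_peaks):
        center = (k + 1) * spacing
        start = center - peak_width // 2
        peaks.append(GenomicInterval(chrom, start, start + peak_width,
                                     name=f"peak{k}"))
        if direct[k]:
            offset = rng.integers(-(100 - L), 100 - L + 1)
            pos = center + int(offset) - L // 2
            for _ in range(200):
                inst = [rng.choice(list(BASES), p=row) for row in pwm.probs]
                if (min_instance_score is None
                        or score_window(pwm, "".join(inst))
                        >= min_instance_score):
                    break
            seq[pos:pos + L] = inst
    genome = {chrom: "".join(seq)}
    return peaks, genome, direct.tolist()


# ---------------------------------------------------------------------------
# Multi-lineage expression with planted LEGs
# ---------------------------------------------------------------------------

DEFAULT_LINEAGES = ("panT", "B", "NK", "cDC", "pDC", "monocyte", "granulocyte")


@dataclass
class ExpressionPlan:
    """Planted-LEG simulation: lognormal per-gene baselines with lognormal
    lineage effects; a LEG's target-lineage mean is set to ``leg_fold`` times
    the maximum of its other-lineage means, so the planted enrichment holds
    against every opponent."""

    lineages: tuple[str, ...] = DEFAULT_LINEAGES
    n_genes: int = 600
    n_legs_per_lineage: int = 15
    replicates: int = 3
    base_log_mean: float = math.log(100.0)
    base_log_sd: float = 1.0
    lineage_effect_sd: float = 0.4
    leg_fold: float = 5.0
    dispersion: float = 0.1
    seed: int = 0


def simulate_expression(plan: ExpressionPlan, seed: int | None = None
                        ) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """NB-sampled genes x samples matrix plus planted LEG truth per lineage."""
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    L = len(plan.lineages)
    genes = [f"g{i:04d}" for i in range(plan.n_genes)]
    base = rng.lognormal(plan.base_log_mean, plan.base_log_sd, plan.n_genes)
    effects = rng.lognormal(0.0, plan.lineage_effect_sd, (plan.n_genes, L))
    means = base[:, None] * effects
    truth: dict[str, list[str]] = {lin: [] for lin in plan.lineages}
    gi = 0
    for li, lin in enumerate(plan.lineages):
        for _ in range(plan.n_legs_per_lineage):
            if gi >= plan.n_genes:
                break
            others = np.delete(means[gi], li)
            means[gi, li] = plan.leg_fold * others.max()
            truth[lin].append(genes[gi])
            gi += 1
    cols, data, lineage_of = [], [], {}
    for li, lin in enumerate(plan.lineages):
        for r in range(plan.replicates):
            name = f"{lin}_{r + 1}"
            cols.append(name)
            lineage_of[name] = lin
            mu = means[:, li]
            if plan.dispersion > 0:
                shape = 1.0 / plan.dispersion
                lam = rng.gamma(shape, mu / shape)
            else:
                lam = mu
            data.append(rng.poisson(lam))
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    return ExpressionMatrix(values, lineage_of), truth


# ---------------------------------------------------------------------------
# Loop universe with planted hubs
# ---------------------------------------------------------------------------

def simulate_loop_universe(
    n_hubs: int,
    hub_size_range: tuple[int, int] = (8, 14),
    n_isolated: int = 50,
    seed: int = 0,
    chrom: str = "chrS",
    anchor_size: int = 10_000,
    spacing: int = 50_000,
) -> tuple[LoopSet, list[list[GenomicInterval]]]:
    """Planted dense anchor communities plus isolated loops on fresh anchors.

    Each planted hub is a clique over ``size`` anchors (size drawn from
    ``hub_size_range``, minimum 3). Returns the loop set and the planted hub
    anchor lists.
    """
    rng = np.random.default_rng(seed)
    loops: list[Loop] = []
    truth: list[list[GenomicInterval]] = []
    cursor = spacing

    def next_anchor() -> GenomicInterval:
        nonlocal cursor
        iv = GenomicInterval(chrom, cursor, cursor + anchor_size)
        cursor += spacing
        return iv

    for _ in range(n_hubs):
        size = int(rng.integers(max(hub_size_range[0], 3),
                                hub_size_range[1] + 1))
        anchors = [next_anchor() for _ in range(size)]
        truth.append(anchors)
        for i in range(size):
            for j in range(i + 1, size):
                loops.append(Loop(anchors[i], anchors[j]))
    for _ in range(n_isolated):
        a1, a2 = next_anchor(), next_anchor()
        loops.append(Loop(a1, a2))
    return LoopSet(loops), truth
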