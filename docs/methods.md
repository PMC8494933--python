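# Methods

This note records the models, numerical choices and known limitations of the
package, in the order the pipeline runs.

## Contact maps and balancing

A `ContactMap` is a dense symmetric matrix of raw read-pair counts on a
fixed-size bin grid (default 10 kb; 100 kb for compartment analysis), one
chromosome at a time. Balancing is Knight–Ruiz (inner–outer Newton with
conjugate-gradient inner iterations, after the bnewt scheme), with a plain
Sinkhorn–Knopp fallback on non-convergence; an error is raised only if both
fail. Bins whose raw marginal is below a floor (default 10 counts) are masked
before balancing and carry NaN weights; their scores are reported as NaN, not
zero. Weights are rescaled so the balanced matrix preserves the raw total of
the unmasked submatrix — balanced values stay on a count-like scale, which
matters because the differential-hub weak-pair filter `(WT + dKO) ≤ 10` is
stated on that scale.

## Interaction, compartment and TAD scores

The interaction score is the balanced row sum excluding the diagonal.
Replicate reproducibility is the Pearson correlation of the two score
vectors over the union of unmasked bins (at least 3 required).

Compartment scores are computed at 100-kb bins from the raw matrix by
default (a `balance=` flag exists): observed counts are divided by the mean
contact at each bin separation (distances with fewer than 3 unmasked
observations pool with the nearest shorter distance), the Pearson
correlation matrix of the O/E map is formed over unmasked bins, and the
per-bin score is the projection onto the first principal component of that
correlation matrix. The sign is fixed per chromosome so that the mean
activity (e.g. H3K27ac coverage) of positive-score bins is at least that of
negative-score bins — positive = A compartment. Linear (not log) O/E is
used. A constant matrix raises a degenerate-input error.

The TAD score uses raw counts: the sum of counts over bin pairs with both
bins inside the domain (i ≠ j), divided by the sum over pairs with at least
one bin inside. Domains are snapped outward to the bin grid; a domain with
no overlapping read pairs scores NaN. Differential compartment/TAD values
default to simple differences (dKO − WT); a ratio mode exists because the
appropriate axis is genuinely ambiguous, and regions undefined in either
condition are dropped with a log entry.

## Loop network and hubs

Anchors overlapping by at least 1 bp merge into one node whose canonical
anchor is the union interval — at fixed calling resolution anchors are
mostly identical or disjoint, so this is the minimal unification rule.
Each loop contributes one edge of weight 1; loops whose anchors merge into
the same node would be self-edges and are dropped with a warning, duplicate
node pairs collapse. Communities come from igraph's multilevel modularity
(Louvain) at resolution 1.0, final level, with vertex order fixed by genomic
coordinate and the RNG seeded, so the partition is deterministic and
input-order invariant.

The hub size threshold is the tangency ("elbow") point: community sizes are
sorted ascending, rank and size are each scaled to [0, 1], and the threshold
is the size at the point farthest below the unit-slope diagonal (ties broken
to the largest index, so a perfectly linear curve yields threshold = max and
no hubs). Hubs are communities whose size is strictly greater than the
threshold. Within a hub, anchors are ranked by PageRank (damping 0.85,
weight 1 edges); the top and bottom anchors are exposed for enrichment
contrasts, and size-2 communities (isolated loops) are kept as a control
set.

## Differential counts (loops, accessibility, super enhancers, lineages)

One shared two-group test serves differential loops (fold > 2, p < 0.05),
accessibility sites (fold > 2, FDR < 0.05), super enhancers (FDR < 0.05)
and pairwise lineage comparisons (fold ≥ 5, FDR ≤ 0.01). It is
edgeR-inspired, not bit-compatible: TMM-style trimmed-mean library scaling
(30 % M-trim, 5 % A-trim, reference = sample with the most typical upper
quartile), per-feature method-of-moments dispersions shrunk toward a binned
mean–dispersion trend, and a Wald test on the log fold change with
delta-method variance `(1/μ + φ)/n` per group. Fold changes use normalized
means with pseudocount 0.5. All-zero features are excluded and flagged. On
null NB counts (mean 100, dispersion 0.05, 2 vs 2) the fold > 2 & p < 0.05
rule yields about 1 false call per 200 features, and planted 4-fold features
are recovered with sensitivity ≥ 0.9.

## Differential chromatin-interaction hubs

Both pooled maps are KR-balanced per condition and the dKO matrix is scaled
to the WT balanced total (the data give no other depth anchor). Edges are
upper-triangle bin pairs, same-bin pairs excluded, whose summed value
exceeds the weak-interaction floor (strictly greater than 10) and whose
change is strictly in the requested direction. Louvain runs with edge
weight = the reference condition's balanced value. For each community the
bin of the highest-PageRank node (damping 0.85; ties to the smaller bin) is
the seed; every other member bin is included in the projection only if
`degree/(distance in bins)² < 0.5`, where degree is the unweighted incident
edge count on the full network; the region is the contiguous span of the
retained bins plus the seed. Inside a Louvain community this rule reaches
the far members (whose distance exceeds what their degree justifies), so
the span covers the community's genomic extent; the opposite comparator
(`≥`) is available as a config option and is regression-tested.

Significance is a one-sided paired Wilcoxon signed-rank test over all
internal bin pairs of the region, computed on counts scaled by *joint*
weights — one weight vector obtained by KR-balancing the pooled WT + dKO
matrix and applied to both conditions. Per-condition weights are not used
here deliberately: a strong localized differential signal inflates one
condition's marginals, and per-condition balancing then leaks a small
(~2–4 %) but direction-consistent bias into every pair that shares contact
mass with that region; over ~10⁴ internal pairs the signed-rank statistic
converts this into spurious p ≈ 1e-8–1e-10 "shadow" regions next to a real
hub. Joint weights cancel identically in every WT-vs-dKO comparison and
remove the artifact while leaving the planted signal untouched. Zero
differences are dropped, ties mid-ranked; the null is exact (dynamic
programming over all sign assignments, ties included) for n ≤ 25 pairs and
a tie-corrected, continuity-corrected normal approximation above. Regions
with p below 1e-7 are reported; no maximum edge distance is imposed by
default (a cap is available for memory control).

Genes are associated to a hub when the ±1-kb promoter of any of their TSS
records overlaps the hub region by at least 1 bp.

## Motif scanning and enrichment

PWM probabilities get pseudocount 1e-3 (rows renormalized); log-odds are
natural logs against a uniform background by default (the 7/3 thresholds
correspond to natural-log odds; the true background of the original scoring
is unknown, so uniform is an explicit assumption). N bases contribute 0.
Scores are maximized over all offsets and both strands of the ±100-bp
summit window (clipped at contig ends with a warning). Classification is
strict: Motif⁺ needs best > 7, Motif⁻ needs best < 3, boundary values are
intermediate. Enrichment treats binding events as summit points: expected =
merged region length × genome-wide event density; the binomial p uses the
total event count as trials and expected/total as success probability; a
one-sided Poisson upper tail and a Pearson chi-squared (no continuity
correction) cover the remaining figure statistics.

## Super enhancers, gene association, concordance

Islands with gaps ≤ 12,500 bp stitch into one region (ROSE's conventional
distance; no value is printed in the source analyses), regions are ranked
by summed island signal, and regions strictly above the same tangency
threshold are super enhancers; no TSS exclusion is applied. Signal-to-noise
is the island-filtered read fraction of the SE span. Elements associate to
genes by precedence: the strand-aware window from 50 kb upstream of the TSS
to the TES; otherwise the closest gene by midpoint-to-boundary distance
(ties reported to all tied genes, flagged); loop links are additive for
elements on a loop anchor whose partner anchor overlaps a ±1-kb promoter.
Concordance classes cross expression direction with accessibility
direction in dKO: C1 up/up, C2 up/down, C3 down/up, C4 down/down.

## Lineage-enriched genes

Pairwise NB tests between all lineage pairs (fold ≥ 5 and FDR ≤ 0.01,
inclusive bounds) produce a win matrix; a LEG of lineage L wins ≥ 5 of its 6
comparisons (≥ 2 of 3 for the four T-cell subsets) and has replicate
sd/mean < 1 within L. Divergent replicates can be excluded by a generic
rule — median log-expression correlation with sibling replicates below 0.9 —
rather than by name. LEG sets are exported as GMT for any external
enrichment runner; enrichment statistics themselves are out of scope.

## Synthetic data

Generators are pure functions of their parameters and seed; truth records
travel with the outputs.

*Hi-C*: expected contact `∝ (1+d)^-α` with α = 1 (the canonical
intra-chromosomal scaling), modulated by an alternating compartment
checkerboard (2-Mb blocks, 1.5× within-compartment enrichment — the scale
seen in mammalian maps), optional 3×-enriched TAD blocks and focal loop
additions; an optional differential region multiplies internal expectations
by a fold in one condition only. The matrix is scaled to 5e6 expected pairs
per condition (a realistic per-chromosome share of a pooled library,
split over 2 Poisson replicates) and replicates are independent Poisson
draws — counting noise dominates at this depth; an over-dispersed variant
is not modeled. Defaults: 20-Mb chromosome, 10-kb bins (100-kb for
compartment runs), 300-kb planted region at fold 3.

*Peaks/sequences*: uniform-background sequence with one peak per 2 kb;
"direct" peaks receive a PWM-sampled instance within ±100 bp of the summit,
resampled until its own log-odds reaches 9 (two units above the calling
threshold), so planted sites are bona fide direct-binding sites; indirect
peaks are pure background, whose exact-consensus rate (~2.4 % per 201-bp
window for the 7-bp motif) sets the false-positive floor.

*Expression*: per-gene lognormal baselines (log-mean ln 100, log-sd 1) with
per-lineage lognormal effects (log-sd 0.4); a planted LEG's target-lineage
mean is fold × the maximum of its other-lineage means, so the planted
enrichment holds against every opponent; NB sampling with dispersion 0.1,
3 replicates × 7 lineages, 15 planted LEGs per lineage among 600 genes.
Note a structural consequence: planting at exactly the 5-fold calling
threshold makes the comparison against the strongest opponent a coin flip
(the fold estimate's log-sd is ~0.3 at these settings), and whenever the
second-strongest opponent also lands near the boundary the 5-of-6 allowance
is exhausted — measured recall is ~0.75 at precision 1.0. This is a property
of boundary planting, not of the caller; folds with margin are recovered
essentially completely (see the noiseless/high-fold test).

*Loops*: planted hubs are cliques over consecutive synthetic anchors;
isolated loops use fresh anchor pairs.

What passing these tests shows — and does not show: recovery is
demonstrated under Poisson/NB sampling noise with clean planted structure;
real data add mappability and copy-number artifacts, condition-specific
coverage biases, unbalanced library compositions and structural variation
that the generators deliberately omit.

## Problem sizes

The test suite and the acceptance script run the full differential-hub
pipeline on one 20-Mb chromosome (2,000 bins) per run, 20 null runs for the
specificity check, 400 peaks for motif recovery, 200 compartment bins and a
600-gene × 21-sample expression matrix — sizes at which every planted
signal is comfortably detectable and a full acceptance run completes in
about 90 seconds on one CPU.

## Known limitations

* One chromosome at a time; no inter-chromosomal analysis.
* Loop/TAD/peak/island *calling* is out of scope; the package consumes
  caller output.
* The NB test approximates a quasi-likelihood F-test with a Wald normal
  test; p-values differ from edgeR in the tails.
* Compartment sign fixing needs an informative activity track; with a flat
  track the sign is arbitrary.
* The projection comparator, balanced-vs-raw choices and background model
  are exposed as configuration because the original descriptions are
  ambiguous on these points; defaults are documented above.
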