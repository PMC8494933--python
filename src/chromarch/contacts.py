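"""Contact-matrix model and per-bin scores.

A :class:`ContactMap` holds a symmetric intra-chromosomal matrix of raw read
pair counts at a fixed bin size, plus optional Knight-Ruiz balancing weights
and a mask of low-coverage bins. The scores built on top of it:

* interaction score - balanced row sum excluding the diagonal, per 10-kb bin;
* replicate reproducibility - Pearson correlation of interaction-score vectors;
* compartment score - first principal component of the Pearson correlation
  matrix of the distance-normalized (observed/expected) map, sign-fixed so
  that bins with positive score have the higher mean activity (A compartment
  enriched for H3K27ac);
* TAD score - intra-domain read pairs over all domain-overlapping read pairs,
  same-bin pairs excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .intervals import GenomicInterval

log = logging.getLogger(__name__)


@dataclass
class ContactMap:
    chrom: str
    bin_size: int
    counts: np.ndarray            # (n, n) symmetric, non-negative, raw
    weights: np.ndarray | None = None   # per-bin balancing weights, NaN where masked
    mask: np.ndarray | None = None      # boolean, True = excluded bin

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(c, c.T):
            raise ValueError("counts must be symmetric")
        self.counts = c
        if self.mask is None:
            self.mask = np.zeros(self.n_bins, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def bin_interval(self, b: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, b * self.bin_size, (b + 1) * self.bin_size)

    def balanced(self) -> np.ndarray:
        """Balanced matrix w_i * c_ij * w_j; NaN rows/cols on masked bins."""
        if self.weights is None:
            raise ValueError("map is not balanced; call kr_balance first")
        w = self.weights
        return self.counts * np.outer(w, w)

    def values(self, balanced: bool = True) -> np.ndarray:
        return self.balanced() if balanced else self.counts

    def copy(self) -> "ContactMap":
        return ContactMap(
            self.chrom, self.bin_size, self.counts.copy(),
            None if self.weights is None else self.weights.copy(),
            self.mask.copy(),
        )


def _sinkhorn(sub: np.ndarray, tolerance: float, max_iter: int) -> np.ndarray | None:
    """Plain alternating scaling: returns weights making row sums 1, or None."""
    n = sub.shape[0]
    w = np.ones(n)
    for _ in range(max_iter):
        r = sub @ w * w
        if np.max(np.abs(r - 1.0)) < tolerance:
            return w
        w = w / np.sqrt(r)
    r = sub @ w * w
    if np.max(np.abs(r - 1.0)) < tolerance:
        return w
    return None


def _knight_ruiz(A: np.ndarray, tol: float, max_mvp: int) -> np.ndarray | None:
    """Knight-Ruiz balancing (inner-outer Newton with CG), after the bnewt scheme.

    Returns x with diag(x) A diag(x) doubly stochastic to ``tol``, or None.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = float(rk @ rk)
    rout = rho_km1
    rold = rout
    mvp = 0
    while rout > stop_tol * stop_tol:
        k = 0
        y = e.copy()
        innertol = max(eta * eta * rout, stop_tol * stop_tol)
        rho_km2 = rho_km1
        Z = p = w = None
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = float(rk @ Z)
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / float(p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = np.min((delta - y[ind]) / ap[ind]) if ind.any() else 1.0
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = np.min((Delta - y[ind]) / ap[ind]) if ind.any() else 1.0
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = float(rk @ Z)
            mvp += 1
            if mvp > max_mvp:
                return None
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = float(rk @ rk)
        rout = rho_km1
        mvp += k + 1
        if mvp > max_mvp:
            return None
        rat = rout / rold
        rold = rout
        res_norm = math.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o * eta_o > 0.1:
            eta = max(eta, g * eta_o * eta_o)
        eta = max(min(eta, etamax), stop_tol / (2 * res_norm + 1e-300))
        if not np.isfinite(x).all() or (x <= 0).any():
            return None
    return x


def kr_balance(
    cmap: ContactMap,
    tolerance: float = 1e-6,
    max_iter: int = 3000,
    min_marginal: float = 10.0,
) -> ContactMap:
    """Balance a contact map so every unmasked row sum is equal.

    Bins with a raw marginal below ``min_marginal`` (and all-zero bins) are
    masked and receive NaN weight. Knight-Ruiz is attempted first; on failure
    the Sinkhorn-Knopp iteration is used; if neither converges a RuntimeError
    is raised. Weights are rescaled so the balanced matrix preserves the raw
    total of the unmasked submatrix, keeping values on a count-like scale.
    """
    marg = cmap.counts.sum(axis=1)
    mask = (marg < min_marginal) | (marg <= 0)
    keep = ~mask
    if not keep.any():
        raise ValueError("no unmasked bins to balance")
    sub = cmap.counts[np.ix_(keep, keep)]
    # re-check: masking can zero out rows of the submatrix
    submarg = sub.sum(axis=1)
    if (submarg <= 0).any():
        inner = np.where(keep)[0][submarg <= 0]
        mask[inner] = True
        keep = ~mask
        sub = cmap.counts[np.ix_(keep, keep)]
    m = sub.shape[0]
    w = _knight_ruiz(sub, tolerance, max_mvp=max_iter * 10)
    if w is None:
        log.warning("%s: Knight-Ruiz did not converge; falling back to Sinkhorn",
                    cmap.chrom)
        w = _sinkhorn(sub, tolerance, max_iter)
    if w is None:
        raise RuntimeError(f"{cmap.chrom}: matrix balancing failed to converge")
    # rescale so the balanced total matches the raw total of the kept submatrix
    bal_total = float(w @ sub @ w)
    raw_total = float(sub.sum())
    if bal_total > 0:
        w = w * math.sqrt(raw_total / bal_total)
    weights = np.full(cmap.n_bins, np.nan)
    weights[keep] = w
    out = cmap.copy()
    out.weights = weights
    out.mask = mask
    return out


def interaction_scores(cmap: ContactMap, balanced: bool = True) -> np.ndarray:
    """Per-bin interaction score: row sum excluding the diagonal element.

    Masked bins get NaN, not zero.
    """
    mat = cmap.values(balanced=balanced)
    mat = np.where(np.isnan(mat), 0.0, mat)
    scores = mat.sum(axis=1) - np.diag(mat)
    scores = scores.astype(float)
    scores[cmap.mask] = np.nan
    return scores


def interaction_score(cmap: ContactMap, b: int, balanced: bool = True) -> float:
    if cmap.mask[b]:
        return float("nan")
    return float(interaction_scores(cmap, balanced=balanced)[b])


def replicate_reproducibility(
    rep1: ContactMap, rep2: ContactMap, balanced: bool = True
) -> float:
    """Pearson correlation of the two replicates' interaction-score vectors."""
    if rep1.chrom != rep2.chrom or rep1.bin_size != rep2.bin_size:
        raise ValueError("replicates must share chromosome and bin size")
    if rep1.n_bins != rep2.n_bins:
        raise ValueError("replicates must share the bin grid")
    s1 = interaction_scores(rep1, balanced=balanced)
    s2 = interaction_scores(rep2, balanced=balanced)
    ok = ~(np.isnan(s1) | np.isnan(s2))
    if ok.sum() < 3:
        raise ValueError("fewer than 3 shared unmasked bins")
    r = np.corrcoef(s1[ok], s2[ok])[0, 1]
    return float(r)


def _expected_by_distance(mat: np.ndarray, keep: np.ndarray,
                          min_obs: int = 3) -> np.ndarray:
    """Mean contact per separation over unmasked pairs; sparse distances pooled
    with the nearest well-observed shorter distance."""
    n = mat.shape[0]
    exp = np.ones(n)
    last = None
    for d in range(n):
        if d == 0:
            i = np.arange(n)
            vals = mat[i, i][keep]
        else:
            i = np.arange(n - d)
            ok = keep[i] & keep[i + d]
            vals = mat[i, i + d][ok]
        if vals.size >= min_obs:
            exp[d] = float(vals.mean())
            last = exp[d]
        else:
            exp[d] = last if last is not None else (float(vals.mean()) if vals.size else 1.0)
            if vals.size and last is None:
                last = exp[d]
    exp[exp <= 0] = np.nan
    return exp


@dataclass
class CompartmentTrack:
    chrom: str
    bin_size: int
    scores: np.ndarray  # signed, NaN on masked bins


def compartment_scores(
    cmap: ContactMap,
    activity: np.ndarray,
    balanced: bool = False,
) -> CompartmentTrack:
    """Compartment score per bin: PC1 of the Pearson correlation matrix of the
    observed/expected map, sign fixed by the activity track.

    ``activity`` gives one non-negative value per bin (e.g. H3K27ac coverage);
    after sign fixing, positive-score bins have mean activity at least as high
    as negative-score bins.
    """
    activity = np.asarray(activity, dtype=float)
    if activity.shape[0] != cmap.n_bins:
        raise ValueError("activity track length must equal bin count")
    mat = cmap.values(balanced=balanced)
    marg = cmap.counts.sum(axis=1)
    keep = (~cmap.mask) & (marg > 0)
    if keep.sum() < 3:
        raise ValueError("too few unmasked bins for compartment analysis")
    exp = _expected_by_distance(mat, keep)
    n = cmap.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    oe = mat / exp[d]
    sub = oe[np.ix_(keep, keep)]
    sub = np.where(np.isfinite(sub), sub, 1.0)
    if np.allclose(sub.std(axis=0), 0):
        raise ValueError("degenerate (constant) observed/expected matrix")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    if not np.isfinite(corr).all():
        raise ValueError("correlation undefined: constant rows in O/E matrix")
    # PCA of the correlation matrix: project rows onto the leading eigenvector
    # of the column-centered matrix.
    centered = corr - corr.mean(axis=0, keepdims=True)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    pc1 = evecs[:, -1]
    proj = centered @ pc1
    scores = np.full(n, np.nan)
    scores[keep] = proj
    # sign rule: A compartment (positive score) carries the higher activity
    pos = scores > 0
    neg = scores < 0
    mean_pos = activity[pos].mean() if pos.any() else -np.inf
    mean_neg = activity[neg].mean() if neg.any() else -np.inf
    if mean_neg > mean_pos:
        scores = -scores
    return CompartmentTrack(cmap.chrom, cmap.bin_size, scores)


@dataclass
class TadRecord:
    interval: GenomicInterval
    score: float  # fraction in [0, 1], NaN if undefined


def _interval_bins(iv: GenomicInterval, bin_size: int, n_bins: int) -> np.ndarray:
    """Bins overlapping the interval, snapped outward to the grid."""
    lo = iv.start // bin_size
    hi = -(-iv.end // bin_size)  # ceil
    lo = max(lo, 0)
    hi = min(hi, n_bins)
    return np.arange(lo, hi)


def tad_score(cmap: ContactMap, tad: GenomicInterval) -> TadRecord:
    """Intra-TAD read pairs over TAD-overlapping read pairs, raw counts,
    same-bin pairs excluded."""
    if tad.chrom != cmap.chrom:
        raise ValueError("TAD chromosome does not match map")
    bins = _interval_bins(tad, cmap.bin_size, cmap.n_bins)
    c = cmap.counts
    inb = np.zeros(cmap.n_bins, dtype=bool)
    inb[bins] = True
    iu, ju = np.triu_indices(cmap.n_bins, k=1)
    both = inb[iu] & inb[ju]
    either = inb[iu] | inb[ju]
    intra = float(c[iu[both], ju[both]].sum())
    overlap = float(c[iu[either], ju[either]].sum())
    if overlap == 0:
        return TadRecord(tad, float("nan"))
    return TadRecord(tad, intra / overlap)


def stratify_regions_by_peak_density(
    regions: list[GenomicInterval],
    peaks: list[GenomicInterval],
    length_unit: int = 100_000,
    bounds: list[float] | None = None,
) -> list[tuple[GenomicInterval, float, int]]:
    """Label each region with its peak density (peaks per ``length_unit``) and
    the index of the density group given ``bounds`` (ascending lower edges)."""
    if bounds is None:
        bounds = [0.0]
    out = []
    for region in regions:
        n = sum(
            1 for p in peaks
            if region.contains_point(p.chrom, p.midpoint)
        )
        density = n * length_unit / len(region)
        group = 0
        for gi, b in enumerate(bounds):
            if density >= b:
                group = gi
        out.append((region, density, group))
    return out


def differential_region_score(
    score_wt: float, score_dko: float, mode: str = "difference"
) -> float | None:
    """Per-region differential value: dKO - WT (default) or dKO/WT ratio.

    Returns None (region dropped) when either score is undefined, or in ratio
    mode when WT is zero.
    """
    if any(s is None or (isinstance(s, float) and math.isnan(s))
           for s in (score_wt, score_dko)):
        log.info("differential score dropped: undefined input")
        return None
    if mode == "difference":
        return score_dko - score_wt
    if mode == "ratio":
        if score_wt == 0:
            log.info("differential ratio dropped: WT score is zero")
            return None
        return score_dko / score_wt
    raise ValueError(f"unknown mode {mode!r}")
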