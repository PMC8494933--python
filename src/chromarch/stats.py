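"""Shared statistics: paired Wilcoxon signed-rank with an exact small-sample
null, Benjamini-Hochberg adjustment, and the negative-binomial two-group count
test used for differential loops, accessibility sites, super enhancers and
pairwise lineage comparisons.

The count test is edgeR-inspired (TMM-style library scaling, moment dispersion
estimates shrunk toward a mean-dispersion trend, Wald test on the log fold
change) but is not intended to be bit-compatible with edgeR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_exact_tail_ge(ranks2: np.ndarray, w2: float) -> float:
    """P(W+ >= w) under the exact signed-rank null, ranks given doubled so
    midranks stay integral. Dynamic program over the distribution of W+."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n = len(ranks2)
    w2i = int(math.ceil(w2 - 1e-9))
    tail = counts[w2i:].sum()
    return float(tail / (2.0 ** n))


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "greater",
    exact_max_n: int = 25,
) -> float:
    """One-sided paired Wilcoxon signed-rank p-value for H1 x > y (or x < y).

    Zero differences are dropped; ties receive midranks. The null is exact
    (all 2^n sign assignments, via dynamic programming) for n <= exact_max_n,
    and a normal approximation with tie correction and continuity correction
    otherwise. Returns 1.0 (with a warning) when all differences are zero.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    if d.size == 0:
        log.warning("wilcoxon: all differences zero; p = 1")
        return 1.0
    if alternative == "less":
        d = -d
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= exact_max_n:
        ranks2 = np.rint(ranks * 2).astype(int)
        return _signed_rank_exact_tail_ge(ranks2, 2.0 * w_plus)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mu - 0.5) / math.sqrt(var)
    return float(sps.norm.sf(z))


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs propagate."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q


# ---------------------------------------------------------------------------
# Library scaling (TMM-style)
# ---------------------------------------------------------------------------

def tmm_factors(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05
                ) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, one per column.

    The reference column is the one whose upper quartile is closest to the
    mean upper quartile. Factors are scaled to a geometric mean of 1.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    uq = np.array([np.quantile(c[c > 0], 0.75) if (c > 0).any() else 0.0
                   for c in counts.T]) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.ones(counts.shape[1])
    refcol = counts[:, ref] / lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        obs = counts[:, j] / lib[j]
        ok = (obs > 0) & (refcol > 0)
        if ok.sum() < 2:
            continue
        m = np.log2(obs[ok] / refcol[ok])
        a = 0.5 * np.log2(obs[ok] * refcol[ok])
        # precision weights from the delta method on log ratios
        w = 1.0 / ((lib[j] - counts[ok, j]) / (lib[j] * counts[ok, j])
                   + (lib[ref] - counts[ok, ref]) / (lib[ref] * counts[ok, ref]))
        keep = np.ones(m.size, dtype=bool)
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep &= (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() >= 1:
            f[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    f = f / np.exp(np.mean(np.log(f)))
    return f


# ---------------------------------------------------------------------------
# Negative-binomial two-group test
# ---------------------------------------------------------------------------

@dataclass
class DiffResult:
    """Per-feature differential statistics.

    ``table`` columns: mean_a, mean_b, log2_fc (b over a), p, fdr, call,
    direction ('a-specific'/'b-specific'/'' ), excluded (all-zero features).
    """

    table: pd.DataFrame
    group_a: str
    group_b: str


def _shrunk_dispersions(norm: np.ndarray, groups: list[np.ndarray],
                        prior_weight: float = 10.0) -> np.ndarray:
    """Method-of-moments tagwise dispersions shrunk toward a mean-dispersion
    trend estimated by binned medians."""
    nfeat = norm.shape[0]
    mu = norm.mean(axis=1)
    phi = np.zeros(nfeat)
    for g in range(nfeat):
        num = 0.0
        den = 0.0
        for idx in groups:
            x = norm[g, idx]
            m = x.mean()
            if m <= 0 or x.size < 2:
                continue
            v = x.var(ddof=1)
            num += (v - m) / (m * m) * (x.size - 1)
            den += x.size - 1
        phi[g] = max(num / den, 0.0) if den > 0 else 0.0
    # trend: median dispersion in mean-ordered bins
    trend = np.full(nfeat, np.median(phi) if nfeat else 0.0)
    if nfeat >= 20:
        order = np.argsort(mu)
        nbins = max(5, min(20, nfeat // 10))
        edges = np.array_split(order, nbins)
        centers, meds = [], []
        for e in edges:
            if e.size:
                centers.append(mu[e].mean())
                meds.append(np.median(phi[e]))
        trend = np.interp(mu, centers, meds)
    df_tag = sum(max(idx.size - 1, 0) for idx in groups)
    w = df_tag / (df_tag + prior_weight)
    return np.maximum(w * phi + (1 - w) * trend, 1e-6)


def test_differential_counts(
    count_matrix: pd.DataFrame,
    group_labels: list[str] | np.ndarray,
    fc_threshold: float = 2.0,
    sig_threshold: float = 0.05,
    sig_mode: str = "p",
    pseudocount: float = 0.5,
) -> DiffResult:
    """Two-group negative-binomial differential test on a features x samples
    count matrix.

    A feature is called when |log2 FC| > log2(fc_threshold) and its p-value
    (``sig_mode='p'``) or BH-FDR (``sig_mode='fdr'``) is below
    ``sig_threshold``; for lineage comparisons ``sig_mode`` may also be
    ``'fdr_le'`` / ``'p_le'`` with fold >= threshold and FDR <= threshold
    (inclusive bounds, as used by the lineage rules). Direction labels name
    the group with the higher normalized mean. All-zero features are excluded
    from testing and flagged.
    """
    labels = np.asarray(group_labels)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    a, b = uniq
    idx_a = np.where(labels == a)[0]
    idx_b = np.where(labels == b)[0]
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    if sig_mode not in ("p", "fdr", "p_le", "fdr_le"):
        raise ValueError("sig_mode must be 'p', 'fdr', 'p_le' or 'fdr_le'")
    counts = count_matrix.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs nonzero total counts")
    factors = tmm_factors(counts)
    eff = lib * factors
    scale = np.exp(np.mean(np.log(eff)))
    norm = counts / eff * scale

    excluded = counts.sum(axis=1) == 0
    if excluded.any():
        log.info("test_differential_counts: %d all-zero features excluded",
                 int(excluded.sum()))

    phi = _shrunk_dispersions(norm, [idx_a, idx_b])
    mean_a = norm[:, idx_a].mean(axis=1)
    mean_b = norm[:, idx_b].mean(axis=1)
    l2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    # delta-method variance of log-mean under NB(mu, phi)
    var_ln = (
        (1.0 / np.maximum(mean_a, pseudocount) + phi) / idx_a.size
        + (1.0 / np.maximum(mean_b, pseudocount) + phi) / idx_b.size
    )
    z = (l2fc * math.log(2.0)) / np.sqrt(var_ln)
    p = 2.0 * sps.norm.sf(np.abs(z))
    p[excluded] = np.nan
    fdr = bh_fdr(p)

    inclusive = sig_mode.endswith("_le")
    sig_vals = fdr if sig_mode.startswith("fdr") else p
    if inclusive:
        fc_ok = np.abs(l2fc) >= math.log2(fc_threshold) - 1e-12
        sig_ok = sig_vals <= sig_threshold
    else:
        fc_ok = np.abs(l2fc) > math.log2(fc_threshold)
        sig_ok = sig_vals < sig_threshold
    call = fc_ok & np.where(np.isnan(sig_vals), False, sig_ok) & ~excluded
    direction = np.where(call, np.where(l2fc > 0, f"{b}-specific",
                                        f"{a}-specific"), "")
    table = pd.DataFrame(
        {
            "mean_a": mean_a, "mean_b": mean_b, "log2_fc": l2fc,
            "p": p, "fdr": fdr, "call": call, "direction": direction,
            "excluded": excluded,
        },
        index=count_matrix.index,
    )
    return DiffResult(table=table, group_a=a, group_b=b)


test_differential_counts.__test__ = False  # not a pytest item
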