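"""Lineage-enriched gene (LEG) identification from a multi-lineage expression
matrix, plus genotype differential-expression calls.

A gene is a LEG of lineage L when it is significantly upregulated (fold >= 5,
FDR <= 0.01 by the shared negative-binomial count test) against at least
``min_wins`` of the other lineages (5 of 6 for the seven pan-immune lineages,
2 of 3 for the four T subsets), and its replicate coefficient of variation
(sd/mean) within L is below 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_fdr, test_differential_counts

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Non-negative genes x samples values with per-sample lineage labels."""

    values: pd.DataFrame                 # genes x samples
    lineages: dict[str, str]             # sample -> lineage

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.lineages)
        if missing:
            raise ValueError(f"samples without lineage labels: {sorted(missing)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    def lineage_names(self) -> list[str]:
        return list(dict.fromkeys(self.lineages[s] for s in self.values.columns))

    def samples_of(self, lineage: str) -> list[str]:
        return [s for s in self.values.columns if self.lineages[s] == lineage]

    def submatrix(self, lineage_a: str, lineage_b: str
                  ) -> tuple[pd.DataFrame, list[str]]:
        cols = self.samples_of(lineage_a) + self.samples_of(lineage_b)
        labels = [self.lineages[c] for c in cols]
        return self.values[cols], labels


def drop_outlier_replicates(
    expr: ExpressionMatrix, min_correlation: float = 0.9
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop replicates that diverge from the rest of their lineage.

    A replicate is an outlier when its median log-expression correlation
    with its sibling replicates falls below ``min_correlation`` (the median
    keeps one bad sibling from dragging down the good ones)."""
    dropped = []
    keep_cols = []
    logv = np.log1p(expr.values)
    for s in expr.values.columns:
        sibs = [c for c in expr.samples_of(expr.lineages[s]) if c != s]
        if len(sibs) < 2:
            keep_cols.append(s)
            continue
        rs = [np.corrcoef(logv[s], logv[c])[0, 1] for c in sibs]
        r = float(np.median(rs))
        if r < min_correlation:
            dropped.append(s)
            log.warning("replicate %s dropped: median sibling r=%.3f", s, r)
        else:
            keep_cols.append(s)
    sub = ExpressionMatrix(expr.values[keep_cols],
                           {c: expr.lineages[c] for c in keep_cols})
    return sub, dropped


def pairwise_de(
    expr: ExpressionMatrix,
    lineage_a: str,
    lineage_b: str,
    fc: float = 5.0,
    fdr: float = 0.01,
) -> pd.Series:
    """Per-gene call between two lineages: 'up_a', 'up_b' or 'ns'.

    Delegates to the shared NB count test; a call needs fold >= fc and
    BH-FDR <= fdr (inclusive bounds).
    """
    for lin in (lineage_a, lineage_b):
        if len(expr.samples_of(lin)) < 2:
            raise ValueError(f"lineage {lin} needs at least 2 replicates")
    sub, labels = expr.submatrix(lineage_a, lineage_b)
    res = test_differential_counts(sub, labels, fc_threshold=fc,
                                   sig_threshold=fdr, sig_mode="fdr_le")
    calls = pd.Series("ns", index=sub.index)
    up_b = res.table["call"] & (res.table["log2_fc"] > 0)
    up_a = res.table["call"] & (res.table["log2_fc"] < 0)
    calls[up_a] = "up_a"
    calls[up_b] = "up_b"
    return calls


@dataclass
class LegSet:
    lineage: str
    genes: list[str]
    win_counts: pd.Series        # wins per gene (all genes)
    cv: pd.Series                # within-lineage sd/mean per gene


def _replicate_cv(expr: ExpressionMatrix, lineage: str) -> pd.Series:
    vals = expr.values[expr.samples_of(lineage)]
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    return cv.fillna(np.inf)


def identify_legs(
    expr: ExpressionMatrix,
    fc: float = 5.0,
    fdr: float = 0.01,
    min_wins: int = 5,
    cv_max: float = 1.0,
) -> dict[str, LegSet]:
    """LEG sets for every lineage in the matrix.

    A gene joins LEG(L) when it wins (is called up in L) in at least
    ``min_wins`` of the pairwise comparisons against the other lineages and
    its within-L replicate sd/mean is below ``cv_max``.
    """
    lineages = expr.lineage_names()
    if len(lineages) < 2:
        raise ValueError("need at least two lineages")
    wins = {lin: pd.Series(0, index=expr.values.index) for lin in lineages}
    for i, a in enumerate(lineages):
        for b in lineages[i + 1:]:
            calls = pairwise_de(expr, a, b, fc=fc, fdr=fdr)
            wins[a] += (calls == "up_a").astype(int)
            wins[b] += (calls == "up_b").astype(int)
    out: dict[str, LegSet] = {}
    for lin in lineages:
        cv = _replicate_cv(expr, lin)
        member = (wins[lin] >= min_wins) & (cv < cv_max)
        out[lin] = LegSet(lin, list(expr.values.index[member]), wins[lin], cv)
        log.info("LEG(%s): %d genes (win rule >= %d of %d, CV < %g)",
                 lin, int(member.sum()), min_wins, len(lineages) - 1, cv_max)
    return out


def identify_t_subset_legs(
    expr: ExpressionMatrix,
    fc: float = 5.0,
    fdr: float = 0.01,
    min_wins: int = 2,
    cv_max: float = 1.0,
) -> dict[str, LegSet]:
    """T-subset variant: with four subsets a LEG needs wins in at least two
    of its three comparisons (same CV rule)."""
    return identify_legs(expr, fc=fc, fdr=fdr, min_wins=min_wins,
                         cv_max=cv_max)


def flag_degs(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fc: float = 2.0,
    fdr: float = 0.05,
    min_level: float = 1.0,
) -> pd.DataFrame:
    """Two-genotype DEG calls: fold >= fc, FDR < fdr, and mean expression of
    the higher group >= min_level. Returns the stats table with an 'up_in'
    column ('' when not a DEG)."""
    sub, labels = expr.submatrix(group_a, group_b)
    res = test_differential_counts(sub, labels, fc_threshold=fc,
                                   sig_threshold=fdr, sig_mode="fdr")
    t = res.table.copy()
    higher = np.where(t["log2_fc"] > 0, t["mean_b"], t["mean_a"])
    ok = t["call"] & (higher >= min_level)
    t["up_in"] = np.where(ok, np.where(t["log2_fc"] > 0, group_b, group_a), "")
    return t
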