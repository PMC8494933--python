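"""PWM log-odds scanning, direct/indirect binding classification, and
enrichment statistics for TF binding events.

A peak is scored on the +/-100 bp window around its summit with a position
weight matrix; the log-odds are natural-log ratios of motif to background
probabilities, maximized over offsets and both strands. Peaks with a hit
above the positive threshold (default 7) are Motif+ (direct binding); peaks
whose every hit is below the negative threshold (default 3) are Motif-
(indirect); the rest are intermediate (MotifInt). Both inequalities are
strict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .intervals import GenomicInterval

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MOTIF_POS = "Motif+"
MOTIF_INT = "MotifInt"
MOTIF_NEG = "Motif-"

SUMMIT_FLANK = 100  # bp on each side of the summit


@dataclass
class PWM:
    """Position probability matrix over {A,C,G,T} with a background model.

    A pseudocount is added to every motif probability (rows renormalized), so
    log-odds are always finite.
    """

    probs: np.ndarray                       # (L, 4)
    background: np.ndarray | None = None    # (4,)
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must be (L, 4)")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM position must sum to 1")
        p = p + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        self.probs = p
        bg = (np.full(4, 0.25) if self.background is None
              else np.asarray(self.background, dtype=float))
        if not math.isclose(float(bg.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        self.background = bg

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 5) natural-log odds; column 4 (N) scores 0."""
        lo = np.log(self.probs / self.background)
        return np.hstack([lo, np.zeros((len(self), 1))])

    def reverse_complement(self) -> "PWM":
        rc = self.probs[::-1, ::-1]
        return PWM(rc, self.background[::-1], pseudocount=0.0)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.intp)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def window_scores(pwm: PWM, sequence: str) -> np.ndarray:
    """Log-odds of every hit: all offsets on both strands.

    N bases contribute 0 (background) at their position.
    """
    L = len(pwm)
    if len(sequence) < L:
        raise ValueError("sequence shorter than the motif")
    enc = _encode(sequence)
    n = enc.size - L + 1
    scores = []
    for mat in (pwm.log_odds, pwm.reverse_complement().log_odds):
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        scores.append(mat[np.arange(L), windows].sum(axis=1))
    return np.concatenate(scores)


def score_window(pwm: PWM, sequence: str) -> float:
    """Best log-odds hit over all offsets and both strands."""
    return float(window_scores(pwm, sequence).max())


def classify_score(best_score: float, pos_threshold: float = 7.0,
                   neg_threshold: float = 3.0) -> str:
    """Motif class from the best hit: Motif+ iff best > pos threshold,
    Motif- iff every hit (hence the best) < neg threshold, else MotifInt."""
    if best_score > pos_threshold:
        return MOTIF_POS
    if best_score < neg_threshold:
        return MOTIF_NEG
    return MOTIF_INT


@dataclass
class ScoredPeak:
    interval: GenomicInterval
    summit: int
    best_score: float
    motif_class: str


def classify_peak(
    pwm: PWM,
    genome: dict[str, str],
    peak: GenomicInterval,
    summit: int | None = None,
    pos_threshold: float = 7.0,
    neg_threshold: float = 3.0,
    flank: int = SUMMIT_FLANK,
) -> ScoredPeak:
    """Score the +/-``flank`` bp window around the peak summit and classify.

    The summit defaults to the peak midpoint; the window is clipped to the
    contig with a warning.
    """
    if peak.chrom not in genome:
        raise KeyError(f"no sequence for {peak.chrom}")
    contig = genome[peak.chrom]
    s = peak.midpoint if summit is None else summit
    if not (peak.start <= s < peak.end):
        raise ValueError("summit must lie inside the peak")
    lo, hi = s - flank, s + flank + 1
    if lo < 0 or hi > len(contig):
        log.warning("window around summit %s:%d clipped to contig",
                    peak.chrom, s)
        lo, hi = max(lo, 0), min(hi, len(contig))
    best = score_window(pwm, contig[lo:hi])
    return ScoredPeak(peak, s, best,
                      classify_score(best, pos_threshold, neg_threshold))


def enrichment_score(
    feature_points: list[tuple[str, int]],
    regions: list[GenomicInterval],
    genome_length: int,
) -> tuple[int, float, float, float]:
    """Observed vs expected binding events in a region set.

    ``feature_points`` are event coordinates (peak summits). Regions are
    merged before measuring; expected = total region length x genome-wide
    event density; the p-value is the one-sided upper binomial tail with the
    total event count as trials and expected/total as success probability.
    Returns (observed, expected, ratio, p).
    """
    from .intervals import merge_intervals, total_length

    merged = merge_intervals(regions)
    n = len(feature_points)
    observed = sum(
        1 for chrom, pos in feature_points
        if any(r.contains_point(chrom, pos) for r in merged)
    )
    expected = total_length(merged) * (n / genome_length)
    if expected == 0:
        if observed > 0:
            log.warning("zero expectation with positive observation; p = 0")
            return observed, 0.0, float("inf"), 0.0
        return 0, 0.0, float("nan"), 1.0
    ratio = observed / expected
    prob = min(expected / n, 1.0)
    p = float(sps.binom.sf(observed - 1, n, prob))
    return observed, expected, ratio, p


def poisson_enrichment(observed: int, expected: float) -> float:
    """One-sided upper-tail Poisson p-value P(X >= observed | lambda)."""
    if expected <= 0:
        raise ValueError("expected must be positive")
    return float(sps.poisson.sf(observed - 1, expected))


def motif_class_composition(
    scored_peaks: list[ScoredPeak],
    strata: dict[str, list[ScoredPeak]] | None = None,
    labels: list[str] | None = None,
) -> tuple["pd.DataFrame", float, float, list[str]]:
    """Contingency table of motif classes per stratum with a Pearson
    chi-squared test (no continuity correction).

    Strata may be given as a mapping name -> peaks, or as one label per peak.
    Returns (table, chi2, p, warnings). A single stratum is an error; cells
    with expectation < 1 attach a warning.
    """
    import pandas as pd

    if strata is None:
        if labels is None or len(labels) != len(scored_peaks):
            raise ValueError("provide strata or one label per peak")
        strata = {}
        for pk, lab in zip(scored_peaks, labels):
            strata.setdefault(lab, []).append(pk)
    if len(strata) < 2:
        raise ValueError("chi-squared needs at least two strata")
    classes = [MOTIF_POS, MOTIF_INT, MOTIF_NEG]
    table = pd.DataFrame(
        {name: [sum(p.motif_class == c for p in pks) for c in classes]
         for name, pks in strata.items()},
        index=classes,
    )
    obs = table.to_numpy(dtype=float)
    obs = obs[obs.sum(axis=1) > 0][:, :]
    chi2, p, _, exp = sps.chi2_contingency(obs, correction=False)
    warnings = []
    if (exp < 1).any():
        warnings.append("expected cell count below 1; chi-squared unreliable")
    return table, float(chi2), float(p), warnings
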