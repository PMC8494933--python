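"""Analysis configuration: every threshold the pipeline applies, in one place.

Defaults are the values used throughout the analyses: 10-kb working resolution,
100-kb compartment resolution, PWM log-odds cutoffs of 7 (direct binding) and 3
(indirect), exclusion of weak bin pairs with a summed balanced signal <= 10,
the degree/distance^2 projection ratio 0.5, the 1e-7 hub significance bar, the
2-fold / p<0.05 differential-loop rule, the 2-fold / FDR<0.05 accessibility
rule, the FDR<0.05 super-enhancer rule, the 5-fold / FDR<=0.01 lineage rule
with 5-of-6 wins and a coefficient-of-variation cap of 1, +/-1-kb promoters and
a 50-kb upstream gene-association window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    bin_size: int = 10_000
    compartment_bin_size: int = 100_000
    motif_pos_threshold: float = 7.0
    motif_neg_threshold: float = 3.0
    weak_interaction_sum: float = 10.0
    projection_ratio: float = 0.5
    projection_comparator: str = "lt"  # "lt" (as printed) or "ge" (inverted)
    hub_pvalue: float = 1.0e-7
    loop_fc: float = 2.0
    loop_p: float = 0.05
    chracc_fc: float = 2.0
    chracc_fdr: float = 0.05
    se_fdr: float = 0.05
    se_stitch_distance: int = 12_500
    leg_fc: float = 5.0
    leg_fdr: float = 0.01
    leg_min_wins: int = 5
    leg_cv_max: float = 1.0
    promoter_flank: int = 1_000
    upstream_assoc: int = 50_000
    mask_min_marginal: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "bin_size", "compartment_bin_size", "motif_pos_threshold",
            "motif_neg_threshold", "weak_interaction_sum", "projection_ratio",
            "hub_pvalue", "loop_fc", "loop_p", "chracc_fc", "chracc_fdr",
            "se_fdr", "se_stitch_distance", "leg_fc", "leg_fdr",
            "leg_min_wins", "leg_cv_max", "promoter_flank", "upstream_assoc",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.motif_neg_threshold >= self.motif_pos_threshold:
            raise ValueError("motif_neg_threshold must be below motif_pos_threshold")
        if self.projection_comparator not in ("ge", "lt"):
            raise ValueError("projection_comparator must be 'ge' or 'lt'")

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def updated(self, **overrides) -> "AnalysisConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return AnalysisConfig(**data)
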