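"""Screen configuration: every simulation and analysis parameter in one place.

Defaults reproduce the study conditions of the screen this package models:
a mariner library covering 63% of TA sites, a 3-h selection giving ~20-fold
growth in the control, ~83% kill at the sub-bactericidal dose and ~99.5%
kill at the bactericidal dose, colony bottlenecks of ~100,000 / 8,000 / 230,
and 3 biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

#: Experimental groups, in fixed order: control (BSA-like, grows ~20-fold),
#: sub-bactericidal (~17% survival), bactericidal (~0.5% survival).
GROUPS = ("control", "sub", "bactericidal")

#: One barcode per experimental group (replicates are separate files), as in
#: group-barcoded junction sequencing.  Pairwise Hamming distance >= 3.
DEFAULT_BARCODES = {"control": "ACGTAC", "sub": "CTAGGA", "bactericidal": "GACTCT"}


@dataclass
class ScreenConfig:
    """All tunable parameters of the simulated screen and its analysis.

    Attributes
    ----------
    saturation
        Fraction of TA sites carrying an insertion clone in the library.
    growth_factor_control
        Fold CFU change over the 3-h control treatment.
    survival_subbactericidal, survival_bactericidal
        Surviving CFU fraction under each treatment dose.
    colony_bottlenecks
        Colonies pooled per group after plating (control, sub, bactericidal).
    n_replicates
        Biological replicates (independent selections from the same library).
    reads_per_sample
        Junction reads sequenced per sample; a desk-scale default.
    tag_length
        Genomic bp captured next to the transposon junction; 16 bp reflects
        MmeI-class restriction chemistry and is ample for unique mapping.
    read_error_rate
        Per-base substitution error rate in simulated reads.
    pseudocount
        Reads added to actual and predicted when forming Dval for testing
        (raw Dval with pseudocount 0 is always reported alongside).
    min_sites
        Minimum distinct insertion sites for a feature to enter testing.
    alpha
        Significance cutoff on the per-feature P value.
    """

    saturation: float = 0.63
    growth_factor_control: float = 20.0
    survival_subbactericidal: float = 0.17
    survival_bactericidal: float = 0.005
    colony_bottlenecks: Mapping[str, int] = field(
        default_factory=lambda: {"control": 100_000, "sub": 8_000, "bactericidal": 230}
    )
    n_replicates: int = 3
    reads_per_sample: int = 200_000
    tag_length: int = 16
    barcode_length: int = 6
    read_error_rate: float = 0.0
    abundance_sigma: float = 0.5  # sd of ln(initial clone abundance)
    pseudocount: float = 0.5
    min_sites: int = 3
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("saturation", "survival_subbactericidal",
                     "survival_bactericidal", "read_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.growth_factor_control <= 0:
            raise ValueError("growth_factor_control must be positive")
        for g, n in self.colony_bottlenecks.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} in colony_bottlenecks")
            if n < 1:
                raise ValueError(f"colony bottleneck for {g!r} must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        if self.tag_length < 12:
            raise ValueError("tag_length must be >= 12 (uniqueness practical minimum)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")

    def survival(self, group: str) -> float:
        """Expected abundance multiplier for a group (growth for the control)."""
        if group == "control":
            return self.growth_factor_control
        if group == "sub":
            return self.survival_subbactericidal
        if group == "bactericidal":
            return self.survival_bactericidal
        raise ValueError(f"unknown group {group!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["colony_bottlenecks"] = dict(self.colony_bottlenecks)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreenConfig":
        d = dict(d)
        if "colony_bottlenecks" in d:
            d["colony_bottlenecks"] = dict(d["colony_bottlenecks"])
        return cls(**d)


def sample_name(group: str, replicate: int) -> str:
    """Canonical sample identifier, e.g. ``bactericidal_rep2``."""
    return f"{group}_rep{replicate}"
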