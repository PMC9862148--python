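"""Simulation configuration.

Defaults reproduce the structure of the study family's data: an 800-SNP
reading-gene panel of which 116 SNPs are invariant across the family
(leaving 684 variable) and 79 co-segregate with affection status; sibling
morphometry whose pairwise similarity matches the reported reading-region
ICCs; asymmetry indices planted from the reference table; and ROI masks
whose per-axis slice counts fall in the 30-70 range typical of the exported
mask stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import datasets
from .errors import ConfigError

PHENOTYPES = ("thickness", "area", "volume")


def _default_similarity() -> dict[str, dict[str, float]]:
    return datasets.similarity_profile()


def _default_asymmetry() -> dict[tuple[str, str, str], float]:
    return datasets.asymmetry_profile()


@dataclass
class SimulationConfig:
    # genotypes -----------------------------------------------------------
    n_snps_panel: int = 800
    n_snps_background: int = 2000
    #: fraction of panel (and background) SNPs planted with the
    #: "affected siblings share a genotype the unaffected twin lacks" pattern
    coseg_fraction: float = 79 / 800
    #: fraction of SNPs identical across all five family members
    invariant_rate: float = 116 / 800
    #: fraction of genotype calls given a GenCall-style confidence <= 0.15
    missing_rate: float = 0.0
    # morphometry ---------------------------------------------------------
    #: phenotype -> pair label -> target across-ROI correlation
    similarity_profile: dict[str, dict[str, float]] = field(default_factory=_default_similarity)
    #: (subject_id, roi, phenotype) -> exact asymmetry index to plant
    asymmetry_profile: dict[tuple[str, str, str], float] = field(default_factory=_default_asymmetry)
    # masks ---------------------------------------------------------------
    mask_slices_per_axis: tuple[int, int] = (30, 70)
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    #: pair label whose two members share mask shape (plus small jitter);
    #: None -> all three siblings independently jittered
    mask_similar_pair: Optional[str] = None
    #: SD (in slices) of per-subject extent perturbations
    mask_jitter: float = 4.0
    #: SD for the two members of the designated similar pair
    mask_pair_jitter: float = 0.5
    # ---------------------------------------------------------------------
    seed: int = 0

    def validate(self) -> None:
        for name in ("coseg_fraction", "invariant_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_snps_panel <= 0 or self.n_snps_background < 0:
            raise ConfigError("SNP counts must be positive")
        n_coseg = round(self.coseg_fraction * self.n_snps_panel)
        n_inv = round(self.invariant_rate * self.n_snps_panel)
        if n_coseg + n_inv > self.n_snps_panel:
            raise ConfigError("coseg_fraction + invariant_rate exceed the panel size")
        lo, hi = self.mask_slices_per_axis
        if not (1 <= lo <= hi):
            raise ConfigError("mask_slices_per_axis must be an increasing range from >= 1")
        if any(d <= 0 for d in self.grid_shape):
            raise ConfigError("grid_shape dimensions must be positive")
        if any(hi > d for d in self.grid_shape):
            raise ConfigError(
                f"mask_slices_per_axis upper bound {hi} exceeds grid {self.grid_shape}"
            )
        for ph, targets in self.similarity_profile.items():
            if ph not in PHENOTYPES:
                raise ConfigError(f"unknown phenotype {ph!r} in similarity_profile")
            for pair, r in targets.items():
                if not (0.0 <= r <= 1.0):
                    raise ConfigError(f"similarity target {r} for {pair}/{ph} outside [0, 1]")
        for key, a in self.asymmetry_profile.items():
            if not (-2.0 <= a <= 2.0):
                raise ConfigError(f"asymmetry target {a} for {key} outside [-2, 2]")
        if self.mask_jitter < 0 or self.mask_pair_jitter < 0:
            raise ConfigError("mask jitter SDs must be non-negative")

    # number of planted co-segregating / invariant SNPs -------------------
    @property
    def n_coseg_panel(self) -> int:
        return round(self.coseg_fraction * self.n_snps_panel)

    @property
    def n_coseg_background(self) -> int:
        return round(self.coseg_fraction * self.n_snps_background)

    @property
    def n_invariant_panel(self) -> int:
        return round(self.invariant_rate * self.n_snps_panel)

    @property
    def n_invariant_background(self) -> int:
        return round(self.invariant_rate * self.n_snps_background)
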