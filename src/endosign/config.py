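"""Simulation configuration for the synthetic endosperm dataset.

The defaults encode the study conditions the rest of the package is
exercised under: a triploid endosperm with 2:1 maternal:paternal dosage,
10% paternally expressed genes (PEGs, maternal fraction 0.10), 10%
maternally expressed genes (MEGs, maternal fraction 0.95) and 80%
biallelic genes (maternal fraction 2/3), ~100 informative reads per gene
per cross direction, and maternal-allele elevation of the three
signature marks (central-cell CHG methylation, H3K27me3, H3K9me2) on
PEGs only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

from .errors import ConfigurationError

IMPRINTING_CLASSES = ("PEG", "MEG", "biallelic")
HISTONE_MARKS = ("H3K27me3", "H3K9me2")
ALLELES = ("maternal", "paternal")
#: the three signature features scored per gene
SIGNATURE_FEATURES = ("CHG_central_cell", "H3K27me3_mat", "H3K9me2_mat")
METH_CONTEXTS = ("CG", "CHG", "CHH")
METH_SOURCES = (
    "central_cell",
    "sperm",
    "vegetative_cell",
    "endosperm_maternal",
    "endosperm_paternal",
)
CROSS_DIRECTIONS = ("ColxLer", "LerxCol")

#: expected maternal read fraction of a biallelic gene in triploid endosperm (2m:1p)
EXPECTED_BIALLELIC_MATERNAL_FRACTION = 2.0 / 3.0


def _default_class_fractions() -> Dict[str, float]:
    return {"PEG": 0.10, "MEG": 0.10, "biallelic": 0.80}


def _default_maternal_fractions() -> Dict[str, float]:
    return {
        "PEG": 0.10,
        "MEG": 0.95,
        "biallelic": EXPECTED_BIALLELIC_MATERNAL_FRACTION,
    }


def _default_mark_effect() -> Dict[str, Dict[str, float]]:
    zero = {feat: 0.0 for feat in SIGNATURE_FEATURES}
    return {
        "PEG": {"CHG_central_cell": 0.40, "H3K27me3_mat": 2.0, "H3K9me2_mat": 2.0},
        "MEG": dict(zero),
        "biallelic": dict(zero),
    }


def _default_meth_baseline() -> Dict[str, float]:
    # genic methylation baselines typical of Arabidopsis
    return {"CG": 0.24, "CHG": 0.08, "CHH": 0.03}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset generator.

    ``mark_effect`` maps imprinting class -> mean maternal-allele
    elevation of each signature feature: methylation-probability units
    for ``CHG_central_cell`` and log2-ratio units for the histone marks.
    ``contamination`` is the proportion of RNA reads drawn from a purely
    maternal (seed-coat) source.
    """

    n_genes: int = 1000
    chrom_length: int = 8_000_000
    chrom_name: str = "Chr1"
    gene_length_range: Tuple[int, int] = (1000, 3000)
    class_fractions: Dict[str, float] = field(default_factory=_default_class_fractions)
    sequencing_depth: float = 100.0
    maternal_fraction_by_class: Dict[str, float] = field(
        default_factory=_default_maternal_fractions
    )
    contamination: float = 0.0
    mark_effect: Dict[str, Dict[str, float]] = field(default_factory=_default_mark_effect)
    noise_sd: float = 0.5
    overdispersion: float = 0.0  # beta-binomial rho; 0 = pure binomial
    replicates_per_direction: int = 2
    track_step: int = 50
    h3_depth: float = 100.0
    meth_site_spacing: int = 50
    meth_read_depth: float = 10.0
    meth_baseline: Dict[str, float] = field(default_factory=_default_meth_baseline)
    min_gene_gap: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"gene_length_range must satisfy 0 < lo <= hi, got {(lo, hi)}")
        total = sum(self.class_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"class_fractions must sum to 1 (got {total!r})")
        for cls in self.class_fractions:
            if cls not in IMPRINTING_CLASSES:
                raise ConfigurationError(f"unknown imprinting class {cls!r}")
        for cls, f in self.maternal_fraction_by_class.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"maternal fraction for {cls!r} outside [0,1]: {f}")
        f_bi = self.maternal_fraction_by_class.get("biallelic")
        if f_bi is None or not math.isclose(f_bi, EXPECTED_BIALLELIC_MATERNAL_FRACTION, abs_tol=1e-9):
            raise ConfigurationError(
                "maternal_fraction_by_class['biallelic'] must equal 2/3 "
                "(triploid endosperm dosage)"
            )
        if not 0.0 <= self.contamination <= 1.0:
            raise ConfigurationError(f"contamination outside [0,1]: {self.contamination}")
        if not 0.0 <= self.overdispersion < 1.0:
            raise ConfigurationError("overdispersion (rho) must lie in [0,1)")
        if self.sequencing_depth <= 0:
            raise ConfigurationError("sequencing_depth must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.replicates_per_direction < 1:
            raise ConfigurationError("replicates_per_direction must be >= 1")
        if self.track_step < 1 or self.meth_site_spacing < 1:
            raise ConfigurationError("track_step and meth_site_spacing must be >= 1")

    def require_mark_effects(self) -> None:
        """Fail if any simulated class lacks a mark-effect entry."""
        for cls, frac in self.class_fractions.items():
            if frac > 0 and cls not in self.mark_effect:
                raise ConfigurationError(f"mark_effect is missing class {cls!r}")
            if frac > 0:
                missing = [f for f in SIGNATURE_FEATURES if f not in self.mark_effect[cls]]
                if missing:
                    raise ConfigurationError(
                        f"mark_effect[{cls!r}] is missing features {missing}"
                    )
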