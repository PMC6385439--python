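"""Gene annotation container.

Coordinates are 0-based half-open throughout the package; the GFF3
boundary (1-based closed) is converted in :mod:`endosign.io`.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GeneAnnotation:
    """A stranded genomic interval carrying a gene identifier."""

    gene_id: str
    chrom: str
    start: int  # 0-based, inclusive
    end: int  # exclusive
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start
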