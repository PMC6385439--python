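"""Allele-resolved ChIP signal processing.

Raw per-allele ChIP coverage is normalized against an H3 control as a
log2 ratio in fixed-width bins (150 bp by default), standardized with a
z-score transformation, and summarized either per gene (mean z over the
gene body) or as a metagene profile (-2 kb .. TSS .. TES .. +2 kb, with
100-bp flank bins and 40 equal-length body bins).

Tracks are plain numpy arrays on a fixed step grid; missing signal is
NaN, never 0.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .genes import GeneAnnotation

logger = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    """Raw coverage on a fixed step grid: mean read depth per window."""

    step: int
    values: Dict[str, np.ndarray]

    def chrom_length(self, chrom: str) -> int:
        return len(self.values[chrom]) * self.step


@dataclass
class BinTrack:
    """Normalized signal (log2 ratio or z-score) in fixed-width bins.

    ``values[chrom][i]`` covers ``[i*bin_width, (i+1)*bin_width)``;
    NaN marks bins with no signal in either channel.
    """

    bin_width: int
    values: Dict[str, np.ndarray]
    mark: Optional[str] = None
    allele: Optional[str] = None
    meta: Dict[str, object] = field(default_factory=dict)

    def finite_values(self) -> np.ndarray:
        all_vals = np.concatenate([v for v in self.values.values()]) if self.values else np.array([])
        return all_vals[np.isfinite(all_vals)]


@dataclass
class GeneMarkScore:
    """Mean z-score of a mark over one gene body."""

    gene_id: str
    z: float  # NaN when not scorable
    n_bins: int
    mark: Optional[str] = None
    allele: Optional[str] = None

    @property
    def not_scorable(self) -> bool:
        return not np.isfinite(self.z)


@dataclass
class MetageneProfile:
    """Mean signal across genes on an 80-position oriented coordinate.

    Positions run upstream-flank (5' -> TSS), body (TSS -> TES),
    downstream-flank (TES -> 3'); minus-strand genes are flipped before
    averaging. ``n_genes[i]`` counts genes contributing a finite value
    at position ``i``.
    """

    n_flank_bins: int
    body_bins: int
    flank_bin_bp: int
    mean_value: np.ndarray
    n_genes: np.ndarray

    @property
    def n_positions(self) -> int:
        return 2 * self.n_flank_bins + self.body_bins


def bin_log_ratio(
    chip: CoverageTrack,
    control: CoverageTrack,
    bin_width: int = 150,
    pseudocount: float = 1.0,
) -> BinTrack:
    """log2 ratio of ChIP over H3 control in fixed-width bins.

    Per-bin read-equivalents C and H (depth x bp) give
    ``log2((C + eps) / (H + eps))``; bins where both channels are zero
    are missing (NaN), not zero.
    """
    if bin_width < 1:
        raise ConfigurationError("bin_width must be >= 1")
    if set(chip.values) != set(control.values):
        only_chip = sorted(set(chip.values) - set(control.values))
        only_ctrl = sorted(set(control.values) - set(chip.values))
        raise InputError(
            f"chromosome sets differ: ChIP-only {only_chip}, control-only {only_ctrl}"
        )
    if chip.step != control.step:
        raise InputError(f"step mismatch: ChIP {chip.step} vs control {control.step}")
    if bin_width % chip.step != 0:
        raise ConfigurationError(
            f"bin_width ({bin_width}) must be a multiple of the track step ({chip.step})"
        )
    factor = bin_width // chip.step
    out: Dict[str, np.ndarray] = {}
    for chrom in chip.values:
        c = np.asarray(chip.values[chrom], dtype=float)
        h = np.asarray(control.values[chrom], dtype=float)
        if len(c) != len(h):
            raise InputError(f"{chrom}: ChIP and control lengths differ ({len(c)} vs {len(h)})")
        n_bins = math.ceil(len(c) / factor)
        pad = n_bins * factor - len(c)
        if pad:
            c = np.concatenate([c, np.zeros(pad)])
            h = np.concatenate([h, np.zeros(pad)])
        # read-equivalents: depth * bp covered
        c_sum = c.reshape(n_bins, factor).sum(axis=1) * chip.step
        h_sum = h.reshape(n_bins, factor).sum(axis=1) * chip.step
        vals = np.log2((c_sum + pseudocount) / (h_sum + pseudocount))
        vals[(c_sum == 0) & (h_sum == 0)] = np.nan
        out[chrom] = vals
    return BinTrack(bin_width=bin_width, values=out, meta={"pseudocount": pseudocount})


def zscore_track(track: BinTrack, per_chromosome: bool = False) -> BinTrack:
    """Standardize a track to mean 0, sd 1 over its finite bins.

    Population-sd convention (ddof=0). A constant track maps to zeros
    and raises a RuntimeWarning. Missing bins stay missing.
    """

    def _z(arrays: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
        flat = np.concatenate(list(arrays.values()))
        finite = flat[np.isfinite(flat)]
        if finite.size < 2:
            raise InputError("z-score transformation needs at least 2 finite bins")
        mu = finite.mean()
        sd = finite.std(ddof=0)
        out = {}
        if sd == 0.0:
            warnings.warn("constant track: z-scores set to 0", RuntimeWarning, stacklevel=3)
            for chrom, v in arrays.items():
                z = np.where(np.isfinite(v), 0.0, np.nan)
                out[chrom] = z
        else:
            for chrom, v in arrays.items():
                out[chrom] = (v - mu) / sd
        return out

    if per_chromosome:
        values = {}
        for chrom, v in track.values.items():
            values.update(_z({chrom: v}))
    else:
        values = _z(track.values)
    meta = dict(track.meta)
    meta.update({"zscored": True, "sd_convention": "population", "per_chromosome": per_chromosome})
    return BinTrack(
        bin_width=track.bin_width,
        values=values,
        mark=track.mark,
        allele=track.allele,
        meta=meta,
    )


def _interval_mean(values: np.ndarray, bin_width: int, a: float, b: float) -> float:
    """Overlap-weighted mean of track bins intersecting [a, b); NaN bins ignored."""
    if b <= a:
        return np.nan
    a = max(a, 0.0)
    b = min(b, len(values) * bin_width)
    if b <= a:
        return np.nan
    i0 = int(a // bin_width)
    i1 = int(math.ceil(b / bin_width))
    wsum = 0.0
    wtot = 0.0
    for i in range(i0, i1):
        v = values[i]
        if not np.isfinite(v):
            continue
        ov = min(b, (i + 1) * bin_width) - max(a, i * bin_width)
        wsum += v * ov
        wtot += ov
    return wsum / wtot if wtot > 0 else np.nan


def metagene_profile(
    track: BinTrack,
    genes: Iterable[GeneAnnotation],
    flank_bp: int = 2000,
    flank_bin_bp: int = 100,
    body_bins: int = 40,
) -> MetageneProfile:
    """Average oriented signal over genes: flanks in fixed bp bins, body
    in ``body_bins`` equal-length slices.

    Genes shorter than ``body_bins`` bp are skipped (logged). Missing
    track bins are ignored in each position's mean.
    """
    genes = list(genes)
    if not genes:
        raise InputError("metagene_profile requires a non-empty gene set")
    if flank_bp % flank_bin_bp != 0:
        raise ConfigurationError("flank_bp must be divisible by flank_bin_bp")
    n_flank = flank_bp // flank_bin_bp
    n_pos = 2 * n_flank + body_bins
    sums = np.zeros(n_pos)
    counts = np.zeros(n_pos, dtype=int)
    n_skipped = 0
    for gene in genes:
        if gene.length < body_bins:
            n_skipped += 1
            continue
        values = track.values.get(gene.chrom)
        if values is None:
            n_skipped += 1
            continue
        edges: List[float] = []
        edges.extend(gene.start - flank_bp + j * flank_bin_bp for j in range(n_flank))
        body_len = gene.length / body_bins
        edges.extend(gene.start + j * body_len for j in range(body_bins))
        edges.extend(float(gene.end + j * flank_bin_bp) for j in range(n_flank))
        edges.append(float(gene.end + flank_bp))
        prof = np.array(
            [_interval_mean(values, track.bin_width, edges[j], edges[j + 1]) for j in range(n_pos)]
        )
        if gene.strand == "-":
            prof = prof[::-1]
        finite = np.isfinite(prof)
        sums[finite] += prof[finite]
        counts[finite] += 1
    if n_skipped:
        logger.info("metagene_profile: skipped %d genes (too short or absent chromosome)", n_skipped)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MetageneProfile(
        n_flank_bins=n_flank,
        body_bins=body_bins,
        flank_bin_bp=flank_bin_bp,
        mean_value=mean,
        n_genes=counts,
    )


def gene_zscore(track: BinTrack, gene: GeneAnnotation) -> GeneMarkScore:
    """Mean z over all bins overlapping the gene body [start, end).

    Bins partially overlapping the gene boundary count whole. No finite
    overlapping bin -> not scorable (z = NaN).
    """
    values = track.values.get(gene.chrom)
    if values is None:
        return GeneMarkScore(gene.gene_id, np.nan, 0, track.mark, track.allele)
    w = track.bin_width
    i0 = max(gene.start // w, 0)
    i1 = min(math.ceil(gene.end / w), len(values))
    body = values[i0:i1]
    finite = body[np.isfinite(body)]
    if finite.size == 0:
        return GeneMarkScore(gene.gene_id, np.nan, 0, track.mark, track.allele)
    return GeneMarkScore(gene.gene_id, float(finite.mean()), int(finite.size), track.mark, track.allele)


def gene_zscore_table(track: BinTrack, genes: Sequence[GeneAnnotation]) -> pd.DataFrame:
    """Per-gene mean z-scores as a DataFrame (gene_id, mark, allele, z, n_bins)."""
    rows = [gene_zscore(track, g) for g in genes]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "mark": [r.mark for r in rows],
            "allele": [r.allele for r in rows],
            "z": [r.z for r in rows],
            "n_bins": [r.n_bins for r in rows],
        }
    )
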