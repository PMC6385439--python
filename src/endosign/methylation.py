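"""Weighted DNA-methylation levels per gene, context and source.

A cytosine record carries integer methylated/unmethylated read counts
and a context label (CG, CHG or CHH). The gene-level estimator is the
weighted methylation level: total methylated reads over total reads
across the gene's cytosines of one context, which is robust to
per-site coverage variation. A per-site mean is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputError
from .genes import GeneAnnotation

CX_COLUMNS = ("chrom", "pos", "strand", "count_methylated", "count_unmethylated", "context")


@dataclass
class MethylationLevel:
    level: float  # NaN when no covered cytosine
    covered_cytosines: int
    total_reads: int


def gene_methylation_level(
    records: pd.DataFrame,
    gene: GeneAnnotation,
    context: str,
    flank_bp: int = 0,
    per_site_mean: bool = False,
) -> MethylationLevel:
    """Methylation level of one gene in one context.

    Weighted level = sum(methylated) / sum(methylated + unmethylated)
    over covered cytosines within [start - flank, end + flank). Zero
    covered cytosines -> missing level (NaN), never 0.
    """
    for col in CX_COLUMNS:
        if col not in records.columns:
            raise InputError(f"cytosine records missing column {col!r}")
    sel = records[
        (records["chrom"] == gene.chrom)
        & (records["context"] == context)
        & (records["pos"] >= gene.start - flank_bp)
        & (records["pos"] < gene.end + flank_bp)
    ]
    m = sel["count_methylated"].to_numpy(dtype=np.int64)
    u = sel["count_unmethylated"].to_numpy(dtype=np.int64)
    if (m < 0).any() or (u < 0).any():
        raise InputError("negative methylation counts")
    tot = m + u
    covered = tot > 0
    n_cov = int(covered.sum())
    total_reads = int(tot.sum())
    if n_cov == 0:
        return MethylationLevel(np.nan, 0, 0)
    if per_site_mean:
        level = float(np.mean(m[covered] / tot[covered]))
    else:
        level = float(m.sum() / total_reads)
    return MethylationLevel(level, n_cov, total_reads)


def methylation_table(
    records: pd.DataFrame,
    genes: Sequence[GeneAnnotation],
    contexts: Iterable[str] = ("CG", "CHG", "CHH"),
    source: Optional[str] = None,
    genotype: str = "WT",
    flank_bp: int = 0,
    per_site_mean: bool = False,
) -> pd.DataFrame:
    """Per-gene, per-context weighted levels for one source/genotype."""
    rows = []
    for gene in genes:
        for ctx in contexts:
            lv = gene_methylation_level(records, gene, ctx, flank_bp, per_site_mean)
            rows.append(
                (gene.gene_id, ctx, source, genotype, lv.level, lv.covered_cytosines, lv.total_reads)
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "context", "source", "genotype", "level", "covered_cytosines", "total_reads"],
    )


def methylation_levels_nonoverlapping(
    records: pd.DataFrame,
    genes: Sequence[GeneAnnotation],
    context: str,
) -> "pd.Series":
    """Vectorized weighted levels for a sorted, non-overlapping gene set.

    Equivalent to :func:`gene_methylation_level` per gene (asserted by
    tests) but maps cytosines to genes with a single binary search, so
    it scales to genome-sized tables. Genes must be non-overlapping;
    the single-chromosome case is assumed per chromosome.
    """
    levels = pd.Series(np.nan, index=[g.gene_id for g in genes], name="level")
    for chrom in {g.chrom for g in genes}:
        sub = [g for g in sorted(genes, key=lambda g: g.start) if g.chrom == chrom]
        starts = np.array([g.start for g in sub])
        ends = np.array([g.end for g in sub])
        sel = records[(records["chrom"] == chrom) & (records["context"] == context)]
        pos = sel["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(sub) - 1)])
        idx = idx[ok]
        m = sel["count_methylated"].to_numpy()[ok]
        u = sel["count_unmethylated"].to_numpy()[ok]
        msum = np.bincount(idx, weights=m, minlength=len(sub))
        tsum = np.bincount(idx, weights=m + u, minlength=len(sub))
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = np.where(tsum > 0, msum / np.maximum(tsum, 1), np.nan)
        levels.loc[[g.gene_id for g in sub]] = lv
    return levels


def allelic_level_difference(level_mat: float, level_pat: float) -> float:
    """Maternal minus paternal level; missing if either side is missing."""
    if level_mat is None or level_pat is None:
        return np.nan
    if not (np.isfinite(level_mat) and np.isfinite(level_pat)):
        return np.nan
    for name, v in (("maternal", level_mat), ("paternal", level_pat)):
        if not 0.0 <= v <= 1.0:
            raise InputError(f"{name} level outside [0,1]: {v}")
    return float(level_mat - level_pat)
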