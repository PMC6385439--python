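"""Allele-specific imprinting caller for reciprocal-cross RNA-seq counts.

In triploid endosperm a biallelic gene is expected to show a 2:1
maternal:paternal read ratio. Per gene and cross direction, deviation
from 2:1 is assessed with a 1-df chi-square goodness-of-fit test
(no Yates correction by default), with Benjamini-Hochberg FDR control
per direction. Calls:

* MEG:  maternal fraction >= 0.85 in both directions, q < 0.01 in both
* PEG:  paternal fraction >= 0.50 in both directions, q < 0.01 in both
* biallelic otherwise; not_testable below 20 informative reads in
  either direction.

Maternal seed-coat contamination inflates the maternal fraction above
2/3; it is estimated by inverting the mixture
``f_obs = (1 - c) * 2/3 + c``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import EXPECTED_BIALLELIC_MATERNAL_FRACTION
from .errors import InputError

COUNT_COLUMNS = ("gene_id", "direction", "maternal", "paternal")


@dataclass
class ContaminationEstimate:
    """Maternal-contamination proportion inferred from pooled counts."""

    c: float
    f_obs: float
    n_genes: int


def merge_replicates(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum replicate counts per gene and direction."""
    for col in COUNT_COLUMNS:
        if col not in counts.columns:
            raise InputError(f"count table missing column {col!r}")
    merged = (
        counts.groupby(["gene_id", "direction"], as_index=False)[["maternal", "paternal"]]
        .sum()
    )
    return merged


def informative_filter(counts: pd.DataFrame, min_reads: int = 20) -> pd.DataFrame:
    """Keep genes with >= min_reads informative reads in every direction.

    Input must be replicate-merged (one row per gene x direction).
    Returns the input with a boolean ``testable`` column; a gene absent
    from any direction is not testable.
    """
    if min_reads < 0:
        raise InputError("min_reads must be >= 0")
    counts = counts.copy()
    counts["informative"] = counts["maternal"] + counts["paternal"]
    directions = sorted(counts["direction"].unique())
    wide = counts.pivot_table(index="gene_id", columns="direction", values="informative", fill_value=0)
    ok = (wide[directions] >= min_reads).all(axis=1) & (
        wide.shape[1] == len(directions)
    )
    per_gene = ok.reindex(counts["gene_id"]).to_numpy()
    counts["testable"] = per_gene
    return counts


def chisq_allelic_test(
    maternal: int,
    paternal: int,
    expected_ratio: Tuple[float, float] = (2.0, 1.0),
    yates: bool = False,
) -> Tuple[float, float]:
    """1-df goodness-of-fit of (maternal, paternal) against the dosage ratio.

    Expected counts are ``n * r_m`` and ``n * r_p`` for total n; the
    statistic is the usual Pearson chi-square, with an optional Yates
    continuity correction (off by default).
    """
    m, p = float(maternal), float(paternal)
    if m < 0 or p < 0:
        raise InputError("counts must be non-negative")
    n = m + p
    if n == 0:
        raise InputError("chi-square test undefined for zero informative reads")
    rm, rp = expected_ratio
    em, ep = n * rm / (rm + rp), n * rp / (rm + rp)
    if yates:
        stat = (abs(m - em) - 0.5) ** 2 / em + (abs(p - ep) - 0.5) ** 2 / ep
        stat = max(stat, 0.0)
    else:
        stat = (m - em) ** 2 / em + (p - ep) ** 2 / ep
    return float(stat), float(stats.chi2.sf(stat, df=1))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, ties preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def call_imprinting(
    counts: pd.DataFrame,
    min_reads: int = 20,
    fdr_level: float = 0.01,
    meg_min_maternal: float = 0.85,
    peg_min_paternal: float = 0.50,
    expected_ratio: Tuple[float, float] = (2.0, 1.0),
    yates: bool = False,
) -> pd.DataFrame:
    """Classify every gene as MEG, PEG, biallelic or not_testable.

    ``counts`` is a long table (gene_id, direction, maternal, paternal,
    optionally replicate); replicates are summed per direction before
    testing. The chi-square p-values are FDR-adjusted per direction
    over testable genes; MEG/PEG calls must satisfy the fraction rule
    and q < fdr_level in *both* cross directions.
    """
    merged = merge_replicates(counts)
    directions = sorted(merged["direction"].unique())
    flt = informative_filter(merged, min_reads=min_reads)
    wide = flt.pivot(index="gene_id", columns="direction", values=["maternal", "paternal"])
    genes = wide.index.to_numpy()

    mat = {
        d: wide[("maternal", d)].to_numpy(dtype=float) for d in directions
    }
    pat = {
        d: wide[("paternal", d)].to_numpy(dtype=float) for d in directions
    }
    for d in directions:
        mat[d] = np.nan_to_num(mat[d]).astype(np.int64)
        pat[d] = np.nan_to_num(pat[d]).astype(np.int64)
    testable_by_gene = flt.groupby("gene_id")["testable"].all().reindex(wide.index)
    testable = testable_by_gene.fillna(False).to_numpy(dtype=bool)

    out = pd.DataFrame({"gene_id": genes, "testable": testable})
    sig_all = np.ones(len(genes), dtype=bool)
    meg_frac = np.ones(len(genes), dtype=bool)
    peg_frac = np.ones(len(genes), dtype=bool)
    for d in directions:
        n = mat[d] + pat[d]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, mat[d] / np.maximum(n, 1), np.nan)
        stat = np.full(len(genes), np.nan)
        pval = np.full(len(genes), np.nan)
        idx = np.where(testable)[0]
        for i in idx:
            if n[i] > 0:
                stat[i], pval[i] = chisq_allelic_test(mat[d][i], pat[d][i], expected_ratio, yates)
        q = np.full(len(genes), np.nan)
        fin = idx[np.isfinite(pval[idx])]
        if fin.size:
            q[fin] = bh_fdr(pval[fin])
        out[f"informative_{d}"] = n
        out[f"f_{d}"] = f
        out[f"chi2_{d}"] = stat
        out[f"p_{d}"] = pval
        out[f"q_{d}"] = q
        sig_all &= np.where(testable, q < fdr_level, False)
        meg_frac &= np.where(testable, f >= meg_min_maternal, False)
        peg_frac &= np.where(testable, (1.0 - f) >= peg_min_paternal, False)

    call = np.full(len(genes), "biallelic", dtype=object)
    call[~testable] = "not_testable"
    call[testable & sig_all & meg_frac] = "MEG"
    call[testable & sig_all & peg_frac] = "PEG"
    out["call"] = call
    return out


def estimate_contamination(
    counts: pd.DataFrame,
    expected_fraction: float = EXPECTED_BIALLELIC_MATERNAL_FRACTION,
) -> ContaminationEstimate:
    """Invert f_obs = (1-c)*f_exp + c from pooled maternal/paternal counts.

    By default all supplied genes contribute (restrict the table to a
    known-biallelic set for an unbiased estimate when imprinted genes
    are abundant). c is clamped to [0, 1].
    """
    m = counts["maternal"].sum()
    p = counts["paternal"].sum()
    total = m + p
    if total <= 0:
        raise InputError("contamination estimate requires pooled informative reads > 0")
    f_obs = m / total
    denom = 1.0 - expected_fraction
    c = (f_obs - expected_fraction) / denom
    c = float(np.clip(c, 0.0, 1.0))
    return ContaminationEstimate(c=c, f_obs=float(f_obs), n_genes=int(counts["gene_id"].nunique()))
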