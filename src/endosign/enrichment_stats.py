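"""Enrichment and distribution-comparison statistics.

Hypergeometric over-representation (upper tail, computed in log space),
per-category 2x2 chi-square composition tests against a reference
category, Wilcoxon rank-sum (exact enumeration for small samples,
tie-corrected normal approximation otherwise), and expression-bias
profiles of mark levels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Upper-tail hypergeometric over-representation of a category among draws."""

    N: int  # population size
    K: int  # category size in the population
    n: int  # number of draws
    k: int  # category members among the draws
    p_value: float  # P(X >= k); may underflow to 0.0 in double precision
    log10_p: float  # exact log10 of the p-value (never -inf for k <= min(K, n))


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), including the observed k.

    The survival function is evaluated in log space so extreme
    enrichments report a finite log10 p-value instead of 0.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and 0 <= K and 0 <= n):
        raise InputError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return EnrichmentResult(N, K, n, k, 1.0, 0.0)
    logp = stats.hypergeom.logsf(k - 1, N, K, n)
    return EnrichmentResult(N, K, n, k, float(np.exp(logp)), float(logp / math.log(10)))


def category_composition_test(
    category_counts: Mapping[object, Tuple[int, int]],
    reference_counts: Tuple[int, int],
) -> pd.DataFrame:
    """Per-category 2x2 chi-square against a reference category.

    Each category supplies (members, non-members) counts — e.g. PEGs vs
    non-PEGs — compared with the reference (typically the maximum-score
    category). When any expected cell is < 1 the test switches to the
    exact hypergeometric (Fisher) p-value, logged per category.
    Empty categories are skipped with a log entry.
    """
    ref = np.asarray(reference_counts, dtype=float)
    if ref.sum() <= 0:
        raise InputError("reference category is empty")
    rows = []
    for cat, (a, b) in category_counts.items():
        if a + b == 0:
            logger.info("category_composition_test: category %r is empty, skipped", cat)
            continue
        table = np.array([[a, b], ref], dtype=float)
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if (expected < 1).any():
            _, p = stats.fisher_exact(table.astype(int))
            stat = np.nan
            method = "fisher_exact"
            logger.info(
                "category_composition_test: expected cell < 1 in category %r, "
                "exact hypergeometric p used",
                cat,
            )
        else:
            stat = float(((table - expected) ** 2 / expected).sum())
            p = float(stats.chi2.sf(stat, df=1))
            method = "chi2"
        rows.append((cat, a, b, stat, p, method))
    return pd.DataFrame(
        rows, columns=["category", "members", "non_members", "chi2", "p_value", "method"]
    )


def _mann_whitney_u(ranks_x: np.ndarray, n_x: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2)


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 12,
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration over all rank assignments when
    ``len(x) + len(y) <= exact_max_n`` (ties handled by enumerating the
    observed pooled values); otherwise the normal approximation with
    tie correction and no continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise InputError(f"unknown alternative {alternative!r}")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = _mann_whitney_u(ranks[:nx], nx)
    mu = nx * ny / 2.0

    if nx + ny <= exact_max_n:
        # enumerate every subset of positions assignable to x
        us = np.array(
            [_mann_whitney_u(ranks[list(idx)], nx) for idx in combinations(range(nx + ny), nx)]
        )
        total = us.size
        if alternative == "two-sided":
            p = np.sum(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12) / total
        elif alternative == "greater":
            p = np.sum(us >= u_obs - 1e-12) / total
        else:
            p = np.sum(us <= u_obs + 1e-12) / total
        return float(min(p, 1.0))

    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return 1.0
    z = (u_obs - mu) / math.sqrt(var)
    if alternative == "two-sided":
        return float(2 * stats.norm.sf(abs(z)))
    if alternative == "greater":
        return float(stats.norm.sf(z))
    return float(stats.norm.cdf(z))


def bias_profile(
    mark_values: Mapping[str, Mapping[str, float]],
    maternal_fractions: Mapping[str, float],
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Mean mark value per maternal-fraction bin, per mark/allele series.

    ``mark_values`` maps a series name (e.g. ``"H3K27me3_maternal"``)
    to per-gene values; genes are binned by their maternal read
    fraction over ``bin_edges`` (must cover [0, 1]; last bin closed).
    Empty bins report NaN.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ConfigurationError("bin edges must be strictly ascending with >= 2 values")
    if edges[0] > 0.0 or edges[-1] < 1.0:
        raise ConfigurationError("bin edges must cover [0, 1]")
    rows = []
    for series, values in mark_values.items():
        genes = [g for g in values if g in maternal_fractions]
        fracs = np.array([maternal_fractions[g] for g in genes], dtype=float)
        vals = np.array([values[g] for g in genes], dtype=float)
        idx = np.digitize(fracs, edges, right=False) - 1
        idx[fracs >= edges[-1]] = len(edges) - 2  # close the last bin
        for b in range(len(edges) - 1):
            sel = (idx == b) & np.isfinite(vals)
            mean = float(vals[sel].mean()) if sel.any() else np.nan
            rows.append((series, edges[b], edges[b + 1], mean, int(sel.sum())))
    return pd.DataFrame(rows, columns=["series", "bin_lo", "bin_hi", "mean_value", "n_genes"])
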