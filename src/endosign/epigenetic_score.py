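"""Discrete epigenetic scoring of the tripartite PEG signature.

Each gene receives a level 0..L (default L=4) for each of three
features — central-cell CHG methylation, maternal-allele H3K27me3 and
maternal-allele H3K9me2 — and the combined score is their sum (0..12
by default). Genes in the maximum-score category form the predicted
PEG set.

Default level breakpoints are the quantiles [0, .25, .5, .75] of the
genes with present (finite) signal, so absent genes score 0 and
present genes split into quartile levels 1..4. Breakpoints are fully
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

SCORE_FEATURES = ("chg_cc", "k27_mat", "k9_mat")


@dataclass
class EpigeneticScore:
    gene_id: str
    level_chg_cc: int
    level_k27_mat: int
    level_k9_mat: int
    score: int
    category: int
    is_max_category: bool


def level_bin(value: float, breakpoints: Sequence[float]) -> int:
    """Number of breakpoints <= value (closed-left rule); missing -> 0."""
    bp = np.asarray(breakpoints, dtype=float)
    if bp.ndim != 1 or bp.size == 0:
        raise ConfigurationError("breakpoints must be a non-empty 1-D sequence")
    if not np.all(np.diff(bp) > 0):
        raise ConfigurationError(f"breakpoints must be strictly ascending, got {list(bp)}")
    if value is None or not np.isfinite(value):
        return 0
    return int(np.sum(bp <= value))


def quartile_breakpoints(values: Sequence[float], n_levels: int = 4) -> np.ndarray:
    """Breakpoints at quantiles [0, 1/L, ..., (L-1)/L] of present values.

    Computed over finite values only; the lowest breakpoint is their
    minimum, so every present gene gets at least level 1.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InputError("no finite values to derive breakpoints from")
    qs = np.quantile(vals, [i / n_levels for i in range(n_levels)])
    if not np.all(np.diff(qs) > 0):
        raise ConfigurationError(
            "quantile breakpoints are not strictly ascending (heavily tied values); "
            "supply explicit breakpoints instead"
        )
    return qs


def combined_score(
    gene_id: str,
    level_chg_cc: int,
    level_k27_mat: int,
    level_k9_mat: int,
    max_level: int = 4,
) -> EpigeneticScore:
    """Sum the three per-mark levels into the combined score (0..3*L)."""
    levels = (level_chg_cc, level_k27_mat, level_k9_mat)
    for lv in levels:
        if not (isinstance(lv, (int, np.integer)) and 0 <= lv <= max_level):
            raise InputError(f"level {lv!r} outside 0..{max_level}")
    score = int(sum(levels))
    return EpigeneticScore(
        gene_id=gene_id,
        level_chg_cc=int(level_chg_cc),
        level_k27_mat=int(level_k27_mat),
        level_k9_mat=int(level_k9_mat),
        score=score,
        category=score,
        is_max_category=(score == 3 * max_level),
    )


def score_table(
    chg_cc: Mapping[str, float],
    k27_mat: Mapping[str, float],
    k9_mat: Mapping[str, float],
    breakpoints: Optional[Dict[str, Sequence[float]]] = None,
    max_level: int = 4,
) -> pd.DataFrame:
    """Score every gene present in all three feature maps.

    ``breakpoints`` maps feature name in ``SCORE_FEATURES`` to explicit
    ascending breakpoints; omitted features use quartile breakpoints of
    their own present values.
    """
    genes = sorted(set(chg_cc) & set(k27_mat) & set(k9_mat))
    if not genes:
        raise InputError("no genes shared by the three feature tables")
    feats = {"chg_cc": chg_cc, "k27_mat": k27_mat, "k9_mat": k9_mat}
    breakpoints = dict(breakpoints or {})
    levels: Dict[str, List[int]] = {}
    for name, table in feats.items():
        bp = breakpoints.get(name)
        if bp is None:
            bp = quartile_breakpoints([table[g] for g in genes], n_levels=max_level)
            breakpoints[name] = bp
        levels[name] = [level_bin(table[g], bp) for g in genes]
    rows = [
        combined_score(g, levels["chg_cc"][i], levels["k27_mat"][i], levels["k9_mat"][i], max_level)
        for i, g in enumerate(genes)
    ]
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "level_chg_cc": [r.level_chg_cc for r in rows],
            "level_k27_mat": [r.level_k27_mat for r in rows],
            "level_k9_mat": [r.level_k9_mat for r in rows],
            "score": [r.score for r in rows],
            "category": [r.category for r in rows],
            "is_max_category": [r.is_max_category for r in rows],
        }
    )
    df.attrs["breakpoints"] = {k: list(np.asarray(v, dtype=float)) for k, v in breakpoints.items()}
    return df


def maternal_specific_filter(
    z_maternal: Mapping[str, float],
    z_paternal: Mapping[str, float],
    threshold: float = 1.0,
) -> pd.Series:
    """Flag genes carrying a mark on the maternal but not the paternal allele.

    maternal-specific <=> z_mat >= threshold and z_pat < threshold.
    Missing paternal z counts as below threshold (the number of such
    genes is logged); missing maternal z is never maternal-specific.
    """
    genes = sorted(z_maternal)
    n_missing_pat = 0
    flags = {}
    for g in genes:
        zm = z_maternal.get(g, np.nan)
        zp = z_paternal.get(g, np.nan)
        if not np.isfinite(zp):
            n_missing_pat += 1
            zp = -np.inf
        flags[g] = bool(np.isfinite(zm) and zm >= threshold and zp < threshold)
    if n_missing_pat:
        logger.info(
            "maternal_specific_filter: %d genes lacked a paternal z-score "
            "(treated as below threshold)",
            n_missing_pat,
        )
    return pd.Series(flags, name="maternal_specific")


def predict_pegs(scores: pd.DataFrame) -> List[str]:
    """Genes in the maximum-score category, sorted by gene_id."""
    return sorted(scores.loc[scores["is_max_category"], "gene_id"].tolist())
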