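"""Synthetic endosperm dataset generator.

Emulates the statistical structure the downstream analysis assumes:

* non-overlapping stranded gene annotations on one chromosome;
* per-allele histone ChIP coverage (H3K27me3, H3K9me2) with a flat H3
  control, where PEG-class genes carry a maternal-allele log2 elevation
  over gene bodies;
* per-cytosine methylation calls (CG/CHG/CHH) for five sources, with
  central-cell CHG elevated on PEG genes;
* reciprocal-cross allele-specific RNA counts with Poisson totals and a
  binomial maternal split at ``f_eff = (1-c) * f_class + c`` where c is
  the maternal seed-coat contamination proportion.

All randomness derives from ``config.seed`` via per-stage substreams,
so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .chip_signal import CoverageTrack
from .config import (
    ALLELES,
    CROSS_DIRECTIONS,
    HISTONE_MARKS,
    METH_CONTEXTS,
    METH_SOURCES,
    SimulationConfig,
)
from .errors import ConfigurationError, InputError
from .genes import GeneAnnotation

# substream salts: keep each stage's randomness independent of the others
_SALT_ANNOTATION = 11
_SALT_TRUTH = 12
_SALT_MARKS = 13
_SALT_COUNTS = 14

_MARK_FEATURE = {"H3K27me3": "H3K27me3_mat", "H3K9me2": "H3K9me2_mat"}
# offset of each context's cytosines within a spacing window, so the
# three contexts never collide at one position
_CONTEXT_OFFSET = {"CG": 0, "CHG": 17, "CHH": 34}

TRUTH_COLUMNS = (
    "gene_id",
    "imprinting_class",
    "maternal_fraction",
    "mu_H3K27me3_maternal",
    "mu_H3K27me3_paternal",
    "mu_H3K9me2_maternal",
    "mu_H3K9me2_paternal",
    "p_CHG_central_cell",
)


@dataclass
class MarkData:
    """Simulated chromatin and methylation data."""

    chip: Dict[Tuple[str, str], CoverageTrack]  # (mark, allele) -> coverage
    h3: Dict[str, CoverageTrack]  # allele -> control coverage
    methylation: Dict[str, pd.DataFrame]  # source -> CX records


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: List[GeneAnnotation]
    truth: pd.DataFrame
    marks: MarkData
    counts: pd.DataFrame


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), salt])


def generate_annotation(config: SimulationConfig) -> List[GeneAnnotation]:
    """Place non-overlapping stranded genes on one chromosome.

    Gene lengths are uniform over ``gene_length_range``; inter-gene gaps
    are ``min_gene_gap`` plus a multinomial share of the slack, which
    guarantees non-overlap. Infeasible configurations raise upfront.
    """
    rng = _rng(config, _SALT_ANNOTATION)
    n = config.n_genes
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    required = int(lengths.sum()) + (n + 1) * config.min_gene_gap
    if required > config.chrom_length:
        raise ConfigurationError(
            f"cannot place {n} genes of total length {int(lengths.sum())} bp "
            f"plus {(n + 1) * config.min_gene_gap} bp of minimum gaps on a "
            f"{config.chrom_length} bp chromosome"
        )
    slack = config.chrom_length - required
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    gaps = config.min_gene_gap + extra
    strands = rng.choice(np.array(["+", "-"]), size=n)
    genes = []
    pos = 0
    width = max(5, len(str(n)))
    for i in range(n):
        pos += int(gaps[i])
        start = pos
        end = start + int(lengths[i])
        genes.append(
            GeneAnnotation(
                gene_id=f"GENE{i + 1:0{width}d}",
                chrom=config.chrom_name,
                start=start,
                end=end,
                strand=str(strands[i]),
            )
        )
        pos = end
    return genes


def generate_truth(genes: List[GeneAnnotation], config: SimulationConfig) -> pd.DataFrame:
    """Assign imprinting classes and true generating parameters per gene.

    Class counts are the rounded class fractions (biallelic absorbs the
    remainder), shuffled deterministically.
    """
    config.require_mark_effects()
    rng = _rng(config, _SALT_TRUTH)
    n = len(genes)
    n_peg = int(round(n * config.class_fractions.get("PEG", 0.0)))
    n_meg = int(round(n * config.class_fractions.get("MEG", 0.0)))
    if n_peg + n_meg > n:
        raise ConfigurationError("PEG + MEG fractions exceed the gene count")
    labels = np.array(["PEG"] * n_peg + ["MEG"] * n_meg + ["biallelic"] * (n - n_peg - n_meg))
    labels = labels[rng.permutation(n)]
    baseline_chg = config.meth_baseline["CHG"]
    rows = []
    for gene, cls in zip(genes, labels):
        eff = config.mark_effect[cls]
        rows.append(
            (
                gene.gene_id,
                cls,
                config.maternal_fraction_by_class[cls],
                eff["H3K27me3_mat"],
                0.0,
                eff["H3K9me2_mat"],
                0.0,
                float(np.clip(baseline_chg + eff["CHG_central_cell"], 0.0, 1.0)),
            )
        )
    return pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))


def _check_truth_covers(genes: List[GeneAnnotation], truth: pd.DataFrame) -> None:
    truth_ids = truth["gene_id"]
    if truth_ids.duplicated().any():
        raise InputError("truth table lists a gene more than once")
    missing = {g.gene_id for g in genes} - set(truth_ids)
    if missing:
        raise InputError(f"truth table missing genes: {sorted(missing)[:5]}...")


def simulate_marks(
    genes: List[GeneAnnotation], truth: pd.DataFrame, config: SimulationConfig
) -> MarkData:
    """Simulate ChIP coverage tracks and per-cytosine methylation calls.

    ChIP coverage per step is ``h3_depth * 2**z`` with
    ``z ~ N(effect, noise_sd)`` over PEG gene bodies on the maternal
    allele (effect 0 elsewhere), so the noiseless log2 ratio equals the
    configured effect exactly. The H3 control is flat and positive.
    """
    config.require_mark_effects()
    _check_truth_covers(genes, truth)
    rng = _rng(config, _SALT_MARKS)
    step = config.track_step
    n_steps = -(-config.chrom_length // step)
    chrom = config.chrom_name
    cls_by_gene = dict(zip(truth["gene_id"], truth["imprinting_class"]))

    h3 = {
        allele: CoverageTrack(step=step, values={chrom: np.full(n_steps, config.h3_depth)})
        for allele in ALLELES
    }
    chip: Dict[Tuple[str, str], CoverageTrack] = {}
    for mark in HISTONE_MARKS:
        feature = _MARK_FEATURE[mark]
        for allele in ALLELES:
            mu = np.zeros(n_steps)
            if allele == "maternal":
                for gene in genes:
                    eff = config.mark_effect[cls_by_gene[gene.gene_id]][feature]
                    if eff:
                        mu[gene.start // step : -(-gene.end // step)] += eff
            z = mu + rng.normal(0.0, config.noise_sd, n_steps) if config.noise_sd > 0 else mu
            chip[(mark, allele)] = CoverageTrack(
                step=step, values={chrom: config.h3_depth * np.exp2(z)}
            )

    methylation: Dict[str, pd.DataFrame] = {}
    for source in METH_SOURCES:
        frames = []
        for context in METH_CONTEXTS:
            offset = _CONTEXT_OFFSET[context]
            positions, probs = [], []
            for gene in genes:
                pos = np.arange(gene.start + offset, gene.end, config.meth_site_spacing)
                p = config.meth_baseline[context]
                if context == "CHG" and source == "central_cell":
                    p += config.mark_effect[cls_by_gene[gene.gene_id]]["CHG_central_cell"]
                positions.append(pos)
                probs.append(np.full(pos.size, np.clip(p, 0.0, 1.0)))
            pos = np.concatenate(positions)
            p = np.concatenate(probs)
            cov = rng.poisson(config.meth_read_depth, pos.size)
            meth = rng.binomial(cov, p)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": "+",
                        "count_methylated": meth,
                        "count_unmethylated": cov - meth,
                        "context": context,
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        methylation[source] = df.sort_values("pos", kind="stable").reset_index(drop=True)
    return MarkData(chip=chip, h3=h3, methylation=methylation)


def simulate_counts(
    genes: List[GeneAnnotation], truth: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Reciprocal-cross allele-specific RNA counts.

    Per gene, direction and replicate: total ~ Poisson(depth/replicates)
    and maternal ~ Binomial(total, f_eff) with
    ``f_eff = (1-c) * f_class + c``. An optional beta-binomial
    overdispersion rho draws the per-observation success probability
    from Beta(f_eff, rho). Reciprocal directions swap accession labels
    but preserve parental roles, so f_eff is direction-independent.
    """
    _check_truth_covers(genes, truth)
    if config.sequencing_depth <= 0:
        raise ConfigurationError("sequencing_depth must be positive")
    rng = _rng(config, _SALT_COUNTS)
    order = {g.gene_id: i for i, g in enumerate(genes)}
    truth = truth.sort_values("gene_id", key=lambda s: s.map(order)).reset_index(drop=True)
    n = len(genes)
    c = config.contamination
    f_class = truth["maternal_fraction"].to_numpy()
    f_eff = (1.0 - c) * f_class + c
    per_rep_depth = config.sequencing_depth / config.replicates_per_direction
    rho = config.overdispersion
    frames = []
    for direction in CROSS_DIRECTIONS:
        for rep in range(1, config.replicates_per_direction + 1):
            total = rng.poisson(per_rep_depth, n)
            if rho > 0:
                a = f_eff * (1.0 / rho - 1.0)
                b = (1.0 - f_eff) * (1.0 / rho - 1.0)
                p = rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))
            else:
                p = f_eff
            maternal = rng.binomial(total, p)
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": truth["gene_id"],
                        "direction": direction,
                        "replicate": rep,
                        "maternal": maternal,
                        "paternal": total - maternal,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: annotation, truth, marks and counts."""
    genes = generate_annotation(config)
    truth = generate_truth(genes, config)
    marks = simulate_marks(genes, truth, config)
    counts = simulate_counts(genes, truth, config)
    return SimulatedDataset(config=config, genes=genes, truth=truth, marks=marks, counts=counts)
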