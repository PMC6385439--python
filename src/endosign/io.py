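"""Readers and writers for the plain-text formats the pipeline exchanges.

GFF3 (1-based closed on disk, converted to 0-based half-open in
memory), bedGraph coverage/score tracks, CX-report-style cytosine
tables, allele-specific count tables and the JSON truth table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd

from .chip_signal import BinTrack, CoverageTrack
from .errors import InputError
from .genes import GeneAnnotation
from .methylation import CX_COLUMNS

PathLike = Union[str, Path]


# ---------------------------------------------------------------- GFF3

def write_gff3(genes: List[GeneAnnotation], path: PathLike, source: str = "endosign") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_gff3(path: PathLike, feature_type: str = "gene") -> List[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise InputError(f"malformed GFF3 line: {line.rstrip()!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            if ftype != feature_type:
                continue
            gene_id = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gene_id = item[3:]
                    break
            if gene_id is None:
                raise InputError(f"GFF3 feature without ID attribute: {line.rstrip()!r}")
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                )
            )
    return genes


# ------------------------------------------------------------ bedGraph

def _write_bedgraph_values(values: Dict[str, np.ndarray], width: int, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(values):
            v = values[chrom]
            i = 0
            n = len(v)
            while i < n:
                j = i + 1
                vi = v[i]
                if np.isnan(vi):
                    i += 1
                    continue
                while j < n and v[j] == vi:
                    j += 1
                fh.write(f"{chrom}\t{i * width}\t{j * width}\t{vi:.6g}\n")
                i = j


def write_bedgraph(track: Union[CoverageTrack, BinTrack], path: PathLike) -> None:
    width = track.step if isinstance(track, CoverageTrack) else track.bin_width
    _write_bedgraph_values(track.values, width, path)


def _read_bedgraph_values(path: PathLike, width: int, missing: float) -> Dict[str, np.ndarray]:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#"
    )
    out: Dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        n = int(np.ceil(sub["end"].max() / width))
        acc = np.zeros(n)
        cov = np.zeros(n)
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            i0, i1 = int(s // width), int(np.ceil(e / width))
            for i in range(i0, i1):
                ov = min(e, (i + 1) * width) - max(s, i * width)
                acc[i] += v * ov
                cov[i] += ov
        vals = np.full(n, missing)
        nz = cov > 0
        vals[nz] = acc[nz] / cov[nz]
        out[str(chrom)] = vals
    return out


def read_bedgraph_coverage(path: PathLike, step: int) -> CoverageTrack:
    """Rasterize a bedGraph onto a fixed step grid (mean depth per window).

    Bases not covered by any interval count as depth 0.
    """
    values = _read_bedgraph_values(path, step, missing=0.0)
    # uncovered stretches are depth 0, not missing
    return CoverageTrack(step=step, values=values)


def read_bedgraph_track(path: PathLike, bin_width: int, **kwargs) -> BinTrack:
    """Read a score track (e.g. a written z-score track); gaps are missing."""
    values = _read_bedgraph_values(path, bin_width, missing=np.nan)
    return BinTrack(bin_width=bin_width, values=values, **kwargs)


# ----------------------------------------------------------- CX report

def write_cx_report(records: pd.DataFrame, path: PathLike) -> None:
    records.loc[:, list(CX_COLUMNS)].to_csv(path, sep="\t", header=False, index=False)


def read_cx_report(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < len(CX_COLUMNS):
        raise InputError(f"CX report needs {len(CX_COLUMNS)} columns, found {df.shape[1]}")
    df = df.iloc[:, : len(CX_COLUMNS)]
    df.columns = list(CX_COLUMNS)
    return df


# -------------------------------------------------------- count tables

def write_counts(counts: pd.DataFrame, path: PathLike) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "direction", "maternal", "paternal"):
        if col not in df.columns:
            raise InputError(f"count table missing column {col!r}")
    return df


# --------------------------------------------------------- truth table

def write_truth_json(truth: pd.DataFrame, path: PathLike) -> None:
    payload = {
        row["gene_id"]: {k: row[k] for k in truth.columns if k != "gene_id"}
        for _, row in truth.iterrows()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth_json(path: PathLike) -> pd.DataFrame:
    with open(path) as fh:
        payload = json.load(fh)
    rows = [{"gene_id": g, **fields} for g, fields in payload.items()]
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)
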