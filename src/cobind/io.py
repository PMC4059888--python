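"""Readers and writers for the plain-text interchange formats.

Genes travel as BED12 (one block per gene; coordinates half-open), peaks as
BED6 plus a seventh summit column, reads as BED6, coverage as bedGraph, and
tables as TSV with a header. GTF-style 1-based inputs are converted to the
internal 0-based half-open convention on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    CoverageTrack,
    ExpressionTable,
    GeneUniverse,
    PeakSet,
    ReadSet,
    SpectralCountTable,
    SynthTruth,
)


def write_genes_bed12(universe: GeneUniverse, path: str | Path) -> None:
    g = universe.genes
    start = np.minimum(g["tss"], g["tts"])
    end = np.maximum(g["tss"], g["tts"]) + 1
    size = end - start
    bed = pd.DataFrame(
        {
            "chrom": g["chrom"], "start": start, "end": end, "name": g["gene_id"],
            "score": 0, "strand": g["strand"], "thickStart": start, "thickEnd": end,
            "itemRgb": "0,0,0", "blockCount": 1, "blockSizes": size.astype(str) + ",",
            "blockStarts": "0,",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed12(path: str | Path, chrom_sizes: Mapping[str, int]) -> GeneUniverse:
    bed = pd.read_csv(path, sep="\t", header=None, usecols=range(6),
                      names=["chrom", "start", "end", "name", "score", "strand"])
    plus = bed["strand"] == "+"
    genes = pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "strand": bed["strand"],
            "tss": np.where(plus, bed["start"], bed["end"] - 1),
            "tts": np.where(plus, bed["end"] - 1, bed["start"]),
        }
    )
    return GeneUniverse(genes=genes, chrom_sizes=dict(chrom_sizes))


def write_peaks_bed(peaks: PeakSet, path: str | Path) -> None:
    """BED6 plus a 7th absolute-summit column."""
    p = peaks.peaks
    bed = pd.DataFrame(
        {
            "chrom": p["chrom"], "start": p["start"], "end": p["end"],
            "name": [f"{peaks.factor_name}_{i}" for i in range(len(p))],
            "score": p["score"].fillna(0.0), "strand": ".", "summit": p["summit"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path: str | Path, factor_name: str = "factor") -> PeakSet:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand", "summit"])
    if bed["summit"].isna().any():  # BED6 without summit: fall back to midpoint
        bed["summit"] = (bed["start"] + bed["end"]) // 2
    peaks = pd.DataFrame(
        {
            "chrom": bed["chrom"], "start": bed["start"], "end": bed["end"],
            "summit": bed["summit"].astype(int), "tag_density": 0.0, "score": bed["score"],
        }
    )
    return PeakSet(factor_name=factor_name, peaks=peaks)


def write_reads_bed(reads: ReadSet, path: str | Path) -> None:
    r = reads.reads
    plus = r["strand"] == "+"
    start = np.where(plus, r["pos"], r["pos"] - reads.read_length + 1).astype(int)
    bed = pd.DataFrame(
        {
            "chrom": r["chrom"], "start": np.maximum(start, 0),
            "end": start + reads.read_length,
            "name": [f"read_{i}" for i in range(len(r))], "score": 0, "strand": r["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path: str | Path) -> ReadSet:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    read_length = int((bed["end"] - bed["start"]).mode()[0])
    plus = bed["strand"] == "+"
    reads = pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "pos": np.where(plus, bed["start"], bed["end"] - 1),
            "strand": bed["strand"],
        }
    )
    return ReadSet(reads=reads, read_length=read_length)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.bins):
            vec = track.bins[chrom]
            for i, v in enumerate(vec):
                if v != 0:
                    fh.write(
                        f"{chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v:g}\n"
                    )


def read_bedgraph(
    path: str | Path, chrom_sizes: Mapping[str, int], bin_size: int = 25, extension: int = 200
) -> CoverageTrack:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    bins = {
        c: np.zeros(int(np.ceil(size / bin_size))) for c, size in chrom_sizes.items()
    }
    for row in df.itertuples(index=False):
        if row.start % bin_size or (row.end - row.start) != bin_size:
            raise ValueError(f"bedGraph interval not on the {bin_size}-bp grid: {row}")
        bins[row.chrom][row.start // bin_size] = row.value
    total = float(sum(v.sum() for v in bins.values()))
    return CoverageTrack(bin_size=bin_size, bins=bins, extension=extension, total_tags=total)


def write_expression_tsv(expr: ExpressionTable, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path, unit: str = "FPKM") -> ExpressionTable:
    """Read a gene x sample TSV whose columns are named ``condition_rep``."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    cond, rep = [], []
    for c in values.columns:
        base, _, r = c.rpartition("_")
        cond.append(base)
        rep.append(int(r) if r.isdigit() else 0)
    samples = pd.DataFrame(
        {"condition": cond, "replicate": rep}, index=pd.Index(values.columns, name="sample")
    )
    return ExpressionTable(values=values, samples=samples, unit=unit)


def write_counts_tsv(counts: SpectralCountTable, path: str | Path) -> None:
    counts.counts.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> SpectralCountTable:
    return SpectralCountTable(pd.read_csv(path, sep="\t"))


def write_truth_tsv(truth: SynthTruth, path: str | Path) -> None:
    rows = []
    for gid in sorted(truth.specific_genes):
        rows.append(("specific", gid, ""))
    for gid in sorted(truth.de_genes_up):
        rows.append(("de", gid, "up"))
    for gid in sorted(truth.de_genes_down):
        rows.append(("de", gid, "down"))
    for factor, ids in truth.bound_genes.items():
        for gid in sorted(ids):
            rows.append((f"bound:{factor}", gid, ""))
    for cplx, ids in truth.complex_members.items():
        for pid in sorted(ids):
            rows.append((f"complex:{cplx}", pid, ""))
    pd.DataFrame(rows, columns=["kind", "id", "direction"]).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    def convert(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=convert) + "\n")
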