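"""Shared domain containers.

All genomic coordinates are 0-based, half-open (BED native). A gene is
represented by its transcription start site (TSS) and transcription
termination site (TTS); on the minus strand the TSS is the larger
coordinate. Every container here is a thin, validated wrapper around a
pandas DataFrame or numpy arrays so the statistical modules can stay
vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tts"]
PEAK_COLUMNS = ["chrom", "start", "end", "summit", "tag_density", "score"]


@dataclass(frozen=True)
class GeneUniverse:
    """Non-redundant gene models defining the ID pool for all set statistics.

    Parameters
    ----------
    genes : DataFrame with columns ``gene_id, chrom, strand, tss, tts``.
        One row per gene after collapsing redundant transcripts; the number
        of rows is the universe size ``N`` used by the enrichment null.
    chrom_sizes : mapping of chromosome name to length in bp.
    """

    genes: pd.DataFrame
    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        g = self.genes
        missing = [c for c in GENE_COLUMNS if c not in g.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id: {dup!r}")
        unknown = set(g["chrom"]) - set(self.chrom_sizes)
        if unknown:
            raise ValueError(f"gene chromosomes not in chrom_sizes: {sorted(unknown)}")
        if not g["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        sizes = g["chrom"].map(self.chrom_sizes)
        for col in ("tss", "tts"):
            if (g[col] < 0).any() or (g[col] >= sizes).any():
                raise ValueError(f"{col} outside chromosome bounds")
        plus = g["strand"] == "+"
        if (g.loc[plus, "tss"] >= g.loc[plus, "tts"]).any():
            raise ValueError("plus-strand gene with tss >= tts")
        if (g.loc[~plus, "tss"] <= g.loc[~plus, "tts"]).any():
            raise ValueError("minus-strand gene with tss <= tts")

    @property
    def size(self) -> int:
        """Number of gene IDs (the ``N`` of the enrichment pool)."""
        return len(self.genes)

    @property
    def ids(self) -> set[str]:
        return set(self.genes["gene_id"])

    def starts_ends(self) -> tuple[np.ndarray, np.ndarray]:
        """Half-open genomic extents (start < end) regardless of strand."""
        tss = self.genes["tss"].to_numpy()
        tts = self.genes["tts"].to_numpy()
        return np.minimum(tss, tts), np.maximum(tss, tts) + 1


@dataclass(frozen=True)
class PeakSet:
    """Scored peak intervals for one factor, sorted by (chrom, start).

    Peak intervals are half-open with ``start <= summit < end``. Overlapping
    peaks are legal: caller output is taken as-is.
    """

    factor_name: str
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.peaks
        missing = [c for c in PEAK_COLUMNS if c not in p.columns]
        if missing:
            raise ValueError(f"peak table missing columns: {missing}")
        if len(p):
            if (p["start"] >= p["end"]).any():
                raise ValueError("peak with start >= end")
            bad = (p["summit"] < p["start"]) | (p["summit"] >= p["end"])
            if bad.any():
                raise ValueError("peak summit outside [start, end)")
            if (p["tag_density"] < 0).any():
                raise ValueError("negative tag_density")
            object.__setattr__(
                self,
                "peaks",
                p.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True),
            )

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class ReadSet:
    """Aligned single-end reads reduced to (chrom, 5' position, strand)."""

    reads: pd.DataFrame  # columns chrom, pos (5' end), strand
    read_length: int = 50

    def __post_init__(self) -> None:
        missing = [c for c in ("chrom", "pos", "strand") if c not in self.reads.columns]
        if missing:
            raise ValueError(f"read table missing columns: {missing}")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class ExpressionTable:
    """Gene x sample expression matrix with condition metadata.

    ``values`` is indexed by gene_id; ``samples`` carries one row per column
    of ``values`` with fields ``condition`` ({'test', 'control'}) and
    ``replicate``. ``unit`` tags the scale ('FPKM' or 'intensity').
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "FPKM"

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("sample metadata must be indexed by the value columns")
        if not self.samples["condition"].isin(["test", "control"]).all():
            raise ValueError("condition must be 'test' or 'control'")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")

    def condition_matrix(self, condition: str) -> pd.DataFrame:
        if condition not in set(self.samples["condition"]):
            raise ValueError(f"no samples with condition {condition!r}")
        cols = self.samples.index[self.samples["condition"] == condition]
        return self.values[cols]


@dataclass(frozen=True)
class SpectralCountTable:
    """Protein-level spectral counts from one MudPIT run."""

    counts: pd.DataFrame  # columns protein_id, spectral_count, protein_length

    def __post_init__(self) -> None:
        c = self.counts
        required = ["protein_id", "spectral_count", "protein_length"]
        missing = [col for col in required if col not in c.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        if c["protein_id"].duplicated().any():
            raise ValueError("duplicate protein_id")
        if (c["protein_length"] <= 0).any():
            raise ValueError("protein_length must be positive")
        if (c["spectral_count"] < 0).any():
            raise ValueError("negative spectral_count")


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene IDs drawn from one universe."""

    label: str
    ids: frozenset[str]

    @classmethod
    def from_iterable(cls, label: str, ids: Iterable[str]) -> "GeneSet":
        return cls(label, frozenset(ids))

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class SynthTruth:
    """Ground truth emitted alongside synthetic data, for recovery tests."""

    specific_genes: frozenset[str] = frozenset()
    de_genes_up: frozenset[str] = frozenset()
    de_genes_down: frozenset[str] = frozenset()
    bound_genes: dict[str, frozenset[str]] = field(default_factory=dict)
    complex_members: dict[str, frozenset[str]] = field(default_factory=dict)


@dataclass(frozen=True)
class CoverageTrack:
    """Per-chromosome tag counts in fixed-width bins.

    Built from reads extended 3'-ward to ``extension`` bp and binned at
    ``bin_size`` bp; a bin counts every extended read overlapping it.
    ``normalized`` marks tracks that have been divided by an input control
    (values are then ratios or log2 ratios, not counts).
    """

    bin_size: int
    bins: Mapping[str, np.ndarray]
    extension: int
    total_tags: float
    normalized: bool = False
    log2: bool = False

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be positive")

    def same_grid(self, other: "CoverageTrack") -> bool:
        if self.bin_size != other.bin_size:
            return False
        if set(self.bins) != set(other.bins):
            return False
        return all(len(self.bins[c]) == len(other.bins[c]) for c in self.bins)


@dataclass(frozen=True)
class DensityMatrix:
    """Row-per-region, column-per-bin density matrix around anchors.

    Rows are strand-oriented: downstream is always rightward, so minus-strand
    rows are reversed at extraction time. Bins falling off a chromosome edge
    hold NaN and are excluded from averages.
    """

    values: np.ndarray
    row_ids: list[str]
    flank: int
    bin_size: int
    normalization: str = "none"

    def __post_init__(self) -> None:
        expected = 2 * self.flank // self.bin_size
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise ValueError(
                f"expected {expected} columns for flank {self.flank} at "
                f"bin {self.bin_size}, got {self.values.shape}"
            )
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length mismatch")

    def mean_profile(self) -> np.ndarray:
        """Column means ignoring edge-padding NaNs."""
        return np.nanmean(self.values, axis=0)
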