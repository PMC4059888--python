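"""Peak-to-gene annotation and co-binding set algebra.

Each peak is assigned to exactly one feature class by the position of its
summit, with precedence promoter-TSS > gene body > intergenic. The promoter
window is strand-aware (default 1000 bp upstream to 100 bp downstream of the
TSS, the HOMER-style default). The gene body runs from TSS to TTS and
collapses exons, introns, UTRs and the TTS into a single class; sub-feature
labels are reported for information only. Gene-level binding calls and the
factor-specific / common partition build on these assignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .datatypes import GeneSet, GeneUniverse, PeakSet

PROMOTER = "promoter-TSS"
GENE_BODY = "gene-body"
INTERGENIC = "intergenic"


@dataclass(frozen=True)
class Windows:
    """Annotation window configuration.

    promoter_upstream / promoter_downstream
        Strand-aware promoter window extent around the TSS in bp. The
        window is ``[tss - upstream, tss + downstream]`` on the plus strand
        and mirrored on the minus strand.
    tss_flank
        Half-width of the density-extraction window around the TSS (used by
        the coverage module, kept here so one config describes a run).
    """

    promoter_upstream: int = 1000
    promoter_downstream: int = 100
    tss_flank: int = 2000

    def promoter_interval(self, tss: int, strand: str) -> tuple[int, int]:
        """Closed-open promoter interval for one gene."""
        if strand == "+":
            return tss - self.promoter_upstream, tss + self.promoter_downstream + 1
        return tss - self.promoter_downstream, tss + self.promoter_upstream + 1


@dataclass(frozen=True)
class AnnotationRecord:
    peak_index: int
    chrom: str
    summit: int
    assigned_gene_id: str | None
    feature_class: str
    sub_feature: str
    distance_to_tss: int | None


@dataclass(frozen=True)
class CategoryPartition:
    """Disjoint split of two bound-gene sets into only-A / common / only-B."""

    only_a: GeneSet
    common: GeneSet
    only_b: GeneSet

    @property
    def counts(self) -> dict[str, int]:
        return {
            self.only_a.label: len(self.only_a),
            self.common.label: len(self.common),
            self.only_b.label: len(self.only_b),
        }


class _GeneIndex:
    """Interval trees over promoter windows and gene bodies, per chromosome."""

    def __init__(self, universe: GeneUniverse, windows: Windows):
        self.universe = universe
        self.windows = windows
        self.promoters: dict[str, IntervalTree] = {}
        self.bodies: dict[str, IntervalTree] = {}
        g = universe.genes
        starts, ends = universe.starts_ends()
        for i, row in enumerate(g.itertuples(index=False)):
            ps, pe = windows.promoter_interval(row.tss, row.strand)
            size = universe.chrom_sizes[row.chrom]
            ps, pe = max(ps, 0), min(pe, size)
            ptree = self.promoters.setdefault(row.chrom, IntervalTree())
            if ps < pe:
                ptree.addi(ps, pe, i)
            btree = self.bodies.setdefault(row.chrom, IntervalTree())
            btree.addi(int(starts[i]), int(ends[i]), i)

    def query(self, chrom: str, pos: int, tree_map: dict[str, IntervalTree]) -> list[int]:
        tree = tree_map.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]


def _signed_tss_distance(pos: int, tss: int, strand: str) -> int:
    """Distance from TSS to ``pos``, positive downstream of transcription."""
    d = pos - tss
    return d if strand == "+" else -d


def _pick_nearest(candidates: list[int], pos: int, genes: pd.DataFrame) -> int:
    """Resolve multi-gene hits: nearest TSS, then smallest gene ID."""
    best = None
    for i in candidates:
        tss = genes["tss"].iat[i]
        key = (abs(pos - tss), genes["gene_id"].iat[i])
        if best is None or key < best[0]:
            best = (key, i)
    return best[1]


class PeakAnnotator:
    """Summit-based peak classifier against one gene universe.

    Builds the interval index once and reuses it across calls; the
    module-level functions construct a throwaway instance.
    """

    def __init__(self, universe: GeneUniverse, windows: Windows | None = None):
        self.windows = windows or Windows()
        self.universe = universe
        self._index = _GeneIndex(universe, self.windows)

    def classify(self, chrom: str, summit: int, peak_index: int = -1) -> AnnotationRecord:
        if chrom not in self.universe.chrom_sizes:
            raise KeyError(f"unknown chromosome: {chrom!r}")
        genes = self.universe.genes
        hits = self._index.query(chrom, summit, self._index.promoters)
        if hits:
            i = _pick_nearest(hits, summit, genes)
            return AnnotationRecord(
                peak_index, chrom, summit, genes["gene_id"].iat[i], PROMOTER, "TSS",
                _signed_tss_distance(summit, genes["tss"].iat[i], genes["strand"].iat[i]),
            )
        hits = self._index.query(chrom, summit, self._index.bodies)
        if hits:
            i = _pick_nearest(hits, summit, genes)
            sub = self._sub_feature(summit, i)
            return AnnotationRecord(
                peak_index, chrom, summit, genes["gene_id"].iat[i], GENE_BODY, sub,
                _signed_tss_distance(summit, genes["tss"].iat[i], genes["strand"].iat[i]),
            )
        return AnnotationRecord(peak_index, chrom, summit, None, INTERGENIC, "intergenic", None)

    def _sub_feature(self, pos: int, gene_idx: int) -> str:
        # Without an exon model the informational label distinguishes only
        # the TTS-proximal end of the body from its interior.
        genes = self.universe.genes
        tts = genes["tts"].iat[gene_idx]
        return "TTS" if abs(pos - tts) <= 500 else "intron"

    def annotate(self, peaks: PeakSet) -> tuple[list[AnnotationRecord], dict]:
        records = [
            self.classify(row.chrom, row.summit, i)
            for i, row in enumerate(peaks.peaks.itertuples(index=False))
        ]
        n = len(records)
        summary = {"n_peaks": n}
        for cls in (PROMOTER, GENE_BODY, INTERGENIC):
            count = sum(r.feature_class == cls for r in records)
            summary[cls] = count / n if n else 0.0
        return records, summary

    def bound_genes(self, peaks: PeakSet, label: str | None = None) -> GeneSet:
        """Genes with >= 1 summit in their promoter window or gene body."""
        records, _ = self.annotate(peaks)
        ids = {r.assigned_gene_id for r in records if r.assigned_gene_id is not None}
        return GeneSet.from_iterable(label or peaks.factor_name, ids)


def classify_peak(
    peak_row, universe: GeneUniverse, windows: Windows | None = None
) -> AnnotationRecord:
    """Classify one peak (any object with chrom/summit attributes)."""
    return PeakAnnotator(universe, windows).classify(peak_row.chrom, peak_row.summit)


def annotate_peaks(
    peaks: PeakSet, universe: GeneUniverse, windows: Windows | None = None
) -> tuple[list[AnnotationRecord], dict]:
    """Annotate every peak; returns records and feature-fraction summary."""
    return PeakAnnotator(universe, windows).annotate(peaks)


def call_bound_genes(
    peaks: PeakSet, universe: GeneUniverse, windows: Windows | None = None
) -> GeneSet:
    return PeakAnnotator(universe, windows).bound_genes(peaks)


def partition_categories(
    set_a: GeneSet, set_b: GeneSet, universe_ids: Iterable[str] | None = None
) -> CategoryPartition:
    """Exact Venn split of two bound-gene sets.

    Satisfies |only_A| + |only_B| + 2|common| = |A| + |B|.
    """
    if universe_ids is not None:
        pool = set(universe_ids)
        offenders = sorted((set_a.ids | set_b.ids) - pool)
        if offenders:
            raise ValueError(f"IDs outside universe: {offenders[:10]}")
    common = set_a.ids & set_b.ids
    return CategoryPartition(
        only_a=GeneSet(f"only_{set_a.label}", frozenset(set_a.ids - common)),
        common=GeneSet("common", frozenset(common)),
        only_b=GeneSet(f"only_{set_b.label}", frozenset(set_b.ids - common)),
    )


def records_to_frame(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Flatten annotation records for TSV export."""
    return pd.DataFrame(
        {
            "peak_index": [r.peak_index for r in records],
            "chrom": [r.chrom for r in records],
            "summit": [r.summit for r in records],
            "gene_id": [r.assigned_gene_id or "." for r in records],
            "feature_class": [r.feature_class for r in records],
            "sub_feature": [r.sub_feature for r in records],
            "distance_to_tss": [r.distance_to_tss if r.distance_to_tss is not None else np.nan for r in records],
        }
    )
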