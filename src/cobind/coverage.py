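"""Binned coverage, input normalization, TSS/metagene profiles and clustering.

Reads are extended 3'-ward to a fixed fragment length (default 200 bp) and
counted into fixed-width bins (default 25 bp); density matrices are
extracted strand-aware around TSSs or peak summits, optionally normalized
to an input (control) track after library-size scaling, and clustered with
k-means on per-matrix unit-mean-scaled features (seqMINER-style linear
scaling). Bivalent sites are called by thresholding mean window density of
the active (H3K4me3) and repressive (H3K27me3, Ezh2) marks jointly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .datatypes import CoverageTrack, DensityMatrix, GeneUniverse, PeakSet, ReadSet


def build_coverage(
    reads: ReadSet,
    chrom_sizes: Mapping[str, int],
    extension: int = 200,
    bin_size: int = 25,
) -> CoverageTrack:
    """Bin extended reads into per-chromosome count vectors.

    Each read is extended from its 5' position ``extension`` bp in the 3'
    direction (rightward for '+', leftward for '-'), truncated at
    chromosome ends; every bin the extended read overlaps is incremented.
    """
    if extension < reads.read_length:
        raise ValueError("extension must be >= read length")
    bins: dict[str, np.ndarray] = {
        c: np.zeros(int(np.ceil(size / bin_size)), dtype=np.float64)
        for c, size in chrom_sizes.items()
    }
    df = reads.reads
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in chrom_sizes:
            raise ValueError(f"read on unknown chromosome {chrom!r}")
        size = chrom_sizes[chrom]
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if (pos < 0).any() or (pos >= size).any():
            bad = sub.index[(pos < 0) | (pos >= size)][0]
            raise ValueError(f"read at index {bad} beyond {chrom} bounds")
        plus = (sub["strand"] == "+").to_numpy()
        start = np.where(plus, pos, pos - extension + 1)
        end = np.where(plus, pos + extension, pos + 1)
        start = np.clip(start, 0, size)
        end = np.clip(end, 0, size)
        b0 = start // bin_size
        b1 = (end - 1) // bin_size  # inclusive last bin
        vec = bins[chrom]
        # extended reads span at most ceil(ext/bin)+1 bins; loop over offsets
        max_span = int((b1 - b0).max()) + 1 if len(b0) else 0
        for off in range(max_span):
            sel = b0 + off <= b1
            np.add.at(vec, (b0[sel] + off), 1.0)
    total = float(sum(v.sum() for v in bins.values()))
    return CoverageTrack(
        bin_size=bin_size, bins=bins, extension=extension, total_tags=total
    )


def normalize_to_input(
    track: CoverageTrack,
    input_track: CoverageTrack,
    pseudocount: float = 1.0,
    log2: bool = False,
) -> CoverageTrack:
    """Per-bin IP / input ratio after library-size scaling.

    The input is scaled by ``s = total_ip / total_input`` so both tracks
    carry equal total tags, then each bin becomes
    ``(ip + pseudocount) / (s * input + pseudocount)``, optionally log2.
    """
    if not track.same_grid(input_track):
        raise ValueError("bin grids differ between IP and input tracks")
    if input_track.total_tags <= 0:
        raise ValueError("input track has no tags")
    s = track.total_tags / input_track.total_tags
    out: dict[str, np.ndarray] = {}
    for chrom, ip in track.bins.items():
        ratio = (ip + pseudocount) / (input_track.bins[chrom] * s + pseudocount)
        out[chrom] = np.log2(ratio) if log2 else ratio
    return CoverageTrack(
        bin_size=track.bin_size,
        bins=out,
        extension=track.extension,
        total_tags=track.total_tags,
        normalized=True,
        log2=log2,
    )


def _extract_window(
    track: CoverageTrack, chrom: str, center: int, flank: int
) -> np.ndarray:
    """Strand-agnostic window of bins around ``center``; NaN off the edge."""
    b = track.bin_size
    n_cols = 2 * flank // b
    vec = track.bins[chrom]
    c_bin = center // b
    lo = c_bin - flank // b
    row = np.full(n_cols, np.nan)
    src_lo = max(lo, 0)
    src_hi = min(lo + n_cols, len(vec))
    if src_hi > src_lo:
        row[src_lo - lo : src_hi - lo] = vec[src_lo:src_hi]
    return row


def tss_matrix(
    track: CoverageTrack, universe: GeneUniverse, flank: int = 2000
) -> DensityMatrix:
    """Density around each gene's TSS, strand-oriented (downstream right)."""
    if flank % track.bin_size:
        raise ValueError("flank must be a multiple of the bin size")
    rows, ids = [], []
    for row in universe.genes.itertuples(index=False):
        vals = _extract_window(track, row.chrom, row.tss, flank)
        if row.strand == "-":
            vals = vals[::-1]
        rows.append(vals)
        ids.append(row.gene_id)
    return DensityMatrix(
        values=np.vstack(rows),
        row_ids=ids,
        flank=flank,
        bin_size=track.bin_size,
        normalization="input" if track.normalized else "none",
    )


def peak_matrix(
    track: CoverageTrack, peaks: PeakSet, flank: int = 2000
) -> DensityMatrix:
    """Density around each peak summit (unstranded anchors)."""
    if flank % track.bin_size:
        raise ValueError("flank must be a multiple of the bin size")
    rows, ids = [], []
    for i, row in enumerate(peaks.peaks.itertuples(index=False)):
        rows.append(_extract_window(track, row.chrom, row.summit, flank))
        ids.append(f"{peaks.factor_name}_peak{i}")
    return DensityMatrix(
        values=np.vstack(rows),
        row_ids=ids,
        flank=flank,
        bin_size=track.bin_size,
        normalization="input" if track.normalized else "none",
    )


def metagene_profile(
    track: CoverageTrack,
    universe: GeneUniverse,
    up: int = 1000,
    down: int = 1000,
    gb_bins: int = 40,
) -> np.ndarray:
    """Average profile over upstream flank, length-scaled gene body, downstream flank.

    The gene body is linearly rescaled to ``gb_bins`` columns by
    interpolation so genes of different lengths contribute comparably;
    flanks stay in native bins. NaN (off-chromosome) bins are excluded from
    the average.
    """
    b = track.bin_size
    profiles = []
    for row in universe.genes.itertuples(index=False):
        vec = track.bins[row.chrom]
        g_start, g_end = sorted((row.tss, row.tts))
        g_end += 1
        if g_end - g_start <= 2 * b:
            continue
        body = vec[g_start // b : max(g_start // b + 1, (g_end - 1) // b + 1)]
        x_old = np.linspace(0.0, 1.0, len(body))
        x_new = np.linspace(0.0, 1.0, gb_bins)
        body_scaled = np.interp(x_new, x_old, body)
        # genomic-left flank is upstream for '+' genes, downstream for '-'
        left_w = up if row.strand == "+" else down
        right_w = down if row.strand == "+" else up
        left = (
            _extract_window(track, row.chrom, g_start, left_w)[: left_w // b]
            if left_w
            else np.array([])
        )
        right = (
            _extract_window(track, row.chrom, g_end, right_w)[right_w // b :]
            if right_w
            else np.array([])
        )
        prof = np.concatenate([left, body_scaled, right])
        if row.strand == "-":
            prof = prof[::-1]
        profiles.append(prof)
    if not profiles:
        raise ValueError("no gene longer than two bins")
    return np.nanmean(np.vstack(profiles), axis=0)


@dataclass(frozen=True)
class ClusterAssignment:
    labels: np.ndarray  # 1..k per row
    k: int
    seed: int
    cluster_profiles: np.ndarray  # k x features mean profile
    row_ids: list[str]


class DensityKMeans:
    """k-means over concatenated, unit-mean-scaled density matrices.

    sklearn-style estimator: ``fit`` computes ``labels_`` (1..k, renumbered
    so cluster 1 has the highest mean signal) and ``cluster_profiles_``.
    Scaling each matrix to unit mean before concatenation mirrors the
    linear normalization used by seqMINER-style heatmap tools, letting
    marks of different depth contribute comparably.
    """

    def __init__(self, k: int = 5, seed: int = 0, n_init: int = 10, max_iter: int = 300):
        self.k = k
        self.seed = seed
        self.n_init = n_init
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "seed": self.seed, "n_init": self.n_init, "max_iter": self.max_iter}

    def set_params(self, **params) -> "DensityKMeans":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    @staticmethod
    def _features(matrices: Sequence[DensityMatrix]) -> np.ndarray:
        n_rows = matrices[0].values.shape[0]
        blocks = []
        for m in matrices:
            if m.values.shape[0] != n_rows:
                raise ValueError("matrices must be row-aligned")
            x = np.nan_to_num(m.values, nan=0.0)
            mu = x.mean()
            blocks.append(x / mu if mu > 0 else x)
        return np.hstack(blocks)

    def fit(self, matrices: Sequence[DensityMatrix]) -> "DensityKMeans":
        if self.k < 1:
            raise ValueError("k must be >= 1")
        x = self._features(matrices)
        if self.k > x.shape[0]:
            raise ValueError(f"k={self.k} exceeds number of rows {x.shape[0]}")
        km = KMeans(n_clusters=self.k, random_state=self.seed, n_init=self.n_init, max_iter=self.max_iter)
        raw = km.fit_predict(x)
        # renumber labels by decreasing cluster mean signal
        means = np.array([x[raw == c].mean() if (raw == c).any() else -np.inf for c in range(self.k)])
        order = np.argsort(-means)
        remap = np.empty(self.k, dtype=int)
        remap[order] = np.arange(1, self.k + 1)
        self.labels_ = remap[raw]
        self.cluster_profiles_ = np.vstack(
            [x[self.labels_ == c].mean(axis=0) if (self.labels_ == c).any() else np.zeros(x.shape[1]) for c in range(1, self.k + 1)]
        )
        self.inertia_ = float(km.inertia_)
        self.row_ids_ = list(matrices[0].row_ids)
        return self

    def assignment(self) -> ClusterAssignment:
        return ClusterAssignment(
            labels=self.labels_,
            k=self.k,
            seed=self.seed,
            cluster_profiles=self.cluster_profiles_,
            row_ids=self.row_ids_,
        )


def kmeans_cluster(
    matrices: Sequence[DensityMatrix], k: int, seed: int = 0
) -> ClusterAssignment:
    """Cluster row-aligned density matrices; labels 1..k by decreasing signal."""
    return DensityKMeans(k=k, seed=seed).fit(matrices).assignment()


def peak_density_correlation(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    regions: PeakSet,
    input_track: CoverageTrack | None = None,
    pseudocount: float = 1.0,
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of per-region log2 densities of two tracks.

    Each region's density is the mean bin value over the peak interval; if
    an input track is given both tracks are input-normalized first, and the
    per-region log2 ratio is correlated.
    """
    if input_track is not None:
        track_a = normalize_to_input(track_a, input_track, pseudocount, log2=True)
        track_b = normalize_to_input(track_b, input_track, pseudocount, log2=True)
    vals_a, vals_b = [], []
    b = track_a.bin_size
    for row in regions.peaks.itertuples(index=False):
        lo, hi = row.start // b, (row.end - 1) // b + 1
        vals_a.append(float(np.mean(track_a.bins[row.chrom][lo:hi])))
        vals_b.append(float(np.mean(track_b.bins[row.chrom][lo:hi])))
    a = np.asarray(vals_a)
    bb = np.asarray(vals_b)
    ok = np.isfinite(a) & np.isfinite(bb)
    if ok.sum() < 3:
        raise ValueError("need >= 3 regions with finite densities")
    if a[ok].std() == 0 or bb[ok].std() == 0:
        raise ValueError("constant vector")
    r, p = stats.pearsonr(a[ok], bb[ok])
    pairs = pd.DataFrame({"density_a": a, "density_b": bb})
    return float(r), float(p), pairs


def call_bivalent_sites(
    mark_matrices: Mapping[str, DensityMatrix],
    threshold: float,
    required_marks: Sequence[str] = ("H3K4me3", "H3K27me3", "Ezh2"),
    factor_matrices: Mapping[str, DensityMatrix] | None = None,
    factor_threshold: float | None = None,
) -> pd.DataFrame:
    """Flag bivalent sites and their co-occurrence with factor binding.

    A site is bivalent iff the mean density over the window is at least
    ``threshold`` for every mark in ``required_marks`` (active H3K4me3 plus
    repressive H3K27me3 and Ezh2 jointly). Factor matrices, when given, add
    boolean columns at ``factor_threshold`` (default: same threshold) so
    counts like "bivalent and bound by factor A only" can be tabulated.
    """
    missing = [m for m in required_marks if m not in mark_matrices]
    if missing:
        raise ValueError(f"missing mark matrices: {missing}")
    first = mark_matrices[required_marks[0]]
    n = first.values.shape[0]
    out = pd.DataFrame(index=pd.Index(first.row_ids, name="site"))
    flags = np.ones(n, dtype=bool)
    for mark in required_marks:
        m = mark_matrices[mark]
        if m.values.shape[0] != n:
            raise ValueError("mark matrices must be row-aligned")
        mean_density = np.nanmean(m.values, axis=1)
        out[f"{mark}_mean"] = mean_density
        flags &= mean_density >= threshold
    out["bivalent"] = flags
    if factor_matrices:
        ft = factor_threshold if factor_threshold is not None else threshold
        for name, m in factor_matrices.items():
            if m.values.shape[0] != n:
                raise ValueError("factor matrices must be row-aligned")
            out[f"{name}_bound"] = np.nanmean(m.values, axis=1) >= ft
    return out
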