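"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates, at desk scale, the structure of a two-factor
chromatin study in mouse embryonic stem cells: a gene universe of ~26,460
IDs, factor peak sets with controllable promoter / gene-body / intergenic
proportions (one factor promoter-biased at ~67%, the other gene-body-biased
at ~74%), extended-read coverage with factor-specific TSS profile shapes,
two-condition replicated expression with planted condition-specific and
differentially expressed genes, and IP vs MOCK spectral counts for defined
protein complexes. Every operation takes an explicit seed and draws from
its own numpy Generator; fixed seed means byte-identical output.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Windows, _GeneIndex, _pick_nearest
from .datatypes import (
    ExpressionTable,
    GeneUniverse,
    PeakSet,
    ReadSet,
    SpectralCountTable,
    SynthTruth,
)

DEFAULT_CHROM_SIZES: dict[str, int] = {"chr1": 50_000_000, "chr2": 50_000_000, "chr3": 50_000_000}

#: Feature mixes matching the two factors' published genomic distributions:
#: the promoter-biased factor (67% promoter) and the gene-body-biased one
#: (74% gene body), each with ~10% intergenic.
NSL_LIKE_MIX = (0.67, 0.23, 0.10)
MSL_LIKE_MIX = (0.16, 0.74, 0.10)


def simulate_gene_universe(
    n_genes: int = 26_460,
    chrom_sizes: Mapping[str, int] | None = None,
    min_gene_len: int = 2_000,
    max_gene_len: int = 100_000,
    seed: int = 0,
) -> GeneUniverse:
    """Place ``n_genes`` non-overlapping genes on synthetic chromosomes.

    Gene lengths are log-uniform on [min_gene_len, max_gene_len]; genes are
    assigned to chromosomes proportionally to length capacity and separated
    by random gaps (stick-breaking over the leftover space). Strands are
    drawn independently with probability 1/2.

    Raises
    ------
    ValueError
        If the chromosomes cannot host the requested genes ("cannot place
        genes").
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    chrom_sizes = dict(chrom_sizes or DEFAULT_CHROM_SIZES)
    rng = np.random.default_rng(seed)

    lengths = np.exp(
        rng.uniform(np.log(min_gene_len), np.log(max_gene_len), size=n_genes)
    ).astype(np.int64)

    chroms = list(chrom_sizes)
    capacity = np.array([chrom_sizes[c] for c in chroms], dtype=np.float64)
    # Deterministic proportional allocation of gene counts to chromosomes.
    quota = np.floor(capacity / capacity.sum() * n_genes).astype(int)
    for i in range(n_genes - quota.sum()):
        quota[i % len(chroms)] += 1

    order = rng.permutation(n_genes)
    rows: list[tuple[str, int, int, int]] = []  # chrom, start, end (half-open)
    cursor = 0
    for ci, chrom in enumerate(chroms):
        k = quota[ci]
        idx = order[cursor : cursor + k]
        cursor += k
        if k == 0:
            continue
        occupied = int(lengths[idx].sum())
        slack = chrom_sizes[chrom] - occupied
        if slack < 0:
            raise ValueError(
                f"cannot place genes: {chrom} needs {occupied} bp for {k} genes "
                f"but is {chrom_sizes[chrom]} bp"
            )
        # k+1 gaps summing to the slack, via ordered uniform breakpoints.
        breaks = np.sort(rng.integers(0, slack + 1, size=k))
        gaps = np.diff(np.concatenate([[0], breaks]))
        pos = 0
        for j, gi in enumerate(idx):
            pos += int(gaps[j])
            rows.append((chrom, pos, pos + int(lengths[gi]), gi))
            pos += int(lengths[gi])

    strands = rng.choice(["+", "-"], size=n_genes)
    width = len(str(n_genes))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "gi"])
    table["strand"] = strands[table["gi"].to_numpy()]
    plus = table["strand"] == "+"
    table["tss"] = np.where(plus, table["start"], table["end"] - 1)
    table["tts"] = np.where(plus, table["end"] - 1, table["start"])
    table["gene_id"] = [f"GENE{g:0{width}d}" for g in table["gi"]]
    table = table.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return GeneUniverse(
        genes=table[["gene_id", "chrom", "strand", "tss", "tts"]], chrom_sizes=chrom_sizes
    )


def _sample_outside(
    rng: np.random.Generator,
    index: _GeneIndex,
    chrom_sizes: Mapping[str, int],
    n: int,
    max_tries: int = 200,
) -> list[tuple[str, int]]:
    """Rejection-sample positions outside all gene bodies and promoter windows."""
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out: list[tuple[str, int]] = []
    for _ in range(n):
        for attempt in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            pos = int(rng.integers(0, chrom_sizes[chrom]))
            if not index.query(chrom, pos, index.bodies) and not index.query(
                chrom, pos, index.promoters
            ):
                out.append((chrom, pos))
                break
        else:
            raise ValueError("infeasible feature mix: no intergenic space found")
    return out


def simulate_binding_peaks(
    universe: GeneUniverse,
    n_peaks: int = 2_000,
    feature_mix: tuple[float, float, float] = MSL_LIKE_MIX,
    width_model: tuple[float, float] = (500.0, 150.0),
    seed: int = 0,
    windows: Windows | None = None,
    factor_name: str = "factor",
) -> tuple[PeakSet, SynthTruth]:
    """Generate a peak set whose summits hit the requested feature mix.

    ``feature_mix`` is (promoter, gene_body, intergenic) fractions summing
    to 1. Promoter and gene-body summits are placed strand-aware inside the
    window the annotation module uses, so re-annotation under the same
    ``windows`` recovers the mix within binomial sampling error. The truth
    object lists the targeted genes per factor.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if abs(sum(feature_mix) - 1.0) > 1e-9:
        raise ValueError("feature_mix must sum to 1")
    windows = windows or Windows()
    rng = np.random.default_rng(seed)
    index = _GeneIndex(universe, windows)
    genes = universe.genes
    n_genes = len(genes)
    starts, ends = universe.starts_ends()

    # exact largest-remainder allocation of peak counts to classes, then a
    # random interleaving: the realized mix equals the request up to rounding
    mix = np.asarray(feature_mix, dtype=float)
    counts = np.floor(mix * n_peaks).astype(int)
    remainder = mix * n_peaks - counts
    for extra in np.argsort(-remainder)[: n_peaks - counts.sum()]:
        counts[extra] += 1
    classes = rng.permuted(np.repeat(np.arange(3), counts))

    summits: list[tuple[str, int]] = []
    target_gene: list[str | None] = []
    intergenic_needed = int((classes == 2).sum())
    intergenic_pool = iter(_sample_outside(rng, index, universe.chrom_sizes, intergenic_needed))
    for cls in classes:
        if cls == 0:  # promoter
            for _ in range(200):
                i = int(rng.integers(0, n_genes))
                ps, pe = windows.promoter_interval(genes["tss"].iat[i], genes["strand"].iat[i])
                ps = max(ps, 0)
                pe = min(pe, universe.chrom_sizes[genes["chrom"].iat[i]])
                pos = int(rng.integers(ps, pe))
                hit = index.query(genes["chrom"].iat[i], pos, index.promoters)
                if hit:
                    summits.append((genes["chrom"].iat[i], pos))
                    # neighbouring promoter windows can overlap; the truth
                    # records the gene the annotation rule will assign
                    winner = _pick_nearest(hit, pos, genes)
                    target_gene.append(genes["gene_id"].iat[winner])
                    break
            else:  # pragma: no cover - windows always non-empty after clipping
                raise ValueError("infeasible feature mix: no promoter space")
        elif cls == 1:  # gene body, outside any promoter window
            for _ in range(200):
                i = int(rng.integers(0, n_genes))
                pos = int(rng.integers(starts[i], ends[i]))
                if not index.query(genes["chrom"].iat[i], pos, index.promoters):
                    summits.append((genes["chrom"].iat[i], pos))
                    target_gene.append(genes["gene_id"].iat[i])
                    break
            else:
                raise ValueError("infeasible feature mix: gene bodies fully covered by promoters")
        else:
            summits.append(next(intergenic_pool))
            target_gene.append(None)

    widths = np.clip(
        rng.normal(width_model[0], width_model[1], size=n_peaks), 50, None
    ).astype(np.int64)
    chrom = [c for c, _ in summits]
    summit = np.array([p for _, p in summits], dtype=np.int64)
    size = np.array([universe.chrom_sizes[c] for c in chrom], dtype=np.int64)
    start = np.maximum(summit - widths // 2, 0)
    end = np.minimum(start + widths, size)
    start = np.minimum(start, summit)  # keep summit inside after clipping
    end = np.maximum(end, summit + 1)

    peaks = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "summit": summit,
            "tag_density": rng.lognormal(mean=2.5, sigma=0.6, size=n_peaks),
            "score": rng.exponential(scale=20.0, size=n_peaks) + 5.0,
        }
    )
    truth = SynthTruth(
        bound_genes={factor_name: frozenset(g for g in target_gene if g is not None)}
    )
    return PeakSet(factor_name=factor_name, peaks=peaks), truth


def simulate_reads(
    peaks: PeakSet,
    reads_per_peak: int,
    background_rate: float = 0.0,
    profile_shape: str = "point",
    seed: int = 0,
    chrom_sizes: Mapping[str, int] | None = None,
    strands: Sequence[str] | None = None,
    read_length: int = 50,
    extension: int = 200,
    point_sd: float = 50.0,
    spread_scale: float = 500.0,
) -> ReadSet:
    """Simulate single-end read 5' positions around peak summits.

    ``point`` concentrates extended-read centres on the summit (truncated
    normal within the peak); ``downstream_spread`` pushes centres
    exponentially downstream of the summit along ``strands`` (per-peak, '+'
    by default), emulating a factor that trails into gene bodies. Background
    reads are uniform with Poisson counts at ``background_rate`` reads/bp.
    """
    if background_rate < 0 or reads_per_peak < 0:
        raise ValueError("rates must be >= 0")
    if profile_shape not in ("point", "downstream_spread"):
        raise ValueError(f"unknown profile_shape: {profile_shape!r}")
    if chrom_sizes is None:
        raise ValueError("chrom_sizes is required")
    rng = np.random.default_rng(seed)
    table = peaks.peaks
    if strands is None:
        strands = ["+"] * len(table)

    frames = []
    if reads_per_peak > 0:
        chroms: list[str] = []
        pos: list[np.ndarray] = []
        all_strands: list[np.ndarray] = []
        for i, row in enumerate(table.itertuples(index=False)):
            if profile_shape == "point":
                centers = rng.normal(row.summit, point_sd, size=reads_per_peak)
                centers = np.clip(centers, row.start, row.end - 1)
            else:
                offs = rng.exponential(spread_scale, size=reads_per_peak)
                sign = 1 if strands[i] == "+" else -1
                centers = row.summit + sign * offs
            read_strand = rng.choice(["+", "-"], size=reads_per_peak)
            p5 = np.where(
                read_strand == "+", centers - extension // 2, centers + extension // 2
            )
            p5 = np.clip(p5, 0, chrom_sizes[row.chrom] - 1).astype(np.int64)
            chroms.extend([row.chrom] * reads_per_peak)
            pos.append(p5)
            all_strands.append(read_strand)
        if pos:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chroms,
                        "pos": np.concatenate(pos),
                        "strand": np.concatenate(all_strands),
                    }
                )
            )
    if background_rate > 0:
        for chrom, size in chrom_sizes.items():
            n_bg = rng.poisson(background_rate * size)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": rng.integers(0, size, size=n_bg),
                        "strand": rng.choice(["+", "-"], size=n_bg),
                    }
                )
            )
    reads = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame({"chrom": [], "pos": [], "strand": []})
    )
    return ReadSet(reads=reads, read_length=read_length)


def simulate_expression(
    universe: GeneUniverse,
    n_replicates: int = 3,
    n_specific: int = 282,
    n_de: int = 0,
    effect_log2fc: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    baseline_log2_mean: float = 3.0,
    baseline_log2_sd: float = 2.0,
    specific_floor: float = 2.0,
) -> tuple[ExpressionTable, SynthTruth]:
    """Two-condition replicated expression with planted structure.

    Planted condition-specific genes are expressed at or above
    ``specific_floor`` in the test condition and exactly zero in control
    (before noise; multiplicative noise preserves zeros). Planted DE genes
    are shifted by ``effect_log2fc`` log2 units in the test condition
    (upward if positive). Noise is log-normal with sd ``noise_sd`` in log2
    units, applied per measurement.
    """
    if n_specific + n_de > universe.size:
        raise ValueError("n_specific + n_de exceeds universe size")
    rng = np.random.default_rng(seed)
    ids = universe.genes["gene_id"].to_numpy()
    n = len(ids)

    baseline = 2.0 ** rng.normal(baseline_log2_mean, baseline_log2_sd, size=n)
    chosen = rng.choice(n, size=n_specific + n_de, replace=False)
    specific_idx = chosen[:n_specific]
    de_idx = chosen[n_specific:]

    test_mean = baseline.copy()
    ctrl_mean = baseline.copy()
    ctrl_mean[specific_idx] = 0.0
    test_mean[specific_idx] = np.maximum(test_mean[specific_idx], specific_floor)
    test_mean[de_idx] *= 2.0 ** effect_log2fc

    cols, data = [], []
    for cond, mean in (("test", test_mean), ("control", ctrl_mean)):
        for r in range(1, n_replicates + 1):
            noise = 2.0 ** rng.normal(0.0, noise_sd, size=n)
            data.append(mean * noise)
            cols.append(f"{cond}_{r}")
    values = pd.DataFrame(np.column_stack(data), index=pd.Index(ids, name="gene_id"), columns=cols)
    samples = pd.DataFrame(
        {
            "condition": [c.rsplit("_", 1)[0] for c in cols],
            "replicate": [int(c.rsplit("_", 1)[1]) for c in cols],
        },
        index=pd.Index(cols, name="sample"),
    )
    direction_up = effect_log2fc >= 0
    truth = SynthTruth(
        specific_genes=frozenset(ids[specific_idx]),
        de_genes_up=frozenset(ids[de_idx]) if direction_up else frozenset(),
        de_genes_down=frozenset() if direction_up else frozenset(ids[de_idx]),
    )
    return ExpressionTable(values=values, samples=samples, unit="FPKM"), truth


def simulate_spectral_counts(
    complexes: Mapping[str, Mapping[str, int]],
    bait: str,
    depth: int = 2_000,
    mock_contamination: float = 0.05,
    seed: int = 0,
    mock_depth: int | None = None,
) -> tuple[SpectralCountTable, SpectralCountTable]:
    """IP vs MOCK spectral-count draws for defined protein complexes.

    The bait's complex members receive IP counts multinomially with weight
    proportional to protein length (equal molar abundance of an intact
    complex). Proteins of the other complexes act as background binders:
    they enter the IP draw down-weighted by ``mock_contamination`` and make
    up the MOCK run entirely, so genuine members are absent from MOCK and
    contaminants show comparable abundance in both runs.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    owners = [name for name, members in complexes.items() if bait in members]
    if len(owners) != 1:
        raise ValueError(f"bait {bait!r} must belong to exactly one complex, found {owners}")
    rng = np.random.default_rng(seed)
    members = dict(complexes[owners[0]])
    contaminants = {
        prot: length
        for name, mem in complexes.items()
        if name != owners[0]
        for prot, length in mem.items()
        if prot not in members
    }

    ip_ids = list(members) + list(contaminants)
    ip_w = np.array(
        [members[p] for p in members]
        + [mock_contamination * contaminants[p] for p in contaminants],
        dtype=float,
    )
    ip_counts = np.zeros(len(ip_ids), dtype=np.int64)
    if ip_w.sum() > 0:
        ip_counts = rng.multinomial(depth, ip_w / ip_w.sum())
    lengths = np.array([members.get(p) or contaminants[p] for p in ip_ids])
    ip = pd.DataFrame(
        {"protein_id": ip_ids, "spectral_count": ip_counts, "protein_length": lengths}
    )
    ip = ip[ip["spectral_count"] > 0].reset_index(drop=True)

    mock_ids = list(contaminants)
    if mock_ids:
        w = np.array([contaminants[p] for p in mock_ids], dtype=float)
        mock_counts = rng.multinomial(mock_depth or depth, w / w.sum())
    else:
        mock_counts = np.array([], dtype=np.int64)
    mock = pd.DataFrame(
        {
            "protein_id": mock_ids,
            "spectral_count": mock_counts,
            "protein_length": [contaminants[p] for p in mock_ids],
        }
    )
    mock = mock[mock["spectral_count"] > 0].reset_index(drop=True)
    return SpectralCountTable(ip), SpectralCountTable(mock)
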