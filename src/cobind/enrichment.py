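"""Bootstrap gene-set overlap null with an analytic hypergeometric twin.

The procedure: draw ``n_draw`` distinct gene IDs uniformly without
replacement from a universe of ``N`` IDs, count how many fall in a fixed
interest list of ``K`` IDs, and repeat ``n_iter`` times. The empirical mean
and sd of the overlap define the null; the observed count enters as

    z = (mean - expect) / sd

so z is negative for enrichment — the magnitude |z| is what gets reported.
Because each draw is uniform without replacement, the overlap is exactly
hypergeometric, so the closed-form moments

    mean = n K / N,   sd^2 = n (K/N)(1 - K/N)(N - n)/(N - 1)

serve as an independent oracle for the simulation. p-values come from the
standard-normal tail of |z| (the empirical histogram of 10^4-10^5 draws
cannot resolve tail probabilities like 1e-90; the parametric tail can).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import CategoryPartition
from .datatypes import GeneSet

DEFAULT_N_ITER = 10_000


@dataclass(frozen=True)
class HypergeomMoments:
    """Closed-form mean and sd of the draw-overlap distribution."""

    mean: float
    sd: float


@dataclass(frozen=True)
class BootstrapResult:
    """Empirical overlap null for one interest list, plus significance.

    ``mean``/``sd`` are the empirical moments over ``n_iter`` draws
    (sd with denominator n_iter - 1); ``histogram`` maps overlap count to
    frequency. ``z``, ``abs_z`` and ``p_value`` are attached against an
    observed count by :func:`attach_significance`.
    """

    n_iter: int
    n_draw: int
    pool_size: int
    interest_size: int
    mean: float
    sd: float
    histogram: dict[int, int]
    seed: int
    expect: int | None = None
    z: float | None = None
    abs_z: float | None = None
    p_value: float | None = None
    sided: str | None = None


def hypergeometric_moments(N: int, K: int, n: int) -> HypergeomMoments:
    """Mean and sd of overlap when drawing n of N with K marked.

    Wraps :data:`scipy.stats.hypergeom`; kept as the single source of the
    closed form so the bootstrap can be checked against it.
    """
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if N == 0:
        return HypergeomMoments(0.0, 0.0)
    mean, var = stats.hypergeom.stats(N, K, n, moments="mv")
    return HypergeomMoments(float(mean), float(np.sqrt(var)))


def bootstrap_overlap(
    universe_ids: Sequence[str] | int,
    interest: GeneSet | Iterable[str],
    n_draw: int,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> BootstrapResult:
    """Simulate the overlap null by repeated without-replacement draws.

    ``universe_ids`` may be the ID sequence itself or just the pool size N
    (IDs are then implicit integers); the interest list must be a subset of
    the universe. Each iteration draws ``n_draw`` distinct IDs uniformly and
    records the intersection size with the interest list.
    """
    if isinstance(universe_ids, (int, np.integer)):
        N = int(universe_ids)
        if isinstance(interest, GeneSet):
            raise ValueError("with an integer universe, pass interest as a size or index list")
        interest_idx = np.asarray(list(interest), dtype=np.int64)
        if interest_idx.size and (interest_idx.min() < 0 or interest_idx.max() >= N):
            raise ValueError("interest indices outside universe")
    else:
        ids = list(universe_ids)
        N = len(ids)
        id_pos = {g: i for i, g in enumerate(ids)}
        members = interest.ids if isinstance(interest, GeneSet) else set(interest)
        missing = [g for g in members if g not in id_pos]
        if missing:
            raise ValueError(f"interest IDs outside universe: {sorted(missing)[:10]}")
        interest_idx = np.fromiter((id_pos[g] for g in members), dtype=np.int64)
    if n_draw > N:
        raise ValueError(f"n_draw={n_draw} exceeds universe size {N}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    K = int(interest_idx.size)
    mask = np.zeros(N, dtype=bool)
    mask[interest_idx] = True
    rng = np.random.default_rng(seed)
    overlaps = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        draw = rng.choice(N, size=n_draw, replace=False)
        overlaps[i] = int(mask[draw].sum())

    values, freqs = np.unique(overlaps, return_counts=True)
    sd = float(overlaps.std(ddof=1)) if n_iter > 1 else 0.0
    return BootstrapResult(
        n_iter=n_iter,
        n_draw=n_draw,
        pool_size=N,
        interest_size=K,
        mean=float(overlaps.mean()),
        sd=sd,
        histogram={int(v): int(f) for v, f in zip(values, freqs)},
        seed=seed,
    )


def attach_significance(
    result: BootstrapResult, expect: int, sided: str = "enrichment"
) -> BootstrapResult:
    """Attach z = (mean - expect)/sd and its normal-tail p-value.

    ``expect`` is the observed (experimentally determined) interest count.
    The signed z is negative when the observation exceeds the null mean;
    ``abs_z`` carries the magnitude conventionally reported. One-sided
    p-values integrate the standard-normal tail beyond |z|; two-sided
    doubles it, capped at 1.
    """
    if sided not in ("enrichment", "depletion", "two_sided"):
        raise ValueError(f"unknown sidedness: {sided!r}")
    if result.sd <= 0:
        raise ValueError("degenerate null: sd = 0")
    z = (result.mean - float(expect)) / result.sd
    abs_z = abs(z)
    p = float(stats.norm.sf(abs_z))
    if sided == "two_sided":
        p = min(1.0, 2.0 * p)
    return replace(result, expect=expect, z=z, abs_z=abs_z, p_value=p, sided=sided)


def enrichment_report(
    lists: Mapping[str, int] | CategoryPartition,
    pool_size: int,
    n_draw: int,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    sided: str = "enrichment",
) -> pd.DataFrame:
    """Bootstrap + oracle report for several interest lists.

    ``lists`` maps label -> interest-list size (the observed count doubles
    as the expected value, as in a Venn-category test), or is a
    :class:`CategoryPartition` whose three category sizes are used. Each row
    carries the empirical null, the closed-form moments, z and p. Seeds for
    the per-list bootstraps are derived from ``seed`` by enumeration.
    """
    if isinstance(lists, CategoryPartition):
        lists = {k: v for k, v in lists.counts.items()}
    rows = []
    for j, (label, K) in enumerate(lists.items()):
        oracle = hypergeometric_moments(pool_size, K, n_draw)
        boot = bootstrap_overlap(
            pool_size, range(K), n_draw=n_draw, n_iter=n_iter, seed=seed + j
        )
        if boot.sd <= 0:
            rows.append(
                {
                    "list": label, "K": K, "N": pool_size, "n_draw": n_draw,
                    "boot_mean": boot.mean, "boot_sd": boot.sd,
                    "oracle_mean": oracle.mean, "oracle_sd": oracle.sd,
                    "z": np.nan, "abs_z": np.nan, "p_value": np.nan,
                    "error": "degenerate null",
                }
            )
            continue
        sig = attach_significance(boot, expect=K, sided=sided)
        rows.append(
            {
                "list": label, "K": K, "N": pool_size, "n_draw": n_draw,
                "boot_mean": sig.mean, "boot_sd": sig.sd,
                "oracle_mean": oracle.mean, "oracle_sd": oracle.sd,
                "z": sig.z, "abs_z": sig.abs_z, "p_value": sig.p_value,
                "error": "",
            }
        )
    return pd.DataFrame(rows)
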