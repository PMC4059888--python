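"""Binding-to-expression integration.

Rank-based expression quintiles, notched-boxplot median comparisons,
condition-specific gene calling by a two-threshold on/off rule, and
overlap-percentage tables against bound-gene sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionTable, GeneSet


@dataclass(frozen=True)
class ExpressionGroups:
    """Equal-frequency expression groups; label ``n_groups`` is the highest."""

    labels: pd.Series  # gene_id -> 1..n_groups
    n_groups: int
    degenerate: bool = False

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass(frozen=True)
class NotchedBoxStats:
    n: int
    median: float
    q1: float
    q3: float
    notch_low: float
    notch_high: float


def expression_groups(
    values: Mapping[str, float] | pd.Series,
    n_groups: int = 5,
    positive_only: bool = False,
) -> ExpressionGroups:
    """Rank genes into equal-frequency groups (group ``n_groups`` highest).

    Ties are broken by stable gene-ID order so repeated values still yield
    balanced groups; an all-equal input is flagged degenerate. With
    ``positive_only`` zeros (and negatives) are dropped first, matching the
    convention of considering only density values above zero.
    """
    s = pd.Series(values, dtype=float).dropna()
    if positive_only:
        s = s[s > 0]
    if len(s) < n_groups:
        raise ValueError(f"need >= {n_groups} finite values, have {len(s)}")
    s = s.sort_index(kind="stable")
    order = np.lexsort((np.arange(len(s)), s.to_numpy()))  # value, then stable ID order
    ranks = np.empty(len(s), dtype=int)
    ranks[order] = np.arange(len(s))
    labels = ranks * n_groups // len(s) + 1
    degenerate = bool(s.nunique() == 1)
    if degenerate:
        warnings.warn("degenerate ranking: all expression values equal", stacklevel=2)
    return ExpressionGroups(
        labels=pd.Series(labels, index=s.index, name="group"),
        n_groups=n_groups,
        degenerate=degenerate,
    )


def notched_box_stats(values: Sequence[float]) -> NotchedBoxStats:
    """Median, quartiles and the notch interval median +/- 1.58 IQR/sqrt(n)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 5:
        raise ValueError("need n >= 5 for notch statistics")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    half = 1.58 * (q3 - q1) / math.sqrt(len(x))
    return NotchedBoxStats(
        n=len(x), median=float(med), q1=float(q1), q3=float(q3),
        notch_low=float(med - half), notch_high=float(med + half),
    )


def notch_overlap(a: NotchedBoxStats, b: NotchedBoxStats) -> str:
    """'distinct' when the two notch intervals are disjoint, else 'overlapping'."""
    disjoint = a.notch_high < b.notch_low or b.notch_high < a.notch_low
    return "distinct" if disjoint else "overlapping"


def define_condition_specific_genes(
    expr: ExpressionTable,
    on_floor: float = 1.0,
    off_ceiling: float = 0.1,
    label: str = "condition_specific",
) -> GeneSet:
    """Genes on in the test condition and off in control.

    A gene qualifies iff its mean test-condition value is at least
    ``on_floor`` and its mean control-condition value is at most
    ``off_ceiling`` (both in the table's expression unit, FPKM by default).
    """
    if not math.isfinite(off_ceiling):
        warnings.warn(
            "off_ceiling is infinite: returns all genes above on_floor", stacklevel=2
        )
    test = expr.condition_matrix("test").mean(axis=1)
    ctrl = expr.condition_matrix("control").mean(axis=1)
    keep = (test >= on_floor) & (ctrl <= off_ceiling)
    return GeneSet.from_iterable(label, test.index[keep])


def overlap_percentages(
    reference: GeneSet, bound_sets: Sequence[GeneSet]
) -> pd.DataFrame:
    """Counts and percentages of a reference set covered by each bound set.

    For each bound set the table reports the intersection with the
    reference and the exclusive intersection (reference genes in this set
    and in no other supplied set). Percentages are kept at full precision
    with a half-up integer rounding column for display.
    """
    if len(reference) == 0:
        raise ValueError("empty reference set")
    rows = []
    for i, gs in enumerate(bound_sets):
        inter = reference.ids & gs.ids
        others = frozenset().union(*(o.ids for j, o in enumerate(bound_sets) if j != i)) if len(bound_sets) > 1 else frozenset()
        excl = inter - others
        for name, count in ((gs.label, len(inter)), (f"only_{gs.label}", len(excl))):
            pct = 100.0 * count / len(reference)
            rows.append(
                {
                    "set": name,
                    "count": count,
                    "reference_size": len(reference),
                    "percent": pct,
                    "percent_display": int(math.floor(pct + 0.5)),
                }
            )
    return pd.DataFrame(rows)
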