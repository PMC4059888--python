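"""NSAF scoring of MudPIT spectral counts and the MOCK-IP specificity filter.

Each protein's spectral count is divided by its length in residues to give
a spectral abundance factor (SAF = count / length), correcting for larger
proteins yielding more peptides; SAF values are then normalized by their
sum within the run (NSAF = SAF / sum SAF), so NSAF values are comparable
across runs of different depth and sum to one within a run. A protein is
called specific to an IP when it is absent from the MOCK run or at least
``min_fold`` enriched over it on the NSAF scale.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import SpectralCountTable

ABSENT = "absent_in_mock"
ENRICHED = "enriched"
REJECTED = "rejected"


def compute_nsaf(counts: SpectralCountTable) -> pd.DataFrame:
    """SAF/NSAF table for one run.

    Zero-count proteins are dropped before normalization (NSAF is undefined
    for unobserved proteins). Returns columns ``protein_id, spectral_count,
    protein_length, saf, nsaf, nsaf_x1000``; ``nsaf`` sums to 1 over the run.
    """
    df = counts.counts
    df = df[df["spectral_count"] > 0].copy()
    if df.empty:
        raise ValueError("no protein with a positive spectral count")
    df["saf"] = df["spectral_count"] / df["protein_length"]
    df["nsaf"] = df["saf"] / df["saf"].sum()
    df["nsaf_x1000"] = 1000.0 * df["nsaf"]
    return df.reset_index(drop=True)


def specificity_filter(
    ip: pd.DataFrame, mock: pd.DataFrame | None, min_fold: float = 10.0
) -> pd.DataFrame:
    """Keep IP proteins absent from MOCK or >= ``min_fold`` NSAF-enriched.

    ``ip`` and ``mock`` are NSAF tables from :func:`compute_nsaf` over the
    same search space; ``mock`` may be None or empty (everything then
    passes on the absent branch). Adds ``mock_nsaf``, ``fold_enrichment``
    (NaN when absent) and ``status`` columns; rejected rows are retained
    with status ``rejected`` and a ``kept`` boolean marks the filter result.
    """
    out = ip.copy()
    if mock is None or mock.empty:
        out["mock_nsaf"] = 0.0
    else:
        mock_nsaf = mock.set_index("protein_id")["nsaf"]
        out["mock_nsaf"] = out["protein_id"].map(mock_nsaf).fillna(0.0)
    absent = out["mock_nsaf"] == 0.0
    fold = out["nsaf"] / out["mock_nsaf"].where(~absent)
    out["fold_enrichment"] = fold
    out["status"] = REJECTED
    out.loc[fold >= min_fold, "status"] = ENRICHED
    out.loc[absent, "status"] = ABSENT
    out["kept"] = out["status"] != REJECTED
    return out
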