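"""Thin wrappers around pyranges with 0-based half-open lowercase-column frames.

All genomic tables in this package are pandas DataFrames with at least
``chrom``, ``start``, ``end`` columns (BED convention).  pyranges wants
``Chromosome``/``Start``/``End``; these helpers translate back and forth and
pin down the overlap semantics used everywhere: two intervals overlap iff they
share >= 1 bp (bookended intervals do not overlap).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pyranges as pr

_TO_PR = {"chrom": "Chromosome", "start": "Start", "end": "End"}
_FROM_PR = {v: k for k, v in _TO_PR.items()}


def as_ranges(df: pd.DataFrame) -> pr.PyRanges:
    return pr.PyRanges(df.rename(columns=_TO_PR), int64=True)


def as_frame(gr: pr.PyRanges) -> pd.DataFrame:
    df = gr.df
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = df.rename(columns=_FROM_PR)
    df["chrom"] = df["chrom"].astype(str)
    return df.reset_index(drop=True)


def merge_union(df: pd.DataFrame, min_overlap: int = 1) -> pd.DataFrame:
    """Single-linkage union-merge of intervals sharing >= min_overlap bp.

    pyranges' default merge also joins bookended intervals; a negative slack
    restores the strict rule.
    """
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    merged = as_frame(as_ranges(df[["chrom", "start", "end"]]).merge(slack=-min_overlap))
    return merged.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def overlap_pairs(
    a: pd.DataFrame, b: pd.DataFrame, a_id: str, b_id: str
) -> pd.DataFrame:
    """All (a_id, b_id) pairs whose intervals overlap by >= 1 bp."""
    if a.empty or b.empty:
        return pd.DataFrame(columns=[a_id, b_id])
    ga = as_ranges(a[["chrom", "start", "end", a_id]])
    gb = as_ranges(b[["chrom", "start", "end", b_id]].rename(columns={b_id: "_bid"}))
    j = ga.join(gb)
    if len(j) == 0:
        return pd.DataFrame(columns=[a_id, b_id])
    out = j.df[[a_id, "_bid"]].rename(columns={"_bid": b_id})
    return out.drop_duplicates().reset_index(drop=True)


def count_overlaps(a: pd.DataFrame, b: pd.DataFrame, a_id: str) -> pd.Series:
    """Number of b-intervals overlapping each a-interval by >= 1 bp."""
    if a.empty:
        return pd.Series(dtype=int)
    if b.empty:
        return pd.Series(0, index=a[a_id].to_numpy())
    ga = as_ranges(a[["chrom", "start", "end", a_id]])
    res = ga.count_overlaps(as_ranges(b[["chrom", "start", "end"]])).df
    out = res.set_index(a_id)["NumberOverlaps"]
    return out.reindex(a[a_id]).fillna(0).astype(int)


def subtract(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Base-level subtraction a - b; columns of a other than coords survive."""
    if a.empty:
        return a.copy()
    if b.empty:
        return a.copy().reset_index(drop=True)
    res = as_ranges(a).subtract(as_ranges(b[["chrom", "start", "end"]]))
    out = as_frame(res)
    if out.empty:
        return pd.DataFrame(columns=list(a.columns))
    return out[list(a.columns)]


def overlaps_any(targets: pd.DataFrame, features: pd.DataFrame, target_id: str) -> pd.Series:
    """Boolean per target: does it overlap any feature interval by >= 1 bp."""
    n = count_overlaps(targets, features, target_id)
    return n > 0


def midpoints(df: pd.DataFrame) -> np.ndarray:
    """Integer midpoints (floor of the arithmetic mean of start and end)."""
    return (df["start"].to_numpy() + df["end"].to_numpy()) // 2
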