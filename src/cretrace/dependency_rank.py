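"""Dependency-screen gene ranking.

Given a genes x cell-lines dependency-score matrix (lower = stronger fitness
dependence, e.g. Chronos scores), each gene's most-dependent cell-line set is
taken either as the ``top_k`` lowest-scoring lines or the lowest ``top_fraction``
of lines, and genes are ranked by how many lineage-of-interest lines (e.g.
B-ALL) fall inside that set.  Ties at the top-set boundary are included, so
the realised set can exceed its nominal size; lines with missing scores are
excluded from that gene's ranking.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def dependency_rank(
    scores: pd.DataFrame,
    lineage: Mapping[str, str] | pd.Series,
    lineage_of_interest: str | Sequence[str],
    top_k: int | None = None,
    top_fraction: float | None = None,
) -> pd.DataFrame:
    """Rank genes by lineage-of-interest membership in their top-dependent set.

    Returns a frame sorted by ``n_interest_in_top`` descending with ties
    broken by the mean score of the interest lines (ascending, i.e. most
    dependent first), then by gene id.
    """
    if (top_k is None) == (top_fraction is None):
        raise ValueError("supply exactly one of top_k / top_fraction")
    if top_k is not None and (top_k < 1 or top_k > scores.shape[1]):
        raise ValueError(f"top_k={top_k} out of range for {scores.shape[1]} cell lines")
    if top_fraction is not None and not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    lineage = pd.Series(dict(lineage) if not isinstance(lineage, pd.Series) else lineage)
    missing = set(scores.columns) - set(lineage.index)
    if missing:
        raise ValueError(f"cell line(s) without lineage label: {sorted(missing)[:5]}")
    interest = {lineage_of_interest} if isinstance(lineage_of_interest, str) else set(lineage_of_interest)
    unknown = interest - set(lineage.values)
    if unknown:
        raise ValueError(f"unknown lineage label(s): {sorted(unknown)}")
    interest_lines = lineage.index[lineage.isin(interest)]
    interest_mask = scores.columns.isin(interest_lines)

    rows = []
    mat = scores.to_numpy(dtype=float)
    for i, gene in enumerate(scores.index):
        vals = mat[i]
        ok = np.isfinite(vals)
        n = int(ok.sum())
        if n == 0:
            rows.append((gene, 0, 0, np.nan))
            continue
        size = top_k if top_k is not None else math.ceil(top_fraction * n)
        size = min(size, n)
        finite = vals[ok]
        threshold = np.partition(finite, size - 1)[size - 1]
        top = ok & (vals <= threshold)  # boundary ties included
        count = int((top & interest_mask).sum())
        mean_interest = (
            float(np.nanmean(vals[interest_mask])) if interest_mask.any() else np.nan
        )
        rows.append((gene, count, int(top.sum()), mean_interest))
    out = pd.DataFrame(
        rows, columns=["gene", "n_interest_in_top", "top_set_size", "mean_interest_score"]
    )
    out = out.sort_values(
        by=["n_interest_in_top", "mean_interest_score", "gene"],
        ascending=[False, True, True],
        kind="stable",
        na_position="last",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
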