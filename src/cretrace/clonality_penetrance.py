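"""Clonality Index (CI) and Penetrance Index (PI) scoring.

The CI is a per-sample percentile rank of a peak's size- and depth-normalised
read enrichment (Nscore).  Within each sample, master regions detected in that
sample are ranked from highest to lowest Nscore and binned into percentiles 1
(highest enrichment) to 100 (lowest); regions absent from the sample get CI 0.
The PI of a master region is the number of cohort samples in which it is
detected (>= 1 bp overlap with a sample peak), ranging from 1 to the cohort
size.

Because the verbatim CI orientation puts the most clonal peaks next to the
"absent" code (CI 1 vs CI 0), an inverted reporting scale (101 - CI for
detected peaks, so larger = more clonal, 0 = absent) is provided for analyses
that track clonality increases across stages.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _intervals as iv
from .regions_io import MasterList, SampleRepertoire

NSCORE_SCALE = 1e-6 * 1e-3  # pure positive constants; CI is rank-invariant to them


def nscore(read_count, peak_size, total_mapped_reads) -> np.ndarray:
    """Size- and depth-normalised enrichment: ((count/size)*1e-6)*1e-3 / total."""
    peak_size = np.asarray(peak_size, dtype=float)
    if np.any(peak_size <= 0):
        raise ValueError("zero-size peak")
    if total_mapped_reads <= 0:
        raise ValueError("zero total mapped reads")
    return (np.asarray(read_count, dtype=float) / peak_size) * NSCORE_SCALE / total_mapped_reads


def clonality_index(
    repertoire: SampleRepertoire, master: MasterList
) -> pd.DataFrame:
    """CI column for one sample over the master list.

    Sample peak counts are transferred onto master regions (summed when
    several peaks merged); detected regions are ranked descending by Nscore,
    and the CI bin is ``ceil(100 * rank / n_detected)`` with tied Nscores
    sharing the bin of their minimum rank.  Absent regions get CI 0.

    Returns a frame indexed by region_id with ``nscore`` and ``ci`` columns.
    """
    regions = master.regions
    sizes = (regions["end"] - regions["start"]).to_numpy()
    if np.any(sizes <= 0):
        raise ValueError("zero-size peak in master list")
    out = pd.DataFrame(
        {"nscore": 0.0, "ci": 0},
        index=pd.Index(regions["region_id"], name="region_id"),
    )
    pairs = iv.overlap_pairs(regions, repertoire.peaks, "region_id", "peak_id")
    if pairs.empty:
        return out
    counts = (
        pairs.merge(repertoire.peaks[["peak_id", "read_count"]], on="peak_id")
        .groupby("region_id")["read_count"]
        .sum()
    )
    size_by_id = pd.Series(sizes, index=regions["region_id"])
    ns = pd.Series(
        nscore(
            counts.to_numpy(),
            size_by_id.loc[counts.index].to_numpy(),
            repertoire.total_mapped_reads,
        ),
        index=counts.index,
    )
    # stable sort by region id underlies the ranking; exact ties share the
    # minimum rank and therefore the same percentile bin
    ns = ns.sort_index(kind="stable")
    rank = (-ns).rank(method="min").to_numpy()
    ci = np.ceil(100.0 * rank / len(ns)).astype(int)
    out.loc[ns.index, "nscore"] = ns
    out.loc[ns.index, "ci"] = ci
    return out


def clonality_matrix(
    repertoires: Sequence[SampleRepertoire], master: MasterList
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(nscore, ci) matrices, regions x samples."""
    cols_n, cols_c = {}, {}
    for rep in repertoires:
        col = clonality_index(rep, master)
        cols_n[rep.sample_id] = col["nscore"]
        cols_c[rep.sample_id] = col["ci"]
    return pd.DataFrame(cols_n), pd.DataFrame(cols_c)


def invert_ci(ci: pd.DataFrame | pd.Series):
    """Map detected CIs onto the activity-increasing scale 101 - CI; 0 stays 0."""
    inv = ci.where(ci == 0, 101 - ci)
    return inv


def penetrance_index(
    presence: pd.DataFrame, scope: Sequence[str] | None = None
) -> pd.Series:
    """PI per region: number of in-scope samples detecting it.

    With an explicit scope, regions undetected in the scope are dropped from
    the output; over the full cohort every master region has PI >= 1.
    """
    if scope is not None:
        if len(scope) == 0:
            raise ValueError("empty scope")
        sub = presence[list(scope)]
        pi = sub.sum(axis=1).astype(int)
        return pi[pi > 0]
    return presence.sum(axis=1).astype(int)


def penetrance_composition(
    presence: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    low_cut: int = 14,
) -> pd.DataFrame:
    """Per-group fractions of detected regions by cohort-wide penetrance band.

    Bands: private (PI = 1), low (2..low_cut), high (> low_cut); the three
    fractions sum to 1 within each group.
    """
    cols = [c for g in groups.values() for c in g]
    if sorted(cols) != sorted(presence.columns):
        raise ValueError("groups must partition the samples of the presence matrix")
    pi = penetrance_index(presence)
    rows = {}
    for name, samples in groups.items():
        detected = presence[list(samples)].any(axis=1)
        n = int(detected.sum())
        if n == 0:
            raise ValueError(f"group {name!r} detects zero regions")
        p = pi[detected]
        rows[name] = {
            "private": float((p == 1).sum()) / n,
            "low": float(((p >= 2) & (p <= low_cut)).sum()) / n,
            "high": float((p > low_cut).sum()) / n,
        }
    return pd.DataFrame.from_dict(rows, orient="index")[["private", "low", "high"]]


def penetrance_oe(
    group_a: Sequence[str],
    group_b: Sequence[str],
    presence: pd.DataFrame,
) -> pd.DataFrame:
    """Observed/expected detected-region counts per penetrance value.

    For each cohort-wide PI value, the expected group-A count allocates the
    pooled detection events (A-detected plus B-detected regions at that PI)
    to A in proportion to A's overall share of detection events.  PI values
    with expected 0 are reported as missing (NaN), not 0.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    pi = penetrance_index(presence)
    det_a = presence[list(group_a)].any(axis=1)
    det_b = presence[list(group_b)].any(axis=1)
    n_a, n_b = int(det_a.sum()), int(det_b.sum())
    share_a = n_a / (n_a + n_b)
    levels = np.arange(1, pi.max() + 1)
    obs_a = pd.Series(0, index=levels, dtype=float)
    obs_b = pd.Series(0, index=levels, dtype=float)
    obs_a.update(pi[det_a].value_counts())
    obs_b.update(pi[det_b].value_counts())
    pooled = obs_a + obs_b
    exp_a = pooled * share_a
    exp_b = pooled * (1.0 - share_a)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe_a = np.where(exp_a > 0, obs_a / exp_a, np.nan)
        oe_b = np.where(exp_b > 0, obs_b / exp_b, np.nan)
    return pd.DataFrame(
        {
            "pi": levels,
            "observed_a": obs_a.to_numpy(),
            "observed_b": obs_b.to_numpy(),
            "expected_a": exp_a.to_numpy(),
            "expected_b": exp_b.to_numpy(),
            "oe_a": oe_a,
            "oe_b": oe_b,
        }
    )
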