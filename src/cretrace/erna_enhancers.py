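"""Enhancer RNA quantification and enhancer-tier classification.

eRNA productivity of a CRE is measured over its *non-exonic* bases only: the
exon union is subtracted from the CRE at base level, and RNA fragments are
counted when they overlap the remaining eligible intervals by >= 1 bp (a
fragment touching only exonic bases of the CRE is not counted).  CREs called
significantly more productive in the disease group are the candidate
productive enhancers; external annotation sets (pre-annotated enhancers,
super-enhancers, cell-line ATAC peaks) refine them into tiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _intervals as iv
from .differential import differential_accessibility


@dataclass
class ErnaMatrix:
    counts: pd.DataFrame  # CRE x sample fragment counts over non-exonic bases
    cpm: pd.DataFrame  # counts scaled to fragments-per-million per sample
    eligible_length: pd.Series  # bp of each CRE not covered by any exon


def erna_quantify(
    cres: pd.DataFrame,
    exons: pd.DataFrame,
    fragments: Mapping[str, pd.DataFrame],
) -> ErnaMatrix:
    """Count RNA fragments on the non-exonic portion of each CRE.

    ``cres`` needs chrom/start/end/region_id; ``fragments`` maps sample id to
    a fragment-interval frame.  A fragment is counted once per CRE even when
    it overlaps several eligible sub-intervals of that CRE.
    """
    ids = pd.Index(cres["region_id"])
    eligible = iv.subtract(cres[["chrom", "start", "end", "region_id"]], exons)
    if eligible.empty:
        elig_len = pd.Series(0, index=ids)
    else:
        elig_len = (
            (eligible["end"] - eligible["start"])
            .groupby(eligible["region_id"].to_numpy())
            .sum()
            .reindex(ids)
            .fillna(0)
            .astype(int)
        )
    counts = pd.DataFrame(0, index=ids, columns=list(fragments), dtype=int)
    cpm = pd.DataFrame(0.0, index=ids, columns=list(fragments))
    for sample, frags in fragments.items():
        if frags is None or len(frags) == 0 or eligible.empty:
            continue
        frags = frags.reset_index(drop=True).copy()
        frags["frag_idx"] = np.arange(len(frags))
        pairs = iv.overlap_pairs(eligible, frags, "region_id", "frag_idx")
        if pairs.empty:
            continue
        per_cre = pairs.drop_duplicates().groupby("region_id")["frag_idx"].nunique()
        counts.loc[per_cre.index, sample] = per_cre.astype(int)
        cpm[sample] = counts[sample] / len(frags) * 1e6
    return ErnaMatrix(counts=counts, cpm=cpm, eligible_length=elig_len)


def productive_cres(
    erna: ErnaMatrix | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    logfc_cut: float = 0.7,
    fdr_cut: float = 0.05,
) -> tuple[pd.Index, pd.DataFrame]:
    """CREs significantly more eRNA-productive in group B (e.g. onset).

    Counts are put on a log2 fragments-per-million scale (pseudocount 0.5,
    per-sample totals from the count matrix) and passed through the same
    Welch/BH differential machinery used for accessibility.
    """
    counts = erna.counts if isinstance(erna, ErnaMatrix) else erna
    if len(group_b) == 0:
        raise ValueError("empty group B")
    totals = counts.sum(axis=0).astype(float).replace(0, 1.0)
    norm = np.log2((counts + 0.5).div(totals, axis=1) * 1e6)
    res = differential_accessibility(
        norm, list(group_a), list(group_b), logfc_cut=logfc_cut, fdr_cut=fdr_cut
    )
    return res.index[res["call"] == "up_in_B"], res


def overlap_frequency(
    targets: pd.DataFrame,
    feature_sets: Mapping[str, pd.DataFrame],
    combos: Sequence[Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Fraction of target regions overlapped (>= 1 bp) by each feature set.

    ``combos`` adds union rows: for each listed combination of set names the
    fraction of targets hit by any member is reported; by default the union
    of all sets is appended when more than one set is given.
    """
    if targets.empty:
        raise ValueError("empty target set")
    tid = "region_id" if "region_id" in targets.columns else None
    t = targets.copy()
    if tid is None:
        t["region_id"] = np.arange(len(t))
    n = len(t)
    hits = {
        name: iv.overlaps_any(t, feats, "region_id")
        for name, feats in feature_sets.items()
    }
    rows = [
        (name, int(h.sum()), float(h.sum()) / n) for name, h in hits.items()
    ]
    if combos is None and len(feature_sets) > 1:
        combos = [tuple(feature_sets)]
    for combo in combos or []:
        any_hit = np.zeros(n, dtype=bool)
        for name in combo:
            any_hit |= hits[name].to_numpy()
        rows.append(("|".join(combo), int(any_hit.sum()), float(any_hit.sum()) / n))
    return pd.DataFrame(rows, columns=["feature_set", "n_overlapping", "frequency"])


CANDIDATE_TIER = "candidate_productive_enhancer"


def classify_enhancer_tiers(
    cres: pd.DataFrame,
    erna_annotation: pd.DataFrame,
    super_enhancers: pd.DataFrame,
    cellline_peaks: pd.DataFrame,
    candidate_clusters: Sequence[str] = ("C1", "C2"),
) -> tuple[pd.DataFrame, pd.Series]:
    """Flag CREs against annotation sets and derive the enhancer tier.

    ``cres`` needs chrom/start/end/region_id plus a ``cluster`` column.  The
    candidate-productive tier is the disease-active clusters (C1/C2 by
    default) shared with the cell-line accessible landscape; otherwise a CRE
    falls back to super-enhancer, annotated-enhancer, or other, in that order.
    """
    if "cluster" not in cres.columns:
        raise ValueError("cres must carry a 'cluster' column")
    out = cres[["region_id", "cluster"]].copy()
    out["erna_annotated"] = iv.overlaps_any(cres, erna_annotation, "region_id").to_numpy()
    out["super_enhancer"] = iv.overlaps_any(cres, super_enhancers, "region_id").to_numpy()
    out["cellline_shared"] = iv.overlaps_any(cres, cellline_peaks, "region_id").to_numpy()
    tier = np.full(len(out), "other", dtype=object)
    tier[out["erna_annotated"].to_numpy()] = "annotated_enhancer"
    tier[out["super_enhancer"].to_numpy()] = "super_enhancer"
    candidate = out["cluster"].isin(candidate_clusters).to_numpy() & out["cellline_shared"].to_numpy()
    tier[candidate] = CANDIDATE_TIER
    out["tier"] = tier
    counts = out["tier"].value_counts().sort_index()
    return out, counts
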