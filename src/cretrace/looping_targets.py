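"""Chromatin-loop classification and enhancer-to-gene target assignment.

Loops (promoter-capture Hi-C calls, BEDPE anchors, 0-based half-open) are
labelled promoter-promoter, promoter-CRE or CRE-CRE by whether each anchor
overlaps a promoter window (TSS +/- promoter_window); an anchor overlapping
both a promoter window and a CRE counts as promoter.  Enhancer-gene links use
loop evidence (one anchor on the CRE, the other on a gene's promoter window)
with a proximity fallback to genes whose TSS lies within |proximity_window|
of the CRE midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _intervals as iv
from .regions_io import GeneModel

BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]

LOOP_CLASSES = ("promoter-promoter", "promoter-CRE", "CRE-CRE")

DISTANCE_BIN_EDGES = (50_000, 500_000, 2_000_000)
DISTANCE_BIN_LABELS = ("<50kb", "50-500kb", "0.5-2Mb", ">=2Mb")


@dataclass
class LoopClassification:
    loops: pd.DataFrame  # input columns + loop_class, distance, distance_bin
    class_counts: pd.Series
    distance_histogram: pd.Series  # cis loops only


def read_bedpe(path) -> pd.DataFrame:
    """Read a BEDPE loop file; extra columns (name, score, resolution) kept."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"BEDPE needs >= 6 columns, got {df.shape[1]}")
    extra = [f"col{i}" for i in range(7, df.shape[1] + 1)]
    names = BEDPE_COLUMNS + extra
    if df.shape[1] >= 7:
        names[6] = "name"
    if df.shape[1] >= 8:
        names[7] = "score"
    df.columns = names
    return normalize_anchor_order(df)


def normalize_anchor_order(loops: pd.DataFrame) -> pd.DataFrame:
    """Enforce the anchor1-leftmost convention on cis loops."""
    loops = loops.copy()
    swap = (loops["chrom1"] == loops["chrom2"]) & (loops["start1"] > loops["start2"])
    if swap.any():
        for a, b in (("chrom1", "chrom2"), ("start1", "start2"), ("end1", "end2")):
            loops.loc[swap, [a, b]] = loops.loc[swap, [b, a]].to_numpy()
    return loops


def _anchor_labels(
    anchors: pd.DataFrame, promoters: pd.DataFrame
) -> np.ndarray:
    hit = iv.overlaps_any(anchors, promoters, "loop_idx")
    return hit.to_numpy()


def classify_loops(
    loops: pd.DataFrame,
    gene_model: GeneModel,
    promoter_window: int = 5000,
    bin_edges: Sequence[int] = DISTANCE_BIN_EDGES,
) -> LoopClassification:
    """Label each loop by anchor annotation and bin cis loops by distance.

    Distance is between anchor midpoints; trans-chromosomal loops are
    labelled but excluded from the distance histogram.
    """
    loops = normalize_anchor_order(loops)
    promoters = gene_model.promoter_windows(promoter_window)
    idx = np.arange(len(loops))
    a1 = pd.DataFrame(
        {
            "chrom": loops["chrom1"],
            "start": loops["start1"],
            "end": loops["end1"],
            "loop_idx": idx,
        }
    )
    a2 = pd.DataFrame(
        {
            "chrom": loops["chrom2"],
            "start": loops["start2"],
            "end": loops["end2"],
            "loop_idx": idx,
        }
    )
    p1 = _anchor_labels(a1, promoters)
    p2 = _anchor_labels(a2, promoters)
    n_prom = p1.astype(int) + p2.astype(int)
    loop_class = np.select(
        [n_prom == 2, n_prom == 1], ["promoter-promoter", "promoter-CRE"], "CRE-CRE"
    )
    cis = (loops["chrom1"] == loops["chrom2"]).to_numpy()
    mid1 = (loops["start1"].to_numpy() + loops["end1"].to_numpy()) // 2
    mid2 = (loops["start2"].to_numpy() + loops["end2"].to_numpy()) // 2
    distance = np.where(cis, np.abs(mid2 - mid1), np.nan)

    out = loops.copy()
    out["loop_class"] = loop_class
    out["distance"] = distance
    edges = [0, *bin_edges, np.inf]
    out["distance_bin"] = pd.cut(
        out["distance"], bins=edges, labels=DISTANCE_BIN_LABELS, right=False
    )
    class_counts = (
        out["loop_class"].value_counts().reindex(LOOP_CLASSES).fillna(0).astype(int)
    )
    hist = (
        out.loc[cis, "distance_bin"]
        .value_counts()
        .reindex(DISTANCE_BIN_LABELS)
        .fillna(0)
        .astype(int)
    )
    return LoopClassification(loops=out, class_counts=class_counts, distance_histogram=hist)


def link_targets(
    cres: pd.DataFrame,
    loops: pd.DataFrame,
    gene_model: GeneModel,
    proximity_window: int = 10_000,
    promoter_window: int = 5000,
) -> pd.DataFrame:
    """Assign target genes to CREs: loop evidence first, proximity fallback.

    A loop links a CRE to a gene when one anchor overlaps the CRE and the
    other overlaps the gene's promoter window (either orientation, >= 1 bp).
    CREs without any loop link fall back to every gene whose TSS is within
    ``proximity_window`` of the CRE midpoint; CREs with neither are reported
    unlinked (gene NA, evidence 'none').  Distance is CRE midpoint to TSS.
    """
    loops = normalize_anchor_order(loops)
    promoters = gene_model.promoter_windows(promoter_window)
    cre_cols = cres[["chrom", "start", "end", "region_id"]]
    idx = np.arange(len(loops))
    anchors = []
    for side in (1, 2):
        anchors.append(
            pd.DataFrame(
                {
                    "chrom": loops[f"chrom{side}"],
                    "start": loops[f"start{side}"],
                    "end": loops[f"end{side}"],
                    "loop_idx": idx,
                    "side": side,
                }
            )
        )
    loop_links: set[tuple[str, str]] = set()
    for cre_side, gene_side in ((1, 2), (2, 1)):
        ca = anchors[cre_side - 1]
        ga = anchors[gene_side - 1]
        cre_hits = iv.overlap_pairs(ca, cre_cols, "loop_idx", "region_id")
        gene_hits = iv.overlap_pairs(ga, promoters, "loop_idx", "gene_id")
        if cre_hits.empty or gene_hits.empty:
            continue
        joined = cre_hits.merge(gene_hits, on="loop_idx")
        loop_links.update(zip(joined["region_id"], joined["gene_id"]))

    mids = pd.Series(iv.midpoints(cre_cols), index=cre_cols["region_id"].to_numpy())
    tss = gene_model.genes.set_index("gene_id")
    rows = []
    linked_cres = {c for c, _ in loop_links}
    for cre_id, gene_id in sorted(loop_links):
        d = int(abs(mids[cre_id] - tss.loc[gene_id, "tss"]))
        rows.append((cre_id, gene_id, "loop", d))
    for rec in cre_cols.itertuples(index=False):
        if rec.region_id in linked_cres:
            continue
        mid = (rec.start + rec.end) // 2
        near = tss[(tss["chrom"] == rec.chrom) & ((tss["tss"] - mid).abs() <= proximity_window)]
        if near.empty:
            rows.append((rec.region_id, None, "none", np.nan))
        else:
            for gene_id, g in near.sort_index().iterrows():
                rows.append((rec.region_id, gene_id, "proximity", int(abs(g["tss"] - mid))))
    out = pd.DataFrame(rows, columns=["cre_id", "gene_id", "evidence", "distance"])
    return (
        out.drop_duplicates(subset=["cre_id", "gene_id", "evidence"])
        .sort_values(["cre_id", "gene_id"], kind="stable", na_position="last")
        .reset_index(drop=True)
    )
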