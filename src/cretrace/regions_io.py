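"""Cohort ingestion, master-list construction, counting and region annotation.

The cohort model: each sample contributes a repertoire of ATAC-seq peaks with
per-peak read counts and a per-sample total mapped-read count, plus a disease
stage label drawn from ``healthy / onset / remission / relapse``.  All sample
repertoires are union-merged (single linkage, >= 1 bp overlap) into a
cohort-wide *master list* of disjoint accessible regions with stable ids; the
master list is the coordinate universe for every downstream score.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _intervals as iv

STAGES = ("healthy", "onset", "remission", "relapse")

PEAK_COLUMNS = ["chrom", "start", "end", "peak_id", "read_count"]


@dataclass
class SampleRepertoire:
    """One sample's peak set with counts and sequencing depth."""

    sample_id: str
    stage: str
    peaks: pd.DataFrame  # chrom, start, end, peak_id, read_count
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(
                f"unknown stage label {self.stage!r} for sample {self.sample_id!r};"
                f" expected one of {STAGES}"
            )
        if self.total_mapped_reads <= 0:
            raise ValueError(f"total_mapped_reads must be positive for {self.sample_id!r}")
        self.peaks = (
            self.peaks[PEAK_COLUMNS]
            .sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True)
        )


@dataclass
class MasterList:
    """Merged, disjoint cohort-wide accessible regions with provenance."""

    regions: pd.DataFrame  # chrom, start, end, region_id
    provenance: pd.DataFrame  # region_id, sample_id, peak_id

    @property
    def region_ids(self) -> pd.Index:
        return pd.Index(self.regions["region_id"])

    def presence_matrix(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        """Boolean regions x samples detection matrix (>= 1 bp peak overlap)."""
        mat = pd.DataFrame(False, index=self.region_ids, columns=list(sample_ids))
        if not self.provenance.empty:
            hits = self.provenance[["region_id", "sample_id"]].drop_duplicates()
            hits = hits[hits["sample_id"].isin(mat.columns)]
            mat.values[
                mat.index.get_indexer(hits["region_id"]),
                mat.columns.get_indexer(hits["sample_id"]),
            ] = True
        return mat


@dataclass
class GeneModel:
    """Gene models as a TSS table plus exon intervals.

    ``genes``: gene_id, chrom, strand, tss.  ``exons``: gene_id, chrom, start,
    end.  The TSV serialisation keeps one row per gene with comma-separated
    exon starts/ends (GTF-lite); exon coordinates are stored 0-based half-open,
    with the +1/-1 conversion applied at ingestion when reading 1-based input.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame

    def promoter_windows(self, window: int = 5000) -> pd.DataFrame:
        out = self.genes.copy()
        out["start"] = np.maximum(0, out["tss"] - window)
        out["end"] = out["tss"] + window + 1
        return out[["chrom", "start", "end", "gene_id", "tss", "strand"]]


def _parse_bed(path: str | Path, fmt: str = "bed") -> pd.DataFrame:
    """Parse a BED3/BED6/narrowPeak file, rejecting malformed lines by number.

    Read counts come from the score column (col 5) for BED5+ or from the
    signalValue-adjacent count column (col 7) when ``fmt='narrowpeak'``.
    """
    path = Path(path)
    rows, bad = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                bad.append(lineno)
                continue
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if start < 0 or start >= end:
                    raise ValueError
                name = parts[3] if len(parts) > 3 and parts[3] != "" else None
                if fmt == "narrowpeak" and len(parts) >= 7:
                    count = int(float(parts[6]))
                elif len(parts) > 4:
                    count = int(float(parts[4]))
                else:
                    count = 0
                if count < 0:
                    raise ValueError
            except ValueError:
                bad.append(lineno)
                continue
            rows.append((chrom, start, end, name, count))
    if bad:
        raise ValueError(f"malformed BED lines in {path.name}: {bad}")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id", "read_count"])
    missing = df["peak_id"].isna()
    if missing.any():
        df.loc[missing, "peak_id"] = [f"{path.stem}_peak{i}" for i in df.index[missing]]
    return df


def read_cohort(
    peak_paths: Sequence[str | Path],
    metadata_path: str | Path,
    fmt: str = "bed",
) -> list[SampleRepertoire]:
    """Load one :class:`SampleRepertoire` per peak file.

    Metadata TSV needs ``sample_id``, ``stage``, ``total_mapped_reads`` and
    optionally ``peak_file``; without the latter, files are matched to samples
    by filename stem.
    """
    if len(peak_paths) == 0:
        raise ValueError("empty cohort: no peak files given")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "stage", "total_mapped_reads"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dup}")
    unknown = set(meta["stage"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage label(s): {sorted(unknown)}")
    if len(peak_paths) != len(meta):
        raise ValueError(
            f"{len(peak_paths)} peak files but {len(meta)} metadata rows"
        )

    paths = {Path(p).name: Path(p) for p in peak_paths}
    stems = {Path(p).stem: Path(p) for p in peak_paths}
    reps = []
    for rec in meta.itertuples(index=False):
        if "peak_file" in meta.columns:
            key = Path(getattr(rec, "peak_file")).name
            if key not in paths:
                raise ValueError(f"peak file {key!r} for sample {rec.sample_id!r} not given")
            path = paths[key]
        else:
            if rec.sample_id not in stems:
                raise ValueError(f"no peak file matching sample {rec.sample_id!r}")
            path = stems[rec.sample_id]
        reps.append(
            SampleRepertoire(
                sample_id=rec.sample_id,
                stage=rec.stage,
                peaks=_parse_bed(path, fmt=fmt),
                total_mapped_reads=int(rec.total_mapped_reads),
            )
        )
    return reps


def build_master_list(
    repertoires: Sequence[SampleRepertoire], min_overlap: int = 1
) -> MasterList:
    """Union-merge all sample peaks into disjoint master regions.

    Merging is single linkage: peaks overlapping by >= ``min_overlap`` bp join
    the same region, transitively.  Provenance maps each region to every
    contributing (sample, peak) pair.
    """
    if len(repertoires) == 0:
        raise ValueError("empty cohort: need at least one repertoire")
    frames = []
    for rep in repertoires:
        df = rep.peaks[["chrom", "start", "end", "peak_id"]].copy()
        df["sample_id"] = rep.sample_id
        frames.append(df)
    allpeaks = pd.concat(frames, ignore_index=True)
    merged = iv.merge_union(allpeaks, min_overlap=min_overlap)
    width = max(6, len(str(len(merged))))
    merged["region_id"] = [f"cre_{i:0{width}d}" for i in range(1, len(merged) + 1)]
    allpeaks["_pid"] = np.arange(len(allpeaks))
    pairs = iv.overlap_pairs(merged, allpeaks.rename(columns={"_pid": "pid"}), "region_id", "pid")
    prov = pairs.merge(
        allpeaks[["_pid", "sample_id", "peak_id"]],
        left_on="pid",
        right_on="_pid",
    )[["region_id", "sample_id", "peak_id"]]
    prov = prov.sort_values(["region_id", "sample_id", "peak_id"], kind="stable").reset_index(drop=True)
    return MasterList(regions=merged[["chrom", "start", "end", "region_id"]], provenance=prov)


def build_count_matrix(
    master: MasterList,
    repertoires: Sequence[SampleRepertoire],
    fragments: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Regions x samples integer count matrix.

    Without fragments, each sample's peak counts are transferred to the master
    region they overlap (summed when several peaks merged into one region).
    With fragments, the count is the number of fragment intervals overlapping
    the region by >= 1 bp; a fragment spanning two (disjoint) master regions
    increments both.
    """
    sample_ids = [rep.sample_id for rep in repertoires]
    if fragments is not None:
        unknown = set(fragments) - set(sample_ids)
        if unknown:
            raise ValueError(f"fragment file(s) for unknown sample(s): {sorted(unknown)}")
    mat = pd.DataFrame(0, index=master.region_ids, columns=sample_ids, dtype=int)
    for rep in repertoires:
        if fragments is not None:
            frags = fragments.get(rep.sample_id)
            if frags is None or frags.empty:
                continue
            counts = iv.count_overlaps(master.regions, frags, "region_id")
            mat[rep.sample_id] = counts.reindex(mat.index).fillna(0).astype(int)
        else:
            pairs = iv.overlap_pairs(master.regions, rep.peaks, "region_id", "peak_id")
            if pairs.empty:
                continue
            counts = (
                pairs.merge(rep.peaks[["peak_id", "read_count"]], on="peak_id")
                .groupby("region_id")["read_count"]
                .sum()
            )
            mat.loc[counts.index, rep.sample_id] = counts.astype(int)
    return mat


def annotate_regions(
    master: MasterList, gene_model: GeneModel, promoter_window: int = 5000
) -> pd.DataFrame:
    """Classify regions promoter-like/distal and assign the nearest gene.

    Distance is signed from the region midpoint to the nearest TSS: positive
    when the TSS lies downstream of the midpoint on the gene's strand, zero
    when a TSS falls inside the region.  Promoter-like iff
    ``|tss_distance| <= promoter_window``.
    """
    genes = gene_model.genes
    if genes.empty:
        raise ValueError("empty gene model")
    out = []
    # Deterministic nearest-TSS: per chromosome, ties broken toward the
    # smaller TSS coordinate, then the lexicographically smaller gene id.
    by_chrom = {
        chrom: g.sort_values(["tss", "gene_id"], kind="stable").reset_index(drop=True)
        for chrom, g in genes.groupby("chrom")
    }
    for row in master.regions.itertuples(index=False):
        mid = (row.start + row.end) // 2
        g = by_chrom.get(row.chrom)
        if g is None:
            out.append((row.region_id, "distal", None, np.nan))
            continue
        tss = g["tss"].to_numpy()
        inside = (tss >= row.start) & (tss < row.end)
        if inside.any():
            cand = g[inside]
            best = cand.iloc[np.argmin(np.abs(cand["tss"].to_numpy() - mid))]
            out.append((row.region_id, "promoter-like", best["gene_id"], 0))
            continue
        dist = np.abs(tss - mid)
        best = g.iloc[int(np.argmin(dist))]
        signed = best["tss"] - mid if best["strand"] == "+" else mid - best["tss"]
        klass = "promoter-like" if abs(signed) <= promoter_window else "distal"
        out.append((row.region_id, klass, best["gene_id"], int(signed)))
    return pd.DataFrame(out, columns=["region_id", "class", "nearest_gene", "tss_distance"])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize_cohort(metadata: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Per-group cohort summary: category counts/percentages and numeric stats.

    Returns a long table (group, variable, level, count, percent, mean,
    median, min, max); percentages are rounded half-up to the nearest integer
    as in clinical summary tables.
    """
    if metadata.empty:
        raise ValueError("empty metadata table")
    if group_col not in metadata.columns:
        raise ValueError(f"grouping column {group_col!r} not present")
    rows = []
    for group, sub in metadata.groupby(group_col, sort=True):
        n = len(sub)
        rows.append((group, "n", None, n, None, None, None, None, None))
        for col in metadata.columns:
            if col == group_col:
                continue
            vals = sub[col].dropna()
            if pd.api.types.is_numeric_dtype(metadata[col]):
                if len(vals) == 0:
                    continue
                rows.append(
                    (
                        group, col, None, int(len(vals)), None,
                        float(vals.mean()), float(vals.median()),
                        float(vals.min()), float(vals.max()),
                    )
                )
            else:
                for level, cnt in vals.value_counts().sort_index().items():
                    pct = _round_half_up(100.0 * cnt / n)
                    rows.append((group, col, level, int(cnt), pct, None, None, None, None))
    return pd.DataFrame(
        rows,
        columns=["group", "variable", "level", "count", "percent", "mean", "median", "min", "max"],
    )


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    exons = {
        gid: (
            ",".join(str(s) for s in sub["start"]),
            ",".join(str(e) for e in sub["end"]),
        )
        for gid, sub in model.exons.groupby("gene_id")
    }
    rows = []
    for rec in model.genes.itertuples(index=False):
        es, ee = exons.get(rec.gene_id, ("", ""))
        rows.append((rec.gene_id, rec.chrom, rec.strand, rec.tss, es, ee))
    pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "tss", "exon_starts", "exon_ends"]
    ).to_csv(path, sep="\t", index=False)


def read_gene_model(path: str | Path) -> GeneModel:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    genes = df[["gene_id", "chrom", "strand", "tss"]].copy()
    ex_rows = []
    for rec in df.itertuples(index=False):
        if isinstance(rec.exon_starts, str) and rec.exon_starts:
            starts = [int(s) for s in rec.exon_starts.split(",")]
            ends = [int(e) for e in rec.exon_ends.split(",")]
            for s, e in zip(starts, ends):
                ex_rows.append((rec.gene_id, rec.chrom, s, e))
    exons = pd.DataFrame(ex_rows, columns=["gene_id", "chrom", "start", "end"])
    return GeneModel(genes=genes, exons=exons)
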