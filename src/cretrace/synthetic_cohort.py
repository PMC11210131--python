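"""Synthetic multi-stage chromatin-accessibility cohorts.

Generates everything the pipeline consumes, with the statistical structure the
analysis assumes: a four-stage cohort (healthy/onset/remission/relapse, 32
samples by default) whose master peak universe mixes

* ``core`` peaks detected in every sample (high penetrance, boosted mean),
* ``stage`` peaks private to one disease stage,
* ``dynamic`` peak patterns silent in healthy samples but active across
  disease stages with per-stage fold multipliers (the planted dynamic CREs),
* onset low-penetrance peaks sized so that a configurable fraction of
  onset-detected peaks is private or low-penetrant, and
* per-sample private peaks.

Read counts are negative binomial per (peak, sample) (variance mu + phi*mu^2)
on presence; absent peaks have count 0 and are omitted from that sample's
peak file.  Stage effects are planted multiplicatively on the NB mean.
Companion generators emit RNA fragments (75 bp intervals) with elevated
non-exonic coverage at flagged productive CREs in onset samples, BEDPE loops
with planted CRE-to-promoter anchors, annotation region sets, and a
dependency-score matrix with a labelled B-ALL lineage subset.

All generators are byte-deterministic under a fixed config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _intervals as iv
from .regions_io import STAGES, GeneModel, SampleRepertoire, write_gene_model


def _default_stage_peaks() -> dict[str, int]:
    return {"healthy": 30, "onset": 150, "remission": 30, "relapse": 100}


def _default_private_rate() -> dict[str, int]:
    return {"healthy": 2, "onset": 25, "remission": 2, "relapse": 5}


def _default_dynamic_patterns() -> dict[str, tuple[int, dict[str, float]]]:
    # Four healthy-silent activity shapes.  Detection support (which stages a
    # peak is present in) separates the two clades, intensity separates the
    # clusters within a clade: the onset/relapse-supported pair are the
    # "C1/C2-like" patterns that host the planted eRNA-productive CREs.
    return {
        "onset_relapse_strong": (60, {"onset": 1.0, "relapse": 1.0}),
        "onset_dominant": (60, {"onset": 1.0, "relapse": 0.35}),
        "relapse_remission": (60, {"onset": 0.25, "remission": 1.0, "relapse": 1.0}),
        "disease_wide": (60, {"onset": 1.0, "remission": 1.0, "relapse": 1.0}),
    }


@dataclass
class SyntheticCohortConfig:
    """Generator parameters; defaults are the study conditions used in tests."""

    n_healthy: int = 6
    n_onset: int = 11
    n_remission: int = 7
    n_relapse: int = 8
    genome: Sequence[tuple[str, int]] = (("chr1", 30_000_000), ("chr2", 20_000_000))
    n_core_peaks: int = 600
    n_stage_peaks: dict[str, int] = field(default_factory=_default_stage_peaks)
    dynamic_patterns: dict[str, tuple[int, dict[str, float]]] = field(
        default_factory=_default_dynamic_patterns
    )
    private_peak_rate: dict[str, int] = field(default_factory=_default_private_rate)
    peak_width_mean: int = 400
    nb_mean: float = 50.0
    nb_dispersion: float = 0.3
    promoter_fraction: float = 0.2
    frac_private_low_onset: float = 0.6
    low_penetrance_cut: int = 14
    effect_fold: float = 4.0
    core_mean_boost: float = 2.0
    stage_detect_prob: float = 0.95
    depth_sigma: float = 0.25
    n_genes: int = 150
    erna_base_rate_per_kb: float = 20.0
    erna_exon_rate_per_kb: float = 30.0
    erna_fold: float = 4.0
    erna_fragment_length: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_healthy, self.n_onset, self.n_remission, self.n_relapse)
        if any(c < 0 for c in counts):
            raise ValueError("sample counts must be >= 0")
        if sum(counts) == 0:
            raise ValueError("empty cohort")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for rate in (self.promoter_fraction, self.frac_private_low_onset,
                     self.stage_detect_prob):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def stage_sizes(self) -> dict[str, int]:
        return {
            "healthy": self.n_healthy,
            "onset": self.n_onset,
            "remission": self.n_remission,
            "relapse": self.n_relapse,
        }


@dataclass
class SimulatedCohort:
    config: SyntheticCohortConfig
    metadata: pd.DataFrame  # sample_id, stage, total_mapped_reads
    peaks: pd.DataFrame  # chrom, start, end, peak_id, peak_class, pattern
    presence: pd.DataFrame  # peaks x samples bool
    counts: pd.DataFrame  # peaks x samples int (0 where absent)
    gene_model: GeneModel

    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata["sample_id"])

    def groups(self) -> dict[str, list[str]]:
        return {
            stage: list(self.metadata.loc[self.metadata["stage"] == stage, "sample_id"])
            for stage in STAGES
            if (self.metadata["stage"] == stage).any()
        }

    def repertoires(self) -> list[SampleRepertoire]:
        reps = []
        for rec in self.metadata.itertuples(index=False):
            present = self.presence[rec.sample_id]
            peaks = self.peaks[present.to_numpy()][["chrom", "start", "end", "peak_id"]].copy()
            peaks["read_count"] = self.counts.loc[present.to_numpy(), rec.sample_id].to_numpy()
            reps.append(
                SampleRepertoire(
                    sample_id=rec.sample_id,
                    stage=rec.stage,
                    peaks=peaks.reset_index(drop=True),
                    total_mapped_reads=int(rec.total_mapped_reads),
                )
            )
        return reps

    def peaks_of_pattern(self, patterns: Sequence[str]) -> pd.Index:
        mask = self.peaks["pattern"].isin(patterns)
        return pd.Index(self.peaks.loc[mask, "peak_id"])


def _simulate_gene_model(config: SyntheticCohortConfig, rng: np.random.Generator) -> GeneModel:
    chroms = [c for c, _ in config.genome]
    lengths = np.array([l for _, l in config.genome], dtype=float)
    probs = lengths / lengths.sum()
    genes, exons = [], []
    for i in range(config.n_genes):
        gid = f"gene_{i + 1:04d}"
        ci = rng.choice(len(chroms), p=probs)
        chrom, clen = chroms[ci], int(lengths[ci])
        tss = int(rng.integers(50_000, clen - 50_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((gid, chrom, strand, tss))
        pos = tss
        for _ in range(int(rng.integers(2, 5))):
            ex_len = int(rng.integers(150, 400))
            if strand == "+":
                exons.append((gid, chrom, pos, pos + ex_len))
                pos += ex_len + int(rng.integers(500, 3000))
            else:
                exons.append((gid, chrom, pos - ex_len, pos))
                pos -= ex_len + int(rng.integers(500, 3000))
    return GeneModel(
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "strand", "tss"]),
        exons=pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end"]).sort_values(
            ["chrom", "start"], kind="stable"
        ).reset_index(drop=True),
    )


def _place_peaks(
    n: int,
    config: SyntheticCohortConfig,
    gene_model: GeneModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Disjoint peak placement (>= 1 bp apart), a fraction near TSSs."""
    chroms = [c for c, _ in config.genome]
    lengths = {c: l for c, l in config.genome}
    probs = np.array([lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    n_prom = int(round(config.promoter_fraction * n))
    tss_tab = gene_model.genes
    # sorted start/end lists per chromosome for bisect-based collision checks
    starts: dict[str, list[int]] = {c: [] for c in chroms}
    ends: dict[str, list[int]] = {c: [] for c in chroms}
    rows = []
    attempts = 0
    from bisect import bisect_left

    while len(rows) < n and attempts < 50 * n:
        attempts += 1
        width = max(100, int(rng.normal(config.peak_width_mean, 0.15 * config.peak_width_mean)))
        if len(rows) < n_prom and len(tss_tab):
            g = tss_tab.iloc[int(rng.integers(len(tss_tab)))]
            chrom = g["chrom"]
            center = int(g["tss"] + rng.integers(-4500, 4501))
            start = max(1, center - width // 2)
        else:
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            start = int(rng.integers(1, lengths[chrom] - width - 1))
        end = start + width
        # keep a >= 1 bp gap to the flanking placed peaks on this chromosome
        i = bisect_left(starts[chrom], start)
        if i > 0 and ends[chrom][i - 1] >= start:
            continue
        if i < len(starts[chrom]) and starts[chrom][i] <= end:
            continue
        starts[chrom].insert(i, start)
        ends[chrom].insert(i, end)
        rows.append((chrom, start, end))
    if len(rows) < n:
        raise RuntimeError("could not place disjoint peaks; enlarge the genome")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _peak_plan(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Per-peak class/pattern plan implementing the penetrance architecture."""
    f = config.frac_private_low_onset
    n_dynamic_onset = sum(
        n for n, mult in config.dynamic_patterns.values() if mult.get("onset", 0) > 0
    )
    high_onset = config.n_core_peaks + n_dynamic_onset
    n_stage_onset = config.n_stage_peaks.get("onset", 0) if config.n_onset else 0
    n_priv_onset = config.private_peak_rate.get("onset", 0) * config.n_onset
    if f >= 1.0:
        raise ValueError("frac_private_low_onset must be < 1")
    n_lowpen = max(0, int(round(f / (1 - f) * high_onset)) - n_stage_onset - n_priv_onset)

    rows: list[tuple[str, str]] = []
    rows += [("core", "core")] * config.n_core_peaks
    for stage, n_stage in config.n_stage_peaks.items():
        if config.stage_sizes.get(stage, 0) > 0:
            rows += [("stage", stage)] * n_stage
    for name, (n_pat, _mult) in config.dynamic_patterns.items():
        rows += [("dynamic", name)] * n_pat
    if config.n_onset:
        rows += [("onset_lowpen", "onset_lowpen")] * n_lowpen
    for stage, rate in config.private_peak_rate.items():
        rows += [("private", stage)] * (rate * config.stage_sizes.get(stage, 0))
    return pd.DataFrame(rows, columns=["peak_class", "pattern"])


def simulate_cohort(config: SyntheticCohortConfig) -> SimulatedCohort:
    """Generate peaks, presence, NB counts, metadata and a gene model."""
    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_place, rng_presence, rng_counts, rng_depth = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    gene_model = _simulate_gene_model(config, rng_genes)
    plan = _peak_plan(config)
    coords = _place_peaks(len(plan), config, gene_model, rng_place)
    # classes are assigned to placed coordinates in a random order so that no
    # class occupies a systematic position along the genome
    order = rng_place.permutation(len(plan))
    peaks = coords.copy()
    peaks["peak_class"] = plan["peak_class"].to_numpy()[order]
    peaks["pattern"] = plan["pattern"].to_numpy()[order]
    width = max(6, len(str(len(peaks))))
    peaks["peak_id"] = [f"peak_{i:0{width}d}" for i in range(1, len(peaks) + 1)]
    peaks = peaks[["chrom", "start", "end", "peak_id", "peak_class", "pattern"]]

    sample_ids, stages = [], []
    for stage in STAGES:
        for i in range(config.stage_sizes[stage]):
            sample_ids.append(f"{stage[:3]}_{i + 1:02d}")
            stages.append(stage)
    stage_of = dict(zip(sample_ids, stages))
    cols_by_stage = {
        stage: [s for s in sample_ids if stage_of[s] == stage] for stage in STAGES
    }

    n_pk, n_sm = len(peaks), len(sample_ids)
    presence = np.zeros((n_pk, n_sm), dtype=bool)
    mean_mult = np.zeros((n_pk, n_sm), dtype=float)
    col_of = {s: j for j, s in enumerate(sample_ids)}
    detect = config.stage_detect_prob

    def _bernoulli_cols(cols: list[str], i: int, mult: float) -> None:
        for s in cols:
            if rng_presence.random() < detect:
                presence[i, col_of[s]] = True
                mean_mult[i, col_of[s]] = mult
        if cols and not presence[i, [col_of[s] for s in cols]].any():
            s = cols[int(rng_presence.integers(len(cols)))]
            presence[i, col_of[s]] = True
            mean_mult[i, col_of[s]] = mult

    priv_cursor: dict[str, int] = {stage: 0 for stage in STAGES}
    for i, rec in enumerate(peaks.itertuples(index=False)):
        if rec.peak_class == "core":
            presence[i, :] = True
            mean_mult[i, :] = config.core_mean_boost
        elif rec.peak_class == "stage":
            _bernoulli_cols(cols_by_stage[rec.pattern], i, config.effect_fold)
        elif rec.peak_class == "dynamic":
            _n, mults = config.dynamic_patterns[rec.pattern]
            for stage, m in mults.items():
                if m > 0:
                    _bernoulli_cols(cols_by_stage[stage], i, config.effect_fold * m)
        elif rec.peak_class == "onset_lowpen":
            onset_cols = cols_by_stage["onset"]
            hi = min(config.low_penetrance_cut, len(onset_cols))
            m = int(rng_presence.integers(1, hi + 1))
            chosen = rng_presence.choice(len(onset_cols), size=m, replace=False)
            for j in chosen:
                presence[i, col_of[onset_cols[j]]] = True
                mean_mult[i, col_of[onset_cols[j]]] = 1.0
        elif rec.peak_class == "private":
            cols = cols_by_stage[rec.pattern]
            s = cols[priv_cursor[rec.pattern] % len(cols)]
            priv_cursor[rec.pattern] += 1
            presence[i, col_of[s]] = True
            mean_mult[i, col_of[s]] = 1.0

    depth = np.exp(rng_depth.normal(0.0, config.depth_sigma, size=n_sm))
    mu = config.nb_mean * mean_mult * depth[None, :]
    r = 1.0 / config.nb_dispersion
    counts = np.zeros((n_pk, n_sm), dtype=int)
    pres_idx = np.nonzero(presence)
    mu_p = mu[pres_idx]
    p = r / (r + mu_p)
    draws = rng_counts.negative_binomial(r, p)
    counts[pres_idx] = np.maximum(1, draws)  # present peaks keep a positive count

    total_mapped = np.maximum(1, (1e7 * depth)).astype(np.int64)
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "stage": stages,
            "total_mapped_reads": total_mapped,
        }
    )
    idx = pd.Index(peaks["peak_id"], name="peak_id")
    return SimulatedCohort(
        config=config,
        metadata=metadata,
        peaks=peaks,
        presence=pd.DataFrame(presence, index=idx, columns=sample_ids),
        counts=pd.DataFrame(counts, index=idx, columns=sample_ids),
        gene_model=gene_model,
    )


def simulate_rna_erna(
    config: SyntheticCohortConfig,
    cres: pd.DataFrame,
    gene_model: GeneModel,
    metadata: pd.DataFrame,
    productive_ids: Sequence[str] = (),
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """RNA fragment intervals per sample.

    Exons get baseline gene-derived fragments in every sample; the non-exonic
    part of each CRE gets baseline enhancer transcription, elevated by
    ``config.erna_fold`` at productive CREs in onset-stage samples.  Fragments
    are fixed-length intervals (paired ends collapsed to one interval).
    """
    cre_ids = set(cres["region_id"])
    stray = set(productive_ids) - cre_ids
    if stray:
        raise ValueError(f"productive subset not contained in cre_regions: {sorted(stray)[:5]}")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    flen = config.erna_fragment_length
    eligible = iv.subtract(cres[["chrom", "start", "end", "region_id"]], gene_model.exons)
    productive = set(productive_ids)
    out: dict[str, pd.DataFrame] = {}
    for rec in metadata.itertuples(index=False):
        rows = []
        for ex in gene_model.exons.itertuples(index=False):
            lam = config.erna_exon_rate_per_kb * (ex.end - ex.start) / 1000.0
            for _ in range(rng.poisson(lam)):
                lo = ex.start
                hi = max(lo + 1, ex.end - flen)
                s = int(rng.integers(lo, hi))
                rows.append((ex.chrom, s, min(s + flen, ex.end)))
        for piece in eligible.itertuples(index=False):
            lam = config.erna_base_rate_per_kb * (piece.end - piece.start) / 1000.0
            if piece.region_id in productive and rec.stage == "onset":
                lam *= config.erna_fold
            for _ in range(rng.poisson(lam)):
                lo = piece.start
                hi = max(lo + 1, piece.end - flen)
                s = int(rng.integers(lo, hi))
                rows.append((piece.chrom, s, min(s + flen, piece.end)))
        frags = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        out[rec.sample_id] = frags.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )
    return out


def simulate_loops_and_dependency(
    config: SyntheticCohortConfig,
    cres: pd.DataFrame,
    gene_model: GeneModel,
    n_planted_links: int = 30,
    n_random_loops: int = 120,
    n_cell_lines: int = 120,
    n_interest_lines: int = 11,
    interest_label: str = "B-ALL",
    essential_offset: float = 1.5,
    score_sd: float = 0.3,
    planted_links: Sequence[tuple[str, str]] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]], pd.DataFrame, pd.Series]:
    """Planted CRE-to-promoter loops plus a dependency matrix.

    Returns (loops BEDPE frame, planted (cre_id, gene_id) links, genes x
    cell-lines score frame, cell-line -> lineage labels).  Scores of the
    planted genes are shifted down by ``essential_offset`` in the
    ``interest_label`` lines; offset 0 gives an exchangeable null.
    """
    genes = gene_model.genes
    if genes.empty:
        raise ValueError("gene model is empty")
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    if planted_links is None:
        n_combo = len(cres) * len(genes)
        if n_planted_links > n_combo:
            raise ValueError(
                f"requested {n_planted_links} loops but only {n_combo} CRE x gene combinations"
            )
        pairs = set()
        while len(pairs) < n_planted_links:
            c = cres["region_id"].iloc[int(rng.integers(len(cres)))]
            g = genes["gene_id"].iloc[int(rng.integers(len(genes)))]
            pairs.add((c, g))
        planted_links = sorted(pairs)
    else:
        planted_links = list(planted_links)
        if len(planted_links) > len(cres) * len(genes):
            raise ValueError("requested loops exceed CRE x gene combinations")

    cre_by_id = cres.set_index("region_id")
    gene_by_id = genes.set_index("gene_id")
    resolutions = np.array([5000, 10000, 25000])
    rows = []
    for cre_id, gene_id in planted_links:
        c = cre_by_id.loc[cre_id]
        g = gene_by_id.loc[gene_id]
        tss = int(g["tss"])
        rows.append(
            (
                c["chrom"], int(c["start"]), int(c["end"]),
                g["chrom"], max(0, tss - 1000), tss + 1000,
                f"planted_{cre_id}_{gene_id}",
                int(resolutions[int(rng.integers(3))]),
            )
        )
    # random promoter-promoter and CRE-CRE loops on shared chromosomes
    for _ in range(n_random_loops):
        if rng.random() < 0.5 and len(genes) >= 2:
            g1, g2 = genes.iloc[rng.choice(len(genes), size=2, replace=False)].itertuples(
                index=False
            )
            if g1.chrom != g2.chrom:
                continue
            rows.append(
                (
                    g1.chrom, max(0, g1.tss - 1000), g1.tss + 1000,
                    g2.chrom, max(0, g2.tss - 1000), g2.tss + 1000,
                    "random_pp", int(resolutions[int(rng.integers(3))]),
                )
            )
        elif len(cres) >= 2:
            c1, c2 = cres.iloc[rng.choice(len(cres), size=2, replace=False)].itertuples(
                index=False
            )
            if c1.chrom != c2.chrom:
                continue
            rows.append(
                (
                    c1.chrom, int(c1.start), int(c1.end),
                    c2.chrom, int(c2.start), int(c2.end),
                    "random_cc", int(resolutions[int(rng.integers(3))]),
                )
            )
    loops = pd.DataFrame(
        rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "resolution"],
    )
    swap = (loops["chrom1"] == loops["chrom2"]) & (loops["start1"] > loops["start2"])
    for a, b in (("chrom1", "chrom2"), ("start1", "start2"), ("end1", "end2")):
        loops.loc[swap, [a, b]] = loops.loc[swap, [b, a]].to_numpy()

    lines = [f"{interest_label}_{i + 1:02d}" for i in range(n_interest_lines)] + [
        f"line_{i + 1:03d}" for i in range(n_cell_lines - n_interest_lines)
    ]
    lineage = pd.Series(
        [interest_label] * n_interest_lines
        + [f"other_{i % 7}" for i in range(n_cell_lines - n_interest_lines)],
        index=lines,
        name="lineage",
    )
    scores = pd.DataFrame(
        rng.normal(0.0, score_sd, size=(len(genes), n_cell_lines)),
        index=pd.Index(genes["gene_id"], name="gene"),
        columns=lines,
    )
    essential = sorted({g for _, g in planted_links})
    scores.loc[essential, lineage.index[lineage == interest_label]] -= essential_offset
    return loops, list(planted_links), scores, lineage


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Serialise cohort inputs: BED6 peaks per sample, TSV metadata/counts/genes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    peak_paths = []
    for rep in cohort.repertoires():
        p = outdir / f"{rep.sample_id}.bed"
        bed = rep.peaks.copy()
        bed["strand"] = "."
        bed[["chrom", "start", "end", "peak_id", "read_count", "strand"]].to_csv(
            p, sep="\t", header=False, index=False
        )
        peak_paths.append(p)
    paths["peaks"] = peak_paths  # type: ignore[assignment]
    meta = outdir / "metadata.tsv"
    cohort.metadata.to_csv(meta, sep="\t", index=False)
    paths["metadata"] = meta
    counts = outdir / "counts.tsv"
    cohort.counts.to_csv(counts, sep="\t")
    paths["counts"] = counts
    genes = outdir / "gene_model.tsv"
    write_gene_model(cohort.gene_model, genes)
    paths["gene_model"] = genes
    truth = outdir / "peak_truth.tsv"
    cohort.peaks.to_csv(truth, sep="\t", index=False)
    paths["truth"] = truth
    return paths


def simulate_annotation_sets(
    cohort: SimulatedCohort,
    productive_ids: Sequence[str],
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """External-style annotation BED sets consistent with the planted truth.

    The cell-line peak set mirrors a disease-derived cell line: it carries
    every planted dynamic peak plus a sample of core peaks.  The enhancer
    annotation covers the productive CREs (plus random others); the
    super-enhancer set covers a random slice of disease-active peaks,
    widened.
    """
    rng = np.random.default_rng(cohort.config.seed + 3 if seed is None else seed)
    peaks = cohort.peaks
    dyn = peaks[peaks["peak_class"] == "dynamic"]
    core = peaks[peaks["peak_class"] == "core"]
    prod = peaks[peaks["peak_id"].isin(set(productive_ids))]

    cellline = pd.concat(
        [dyn, core.iloc[rng.choice(len(core), size=len(core) // 2, replace=False)]]
    )[["chrom", "start", "end"]]
    n_extra = min(50, len(peaks))
    extra = peaks.iloc[rng.choice(len(peaks), size=n_extra, replace=False)]
    erna_annot = pd.concat([prod, extra])[["chrom", "start", "end"]].drop_duplicates()
    n_se = max(1, len(dyn) // 6)
    se = dyn.iloc[rng.choice(len(dyn), size=n_se, replace=False)][
        ["chrom", "start", "end"]
    ].copy()
    se["start"] = np.maximum(0, se["start"] - 2000)
    se["end"] = se["end"] + 2000
    return {
        "erna_annotation": erna_annot.sort_values(["chrom", "start"]).reset_index(drop=True),
        "super_enhancers": se.sort_values(["chrom", "start"]).reset_index(drop=True),
        "cellline_peaks": cellline.sort_values(["chrom", "start"]).reset_index(drop=True),
    }
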