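import numpy as np
import pandas as pd
import pytest

from cretrace.regions_io import MasterList, SampleRepertoire, build_master_list
from cretrace.synthetic_cohort import SyntheticCohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default 32-sample four-stage synthetic cohort (study conditions)."""
    return simulate_cohort(SyntheticCohortConfig(seed=20240627))


@pytest.fixture(scope="session")
def default_master(default_cohort):
    reps = default_cohort.repertoires()
    return reps, build_master_list(reps)


def random_peaks(rng, n, chroms=("chr1", "chr2"), span=1_000_000, max_len=5000):
    """Random (possibly overlapping) intervals for oracle comparisons."""
    chrom = rng.choice(chroms, size=n)
    start = rng.integers(0, span, size=n)
    length = rng.integers(1, max_len, size=n)
    return pd.DataFrame({"chrom": chrom, "start": start, "end": start + length})


def naive_union_merge(df):
    """O(n^2)-style single-linkage union of intervals overlapping >= 1 bp."""
    out = []
    for chrom, sub in df.groupby("chrom"):
        ivs = sorted((int(s), int(e)) for s, e in zip(sub["start"], sub["end"]))
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s < cur_e:  # strict overlap, bookended intervals stay apart
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return (
        pd.DataFrame(out, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )


def make_repertoire(sample_id, stage, peaks, total=10_000_000):
    peaks = peaks.copy().reset_index(drop=True)
    if "peak_id" not in peaks:
        peaks["peak_id"] = [f"{sample_id}_p{i}" for i in range(len(peaks))]
    if "read_count" not in peaks:
        peaks["read_count"] = 10
    return SampleRepertoire(
        sample_id=sample_id, stage=stage, peaks=peaks, total_mapped_reads=total
    )


def master_from_regions(regions):
    """MasterList straight from already-disjoint regions (empty provenance)."""
    regions = regions.copy().reset_index(drop=True)
    if "region_id" not in regions:
        regions["region_id"] = [f"r{i:05d}" for i in range(len(regions))]
    return MasterList(
        regions=regions[["chrom", "start", "end", "region_id"]],
        provenance=pd.DataFrame(columns=["region_id", "sample_id", "peak_id"]),
    )
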