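"""Cohort ingestion, master-list merging, counting, annotation, summaries."""

import numpy as np
import pandas as pd
import pytest

from cretrace.regions_io import (
    GeneModel,
    annotate_regions,
    build_count_matrix,
    build_master_list,
    read_cohort,
    summarize_cohort,
)

from conftest import (
    make_repertoire,
    master_from_regions,
    naive_union_merge,
    random_peaks,
)


def _write_bed(path, rows):
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def _write_meta(path, rows):
    pd.DataFrame(rows, columns=["sample_id", "stage", "total_mapped_reads"]).to_csv(
        path, sep="\t", index=False
    )


class TestReadCohort:
    def test_empty_cohort_rejected(self, tmp_path):
        _write_meta(tmp_path / "meta.tsv", [])
        with pytest.raises(ValueError, match="empty cohort"):
            read_cohort([], tmp_path / "meta.tsv")

    def test_line_counts_become_repertoire_sizes(self, tmp_path):
        sizes = {"a": 10, "b": 20, "c": 30}
        paths = []
        for name, n in sizes.items():
            p = tmp_path / f"{name}.bed"
            _write_bed(p, [("chr1", 1000 * i, 1000 * i + 500, f"pk{i}", 7) for i in range(n)])
            paths.append(p)
        _write_meta(
            tmp_path / "meta.tsv",
            [("a", "healthy", 1e6), ("b", "onset", 1e6), ("c", "relapse", 1e6)],
        )
        reps = read_cohort(paths, tmp_path / "meta.tsv")
        assert {r.sample_id: len(r.peaks) for r in reps} == sizes
        assert all((r.peaks["read_count"] == 7).all() for r in reps)

    def test_malformed_lines_reported_with_numbers(self, tmp_path):
        p = tmp_path / "a.bed"
        with open(p, "w") as fh:
            fh.write("chr1\t100\t200\tpk1\t5\n")
            fh.write("chr1\tnot_a_number\t300\n")
            fh.write("chr1\t500\t400\tpk3\t5\n")  # start >= end
        _write_meta(tmp_path / "meta.tsv", [("a", "healthy", 1e6)])
        with pytest.raises(ValueError, match=r"\[2, 3\]"):
            read_cohort([p], tmp_path / "meta.tsv")

    def test_unknown_stage_and_duplicate_sample_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        _write_bed(p, [("chr1", 0, 100, "pk", 1)])
        _write_meta(tmp_path / "meta.tsv", [("a", "cured", 1e6)])
        with pytest.raises(ValueError, match="unknown stage"):
            read_cohort([p], tmp_path / "meta.tsv")
        q = tmp_path / "b.bed"
        _write_bed(q, [("chr1", 0, 100, "pk", 1)])
        pd.DataFrame(
            [("a", "healthy", 1e6), ("a", "onset", 1e6)],
            columns=["sample_id", "stage", "total_mapped_reads"],
        ).to_csv(tmp_path / "meta2.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="duplicate sample_id"):
            read_cohort([p, q], tmp_path / "meta2.tsv")

    def test_full_cohort_roundtrip_preserves_stage_counts(self, tmp_path, default_cohort):
        from cretrace.synthetic_cohort import write_cohort

        paths = write_cohort(default_cohort, tmp_path)
        reps = read_cohort(paths["peaks"], paths["metadata"])
        assert len(reps) == 32
        stage_counts = pd.Series([r.stage for r in reps]).value_counts().to_dict()
        assert stage_counts == {"onset": 11, "relapse": 8, "remission": 7, "healthy": 6}


class TestMasterList:
    def test_single_sample_disjoint_is_identity(self):
        peaks = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [0, 200, 500], "end": [100, 300, 900]}
        )
        master = build_master_list([make_repertoire("s1", "onset", peaks)])
        assert master.regions[["start", "end"]].to_numpy().tolist() == [
            [0, 100], [200, 300], [500, 900],
        ]

    def test_two_sample_overlap_merges(self):
        r1 = make_repertoire(
            "s1", "onset", pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        )
        r2 = make_repertoire(
            "s2", "relapse", pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [250]})
        )
        master = build_master_list([r1, r2])
        assert len(master.regions) == 1
        assert master.regions.iloc[0][["start", "end"]].tolist() == [100, 250]
        assert set(master.provenance["sample_id"]) == {"s1", "s2"}

    def test_bookended_peaks_stay_separate(self):
        peaks = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [100, 200], "end": [200, 300]})
        master = build_master_list([make_repertoire("s1", "onset", peaks)])
        assert len(master.regions) == 2

    def test_matches_naive_union_oracle(self):
        rng = np.random.default_rng(7)
        peaks = random_peaks(rng, 1000)
        reps = [
            make_repertoire(f"s{i}", "onset", peaks.iloc[i::4]) for i in range(4)
        ]
        master = build_master_list(reps)
        expected = naive_union_merge(peaks)
        got = master.regions[["chrom", "start", "end"]].reset_index(drop=True)
        pd.testing.assert_frame_equal(got, expected, check_dtype=False)

    def test_provenance_covers_every_peak_exactly_once(self):
        rng = np.random.default_rng(8)
        peaks = random_peaks(rng, 300)
        reps = [make_repertoire(f"s{i}", "onset", peaks.iloc[i::3]) for i in range(3)]
        master = build_master_list(reps)
        n_peaks = sum(len(r.peaks) for r in reps)
        # regions are disjoint, so each peak overlaps exactly one region
        assert len(master.provenance) == n_peaks
        # and every peak lies fully inside its region (union property)
        regs = master.regions.set_index("region_id")
        for rep in reps:
            prov = master.provenance[master.provenance["sample_id"] == rep.sample_id]
            merged = prov.merge(rep.peaks, on="peak_id")
            r = regs.loc[merged["region_id"]]
            assert (merged["start"].to_numpy() >= r["start"].to_numpy()).all()
            assert (merged["end"].to_numpy() <= r["end"].to_numpy()).all()


class TestCountMatrix:
    def test_peak_transfer_and_zero_column(self):
        r1 = make_repertoire(
            "s1", "onset",
            pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 150], "end": [120, 260],
                          "read_count": [5, 9]}),
        )
        r2 = make_repertoire(
            "s2", "healthy",
            pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100], "read_count": [3]}),
        )
        master = build_master_list([r1, r2])
        mat = build_count_matrix(master, [r1, r2])
        chr1_ids = master.regions.loc[master.regions["chrom"] == "chr1", "region_id"]
        assert (mat.loc[chr1_ids, "s2"] == 0).all()
        assert mat.loc[chr1_ids, "s1"].sum() == 14

    def test_fragment_counting_matches_brute_force(self):
        rng = np.random.default_rng(9)
        regions = master_from_regions(
            pd.DataFrame({"chrom": ["chr1"] * 5, "start": [0, 1000, 2000, 3000, 4000],
                          "end": [500, 1500, 2500, 3500, 4500]})
        )
        rep = make_repertoire("s1", "onset", regions.regions.rename(columns={"region_id": "peak_id"}))
        frags = random_peaks(rng, 200, chroms=("chr1",), span=5000, max_len=300)
        mat = build_count_matrix(regions, [rep], fragments={"s1": frags})
        for _, r in regions.regions.iterrows():
            naive = int(((frags["start"] < r["end"]) & (frags["end"] > r["start"])).sum())
            assert mat.loc[r["region_id"], "s1"] == naive

    def test_fragment_spanning_two_regions_counts_in_both(self):
        regions = master_from_regions(
            pd.DataFrame({"chrom": ["chr1"] * 2, "start": [0, 200], "end": [100, 300]})
        )
        rep = make_repertoire("s1", "onset", regions.regions.rename(columns={"region_id": "peak_id"}))
        frag = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [250]})
        mat = build_count_matrix(regions, [rep], fragments={"s1": frag})
        assert mat["s1"].tolist() == [1, 1]

    def test_unknown_fragment_sample_rejected(self):
        regions = master_from_regions(
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        )
        rep = make_repertoire("s1", "onset", regions.regions.rename(columns={"region_id": "peak_id"}))
        with pytest.raises(ValueError, match="unknown sample"):
            build_count_matrix(regions, [rep], fragments={"sX": pd.DataFrame()})

    def test_counting_is_sample_order_invariant(self):
        rng = np.random.default_rng(10)
        peaks = random_peaks(rng, 100)
        peaks["read_count"] = rng.integers(1, 50, size=len(peaks))
        reps = [make_repertoire(f"s{i}", "onset", peaks.iloc[i::2]) for i in range(2)]
        master = build_master_list(reps)
        a = build_count_matrix(master, reps)
        b = build_count_matrix(master, reps[::-1])
        pd.testing.assert_frame_equal(a, b[a.columns])


class TestAnnotateRegions:
    @staticmethod
    def _model(tss=100_000, strand="+"):
        return GeneModel(
            genes=pd.DataFrame(
                {"gene_id": ["g1"], "chrom": ["chr1"], "strand": [strand], "tss": [tss]}
            ),
            exons=pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]),
        )

    @pytest.mark.parametrize(
        "mid_offset,expected", [(4999, "promoter-like"), (5000, "promoter-like"), (5001, "distal")]
    )
    def test_promoter_window_boundary(self, mid_offset, expected):
        # region of width 2 centred mid_offset bp downstream of the TSS
        start = 100_000 + mid_offset - 1
        master = master_from_regions(
            pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [start + 2]})
        )
        ann = annotate_regions(master, self._model())
        assert ann.iloc[0]["class"] == expected

    def test_signed_distance_follows_strand(self):
        master = master_from_regions(
            pd.DataFrame({"chrom": ["chr1"], "start": [102_999], "end": [103_001]})
        )
        plus = annotate_regions(master, self._model(strand="+"))
        minus = annotate_regions(master, self._model(strand="-"))
        assert plus.iloc[0]["tss_distance"] == -3000  # TSS upstream of midpoint
        assert minus.iloc[0]["tss_distance"] == 3000

    def test_tss_inside_region_gives_zero(self):
        master = master_from_regions(
            pd.DataFrame({"chrom": ["chr1"], "start": [99_000], "end": [101_000]})
        )
        ann = annotate_regions(master, self._model())
        assert ann.iloc[0]["tss_distance"] == 0
        assert ann.iloc[0]["class"] == "promoter-like"

    def test_nearest_gene_matches_exhaustive_search(self):
        rng = np.random.default_rng(11)
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(20)],
                "chrom": "chr1",
                "strand": "+",
                "tss": np.sort(rng.choice(np.arange(0, 1_000_000), size=20, replace=False)),
            }
        )
        model = GeneModel(genes=genes, exons=pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]))
        regions = random_peaks(rng, 200, chroms=("chr1",), span=1_000_000, max_len=2000)
        master = master_from_regions(naive_union_merge(regions))
        ann = annotate_regions(master, model).set_index("region_id")
        for _, r in master.regions.iterrows():
            mid = (r["start"] + r["end"]) // 2
            inside = genes[(genes["tss"] >= r["start"]) & (genes["tss"] < r["end"])]
            if len(inside):
                assert ann.loc[r["region_id"], "tss_distance"] == 0
                continue
            d = (genes["tss"] - mid).abs()
            assert abs(ann.loc[r["region_id"], "tss_distance"]) == d.min()

    def test_empty_gene_model_rejected(self):
        master = master_from_regions(
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        )
        empty = GeneModel(
            genes=pd.DataFrame(columns=["gene_id", "chrom", "strand", "tss"]),
            exons=pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]),
        )
        with pytest.raises(ValueError, match="empty gene model"):
            annotate_regions(master, empty)


class TestSummarizeCohort:
    def test_clinical_table_worked_examples(self):
        # 30 newly diagnosed (21 male), and the relapsed patients' ages at relapse
        newly = pd.DataFrame(
            {
                "group": "newly_diagnosed",
                "sex": ["M"] * 21 + ["F"] * 9,
                "abnormality": ["t(12;21)"] * 6 + ["none"] * 24,
            }
        )
        relapse_ages = [6, 23, 5, 15, 15, 14, 20, 6, 7, 6]
        relapsed = pd.DataFrame(
            {
                "group": "relapsed",
                "sex": ["M"] * 8 + ["F"] * 2,
                "age_at_relapse": relapse_ages,
            }
        )
        meta = pd.concat([newly, relapsed], ignore_index=True)
        summ = summarize_cohort(meta, group_col="group")
        males = summ[
            (summ["group"] == "newly_diagnosed") & (summ["variable"] == "sex") & (summ["level"] == "M")
        ].iloc[0]
        assert males["count"] == 21 and males["percent"] == 70
        t1221 = summ[
            (summ["group"] == "newly_diagnosed")
            & (summ["variable"] == "abnormality")
            & (summ["level"] == "t(12;21)")
        ].iloc[0]
        assert t1221["percent"] == 20
        ages = summ[(summ["group"] == "relapsed") & (summ["variable"] == "age_at_relapse")].iloc[0]
        assert ages["mean"] == pytest.approx(11.7)
        assert (ages["min"], ages["max"]) == (5, 23)

    def test_percent_rounding_half_up(self):
        meta = pd.DataFrame({"group": ["g"] * 8, "flag": ["y", "y", "y"] + ["n"] * 5})
        summ = summarize_cohort(meta)
        y = summ[(summ["variable"] == "flag") & (summ["level"] == "y")].iloc[0]
        assert y["percent"] == 38  # 37.5 rounds half-up

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_cohort(pd.DataFrame(columns=["group"]))
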