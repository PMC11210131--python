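"""Non-exonic eRNA counting, productive-CRE calling, overlaps and tiers."""

import numpy as np
import pandas as pd
import pytest

from cretrace.erna_enhancers import (
    CANDIDATE_TIER,
    classify_enhancer_tiers,
    erna_quantify,
    overlap_frequency,
    productive_cres,
)

from conftest import random_peaks


def _cres(coords):
    df = pd.DataFrame(coords, columns=["chrom", "start", "end"])
    df["region_id"] = [f"cre{i}" for i in range(len(df))]
    return df


def _iv(chrom, start, end):
    return pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})


class TestErnaQuantify:
    def test_cre_inside_exon_has_zero_eligibility(self):
        cres = _cres([("chr1", 100, 200)])
        exons = _iv("chr1", 0, 1000)
        frags = {"s1": _iv("chr1", 120, 180)}
        em = erna_quantify(cres, exons, frags)
        assert em.eligible_length["cre0"] == 0
        assert em.counts.loc["cre0", "s1"] == 0

    def test_exon_subtraction_worked_example(self):
        # CRE [0,1000) with exon [400,600): fragment at 100-175 counts,
        # fragment at 450-525 (entirely exonic) does not
        cres = _cres([("chr1", 0, 1000)])
        exons = _iv("chr1", 400, 600)
        frags = {
            "s1": pd.DataFrame(
                {"chrom": ["chr1", "chr1"], "start": [100, 450], "end": [175, 525]}
            )
        }
        em = erna_quantify(cres, exons, frags)
        assert em.eligible_length["cre0"] == 800
        assert em.counts.loc["cre0", "s1"] == 1

    def test_fragment_on_two_eligible_pieces_counts_once(self):
        cres = _cres([("chr1", 0, 1000)])
        exons = _iv("chr1", 400, 420)
        frags = {"s1": _iv("chr1", 350, 500)}  # spans the small exon
        em = erna_quantify(cres, exons, frags)
        assert em.counts.loc["cre0", "s1"] == 1

    def test_no_fragments_gives_zero_matrix(self):
        cres = _cres([("chr1", 0, 500), ("chr2", 0, 500)])
        exons = _iv("chr1", 10_000, 10_100)
        em = erna_quantify(cres, exons, {"s1": pd.DataFrame(columns=["chrom", "start", "end"])})
        assert (em.counts == 0).all().all()

    def test_counts_additive_over_disjoint_partition(self):
        rng = np.random.default_rng(0)
        whole = _cres([("chr1", 0, 10_000)])
        halves = _cres([("chr1", 0, 5000), ("chr1", 5000, 10_000)])
        exons = _iv("chr1", 2000, 2500)
        # fragments short and away from the split point, so none spans it
        starts = rng.integers(0, 9900, size=300)
        starts = starts[np.abs(starts - 5000) > 200]
        frags = {"s1": pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 80})}
        a = erna_quantify(whole, exons, frags).counts["s1"].sum()
        b = erna_quantify(halves, exons, frags).counts["s1"].sum()
        assert a == b


class TestProductiveCres:
    @staticmethod
    def _matrix(rng, n_cre=300, n_per_group=4, planted=0, fold=4.0):
        cols = [f"h{i}" for i in range(n_per_group)] + [f"o{i}" for i in range(n_per_group)]
        lam = np.full((n_cre, len(cols)), 20.0)
        if planted:
            lam[:planted, n_per_group:] *= fold
        counts = pd.DataFrame(
            rng.poisson(lam), index=[f"cre{i}" for i in range(n_cre)], columns=cols
        )
        return counts, cols[:n_per_group], cols[n_per_group:]

    def test_null_selection_rate_bounded_by_fdr(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(10):
            counts, ga, gb = self._matrix(rng)
            ids, _ = productive_cres(counts, ga, gb, fdr_cut=0.05)
            hits += len(ids)
        assert hits / (10 * 300) <= 0.05 + 0.02

    def test_planted_fold4_recovered(self):
        rng = np.random.default_rng(2)
        counts, ga, gb = self._matrix(rng, planted=50, fold=4.0)
        ids, res = productive_cres(counts, ga, gb)
        planted = {f"cre{i}" for i in range(50)}
        assert len(planted & set(ids)) / 50 >= 0.90
        # and no flood of false calls
        assert len(set(ids) - planted) <= 5

    def test_empty_group_rejected(self):
        rng = np.random.default_rng(3)
        counts, ga, _ = self._matrix(rng, n_cre=10)
        with pytest.raises(ValueError):
            productive_cres(counts, ga, [])


class TestOverlapFrequency:
    def test_identity_and_disjoint(self):
        targets = _cres([("chr1", 0, 100), ("chr1", 500, 600)])
        same = targets[["chrom", "start", "end"]]
        far = _iv("chr2", 0, 100)
        freq = overlap_frequency(targets, {"self": same, "far": far})
        by = freq.set_index("feature_set")["frequency"]
        assert by["self"] == 1.0
        assert by["far"] == 0.0

    def test_108_targets_76_overlapped(self):
        starts = np.arange(108) * 1000
        targets = _cres([("chr1", s, s + 500) for s in starts])
        feature = pd.DataFrame(
            {"chrom": "chr1", "start": starts[:76] + 100, "end": starts[:76] + 200}
        )
        freq = overlap_frequency(targets, {"tf": feature})
        assert freq.iloc[0]["frequency"] == pytest.approx(76 / 108)
        assert freq.iloc[0]["n_overlapping"] == 76

    def test_matches_brute_force_and_monotone(self):
        rng = np.random.default_rng(4)
        targets = random_peaks(rng, 150, span=100_000, max_len=400)
        targets["region_id"] = [f"t{i}" for i in range(len(targets))]
        small = random_peaks(rng, 40, span=100_000, max_len=400)
        big = pd.concat([small, random_peaks(rng, 60, span=100_000, max_len=400)])
        freq = overlap_frequency(targets, {"small": small, "big": big}).set_index("feature_set")
        for name, feats in (("small", small), ("big", big)):
            brute = 0
            for _, t in targets.iterrows():
                brute += bool(
                    (
                        (feats["chrom"] == t["chrom"])
                        & (feats["start"] < t["end"])
                        & (feats["end"] > t["start"])
                    ).any()
                )
            assert freq.loc[name, "n_overlapping"] == brute
        # superset never lowers the fraction
        assert freq.loc["big", "frequency"] >= freq.loc["small", "frequency"]
        # union row covers at least the best single set
        assert freq.loc["small|big", "frequency"] >= freq.loc["big", "frequency"]

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError, match="empty target"):
            overlap_frequency(pd.DataFrame(columns=["chrom", "start", "end"]), {})


class TestEnhancerTiers:
    @staticmethod
    def _fixture():
        cres = _cres([("chr1", i * 1000, i * 1000 + 500) for i in range(8)])
        cres["cluster"] = ["C1", "C1", "C2", "C3", "C3", "C4", "C2", "C1"]
        hit = lambda rows: pd.DataFrame(
            [("chr1", i * 1000 + 100, i * 1000 + 200) for i in rows],
            columns=["chrom", "start", "end"],
        )
        return cres, hit

    def test_candidate_rule_requires_cluster_and_cellline(self):
        cres, hit = self._fixture()
        tiers, counts = classify_enhancer_tiers(
            cres, hit([]), hit([]), hit([0, 3])  # cellline shares cre0 (C1) and cre3 (C3)
        )
        by = tiers.set_index("region_id")["tier"]
        assert by["cre0"] == CANDIDATE_TIER
        assert by["cre3"] != CANDIDATE_TIER  # C3 gated out despite sharing

    def test_c3_with_all_flags_not_candidate(self):
        cres, hit = self._fixture()
        tiers, _ = classify_enhancer_tiers(cres, hit([3]), hit([3]), hit([3]))
        assert tiers.set_index("region_id").loc["cre3", "tier"] == "super_enhancer"

    def test_counts_match_set_intersection_oracle(self):
        rng = np.random.default_rng(5)
        cres = random_peaks(rng, 120, span=200_000, max_len=600)
        cres["region_id"] = [f"c{i}" for i in range(len(cres))]
        cres["cluster"] = rng.choice(["C1", "C2", "C3", "C4"], size=len(cres))
        sets = {
            name: random_peaks(rng, 50, span=200_000, max_len=600)
            for name in ("erna", "se", "cl")
        }
        tiers, counts = classify_enhancer_tiers(cres, sets["erna"], sets["se"], sets["cl"])

        def hits(feats, t):
            return bool(
                (
                    (feats["chrom"] == t["chrom"])
                    & (feats["start"] < t["end"])
                    & (feats["end"] > t["start"])
                ).any()
            )

        expected = []
        for _, t in cres.iterrows():
            e, s, c = (hits(sets[k], t) for k in ("erna", "se", "cl"))
            if t["cluster"] in ("C1", "C2") and c:
                expected.append(CANDIDATE_TIER)
            elif s:
                expected.append("super_enhancer")
            elif e:
                expected.append("annotated_enhancer")
            else:
                expected.append("other")
        assert tiers["tier"].tolist() == expected
        assert counts.sum() == len(cres)

    def test_order_independent(self):
        cres, hit = self._fixture()
        t1, _ = classify_enhancer_tiers(cres, hit([1]), hit([2]), hit([0, 2]))
        t2, _ = classify_enhancer_tiers(
            cres.iloc[::-1].reset_index(drop=True), hit([1]), hit([2]), hit([0, 2])
        )
        m1 = t1.set_index("region_id")["tier"]
        m2 = t2.set_index("region_id")["tier"]
        assert m1.sort_index().equals(m2.sort_index())
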