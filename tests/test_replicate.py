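"""Interval operations, Venn classification, directionality, categories."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from migrascan.replicate import (
    category_sharing,
    classify_parallelism,
    directionality_concordance,
    exclude_control_outliers,
    functional_categorize,
    genes_near,
    intersect_across,
    merge_overlapping,
    sites_to_intervals,
)


def iv(*triples):
    return pd.DataFrame(triples, columns=["chrom", "start", "end"])


def random_intervals(rng, n, span=1000):
    starts = rng.integers(0, span, n)
    lengths = rng.integers(1, 80, n)
    return iv(*[("chr1", int(s), int(s + l)) for s, l in zip(starts, lengths)])


class TestExclusion:
    def test_empty_controls_leave_case_unchanged(self):
        case = iv(("chr1", 0, 50_000), ("chr1", 100_000, 150_000))
        out = exclude_control_outliers(case, [iv()])
        pd.testing.assert_frame_equal(out, case)

    def test_overlapping_control_removes_case_item(self):
        case = iv(("chr1", 0, 50_000), ("chr1", 100_000, 150_000))
        ctrl = iv(("chr1", 40_000, 60_000))
        out = exclude_control_outliers(case, [ctrl])
        assert [(r.start, r.end) for r in out.itertuples()] == [(100_000, 150_000)]

    def test_site_level_exclusion_is_exact_position_match(self):
        case = sites_to_intervals(pd.DataFrame({"chrom": "chr1", "pos": [100, 200]}))
        ctrl = sites_to_intervals(pd.DataFrame({"chrom": "chr1", "pos": [200, 300]}))
        out = exclude_control_outliers(case, [ctrl])
        assert list(out["start"]) == [99]

    def test_output_is_subset_of_input(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            case = random_intervals(rng, 15)
            ctrl = random_intervals(rng, 5)
            out = exclude_control_outliers(case, [ctrl])
            case_set = set(map(tuple, case.to_numpy()))
            assert set(map(tuple, out.to_numpy())) <= case_set


class TestMerge:
    def test_sliding_window_overlap_merges(self):
        out = merge_overlapping(iv(("chr1", 0, 50_000), ("chr1", 25_000, 75_000)))
        assert [(r.start, r.end) for r in out.itertuples()] == [(0, 75_000)]

    def test_boundary_touching_does_not_merge(self):
        out = merge_overlapping(iv(("chr1", 0, 10), ("chr1", 10, 20)))
        assert len(out) == 2

    def test_disjoint_unchanged(self):
        df = iv(("chr1", 0, 10), ("chr1", 20, 30), ("chr2", 0, 10))
        out = merge_overlapping(df)
        assert len(out) == 3

    def test_against_quadratic_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            df = random_intervals(rng, 12)
            got = [(r.chrom, r.start, r.end) for r in merge_overlapping(df).itertuples()]
            want = oracles.merge_quadratic(
                [(r.chrom, r.start, r.end) for r in df.itertuples()]
            )
            assert got == want

    @pytest.mark.skipif(shutil.which("bedtools") is None, reason="bedtools not on PATH")
    def test_against_bedtools(self, tmp_path):
        rng = np.random.default_rng(2)
        df = random_intervals(rng, 30).sort_values(["chrom", "start", "end"])
        bed = tmp_path / "in.bed"
        df.to_csv(bed, sep="\t", header=False, index=False)
        res = subprocess.run(
            ["bedtools", "merge", "-i", str(bed)], capture_output=True, text=True, check=True
        )
        want = [
            (f[0], int(f[1]), int(f[2]))
            for f in (line.split("\t") for line in res.stdout.strip().split("\n"))
        ]
        got = [(r.chrom, r.start, r.end) for r in merge_overlapping(df).itertuples()]
        assert got == want


class TestIntersect:
    def test_identical_sets_all_triple(self):
        s = iv(("chr1", 0, 10), ("chr1", 50, 60))
        out = intersect_across({"a": s, "b": s.copy(), "c": s.copy()})
        assert (out["membership"] == "a,b,c").all()

    def test_disjoint_sets_all_singletons(self):
        out = intersect_across(
            {"a": iv(("chr1", 0, 10)), "b": iv(("chr1", 20, 30)), "c": iv(("chr1", 40, 50))}
        )
        assert sorted(out["membership"]) == ["a", "b", "c"]

    def test_membership_against_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            sets = {lab: random_intervals(rng, 6, span=300) for lab in "abc"}
            out = intersect_across(sets)
            for row in out.itertuples():
                want = {
                    lab
                    for lab, df in sets.items()
                    if any(
                        r.start < row.end and row.start < r.end
                        for r in df.itertuples()
                        if r.chrom == row.chrom
                    )
                }
                assert set(row.membership.split(",")) == want


class TestGenesNear:
    ANNOT = pd.DataFrame(
        {
            "gene_id": ["g1", "g2"],
            "chrom": ["chr1", "chr1"],
            "start": [100_000, 500_000],
            "end": [110_000, 510_000],
            "strand": ["+", "-"],
        }
    )

    def test_site_inside_gene_distance_zero(self):
        items = sites_to_intervals(pd.DataFrame({"chrom": "chr1", "pos": [105_000]}))
        hits = genes_near(items, self.ANNOT)
        assert list(hits["gene_id"]) == ["g1"]
        assert hits.at[0, "distance"] == 0

    def test_boundary_25kb_inclusive(self):
        # site interval [135000, 135001): distance to g1 end (110000) = 25000
        hits = genes_near(iv(("chr1", 135_000, 135_001)), self.ANNOT)
        assert list(hits["gene_id"]) == ["g1"]
        assert hits.at[0, "distance"] == 25_000
        miss = genes_near(iv(("chr1", 135_001, 135_002)), self.ANNOT)
        assert miss.empty

    def test_unannotated_chromosome_yields_no_hits(self):
        hits = genes_near(iv(("chrZ", 0, 100)), self.ANNOT)
        assert hits.empty

    def test_against_all_pairs_oracle(self):
        rng = np.random.default_rng(4)
        annot = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(8)],
                "chrom": "chr1",
                "start": np.sort(rng.choice(np.arange(0, 900_000, 1000), 8, replace=False)),
            }
        )
        annot["end"] = annot["start"] + 5_000
        annot["strand"] = "+"
        items = random_intervals(rng, 20, span=900_000)
        hits = genes_near(items, annot, max_dist_bp=25_000)
        got = {(r.start, r.end, r.gene_id) for r in hits.itertuples()}
        want = set()
        for it in items.drop_duplicates().itertuples():
            for g in annot.itertuples():
                d = oracles.interval_distance(it.start, it.end, g.start, g.end)
                if d <= 25_000:
                    want.add((it.start, it.end, g.gene_id))
        assert got == want


class TestClassifyParallelism:
    def test_three_disjoint_sets(self):
        rep = classify_parallelism({"a": {1, 2}, "b": {3}, "c": {4, 5, 6}})
        assert rep.union_size == 6
        assert rep.shared_two_plus == 0 and rep.shared_all == 0

    def test_region_counts_match_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            sets = {
                lab: set(rng.choice(30, size=rng.integers(3, 15), replace=False))
                for lab in "abc"
            }
            rep = classify_parallelism(sets)
            want = oracles.venn_enumerate(sets)
            assert rep.region_counts == want
            assert sum(rep.region_counts.values()) == rep.union_size

    def test_invariant_ordering(self):
        rep = classify_parallelism({"a": {1, 2, 3}, "b": {2, 3}, "c": {3}})
        assert rep.shared_all <= rep.shared_two_plus <= rep.union_size
        assert rep.shared_all == 1 and rep.shared_two_plus == 2


class TestCategorySharing:
    def test_counts_by_sharedness(self):
        sets = {
            "a": {"t1", "t2", "m1"},
            "b": {"t1", "t3"},
            "c": {"t2", "t3", "m2"},
        }
        rep = classify_parallelism(sets)
        cats = {g: "timing" for g in ["t1", "t2", "t3"]}
        cats.update({"m1": "morphology", "m2": "morphology"})
        out = category_sharing(rep, cats).set_index("category")
        assert out.at["timing", "total"] == 3
        assert out.at["timing", "shared_two_plus"] == 3
        assert out.at["morphology", "single"] == 2
        assert (out["total"] == out["shared_two_plus"] + out["single"]).all()


def _xp(chrom, pos, z, sig):
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "z": z, "significant": sig}
    )


class TestDirectionality:
    def test_concordant_and_discordant_items(self):
        membership = pd.DataFrame(
            {"a": [True, True], "b": [True, True]},
            index=pd.Index(["g1", "g2"], name="item"),
        )
        shared = pd.DataFrame(
            {
                "item": ["g1", "g2"],
                "chrom": ["chr1", "chr1"],
                "start": [0, 1000],
                "end": [500, 1500],
            }
        )
        xp = {
            "a": _xp(["chr1", "chr1"], [100, 1100], [3.0, 2.5], [True, True]),
            "b": _xp(["chr1", "chr1"], [200, 1200], [2.8, -2.9], [True, True]),
        }
        frame, fraction = directionality_concordance(shared, membership, xp)
        assert frame.set_index("item").at["g1", "concordant"]
        assert not frame.set_index("item").at["g2", "concordant"]
        assert fraction == pytest.approx(0.5)

    def test_undetermined_sign_excluded_from_denominator(self):
        membership = pd.DataFrame(
            {"a": [True], "b": [True]}, index=pd.Index(["g1"], name="item")
        )
        shared = pd.DataFrame(
            {"item": ["g1"], "chrom": ["chr1"], "start": [0], "end": [500]}
        )
        xp = {
            "a": _xp(["chr1"], [100], [3.0], [True]),
            "b": _xp(["chr1"], [100], [1.0], [False]),  # not significant
        }
        frame, fraction = directionality_concordance(shared, membership, xp)
        assert not frame.at[0, "determined"]
        assert np.isnan(fraction)

    def test_no_shared_items_gives_undefined_fraction(self):
        membership = pd.DataFrame({"a": [], "b": []}, index=pd.Index([], name="item"))
        frame, fraction = directionality_concordance(
            pd.DataFrame(columns=["item", "chrom", "start", "end"]), membership, {}
        )
        assert frame.empty and np.isnan(fraction)


class TestFunctionalCategorize:
    ANNOT = TestGenesNear.ANNOT

    def test_three_categories(self):
        items = iv(
            ("chr1", 105_000, 105_001),   # inside g1 -> genic
            ("chr1", 90_000, 90_001),     # 10 kb upstream -> proximal-regulatory
            ("chr1", 300_000, 300_001),   # far from both -> intergenic
        )
        out = functional_categorize(items, self.ANNOT)
        got = dict(zip(out["start"], out["category"]))
        assert got == {
            90_000: "proximal-regulatory",
            105_000: "genic",
            300_000: "intergenic",
        }

    def test_counts_against_brute_force(self):
        rng = np.random.default_rng(6)
        items = random_intervals(rng, 25, span=700_000)
        out = functional_categorize(items, self.ANNOT)
        for row in out.itertuples():
            dists = [
                oracles.interval_distance(row.start, row.end, g.start, g.end)
                for g in self.ANNOT.itertuples()
            ]
            if min(dists) == 0:
                assert row.category == "genic"
            elif min(dists) <= 25_000:
                assert row.category == "proximal-regulatory"
            else:
                assert row.category == "intergenic"
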