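"""F_ST, percentile outliers, PCA selection scan, EHH / XP-EHH, rank p."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import oracles
from conftest import make_geno, two_pop_config
from migrascan.containers import HaplotypeMatrix
from migrascan.scanstats import (
    ehh,
    ehh_curve,
    fst_site,
    fst_windows,
    pca_selection_scan,
    percentile_outliers,
    rank_pvalues,
    xpehh_raw,
)
from migrascan.simdata import simulate_frequencies, simulate_genotypes


class TestFstSite:
    @pytest.mark.parametrize(
        "p1,n1,p2,n2,num,den",
        [
            (1.0, 20, 0.0, 20, 1.0, 1.0),                    # fixed difference
            (0.9, 20, 0.1, 20, 0.64 - 2 * 0.09 / 19, 0.82),  # hand computation
            (0.5, 10, 0.5, 10, -2 * 0.25 / 9, 0.5),          # negative allowed
        ],
    )
    def test_hand_computed_values(self, p1, n1, p2, n2, num, den):
        got_num, got_den = fst_site(p1, n1, p2, n2)
        assert got_num == pytest.approx(num, abs=1e-12)
        assert got_den == pytest.approx(den, abs=1e-12)

    def test_reference_fst_values(self):
        num, den = fst_site(0.9, 20, 0.1, 20)
        assert num / den == pytest.approx(0.76894, abs=1e-5)
        num, den = fst_site(1.0, 8, 0.0, 30)
        assert num / den == 1.0


def _site_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "num", "den"])
    df["fst"] = df["num"] / df["den"]
    df["defined"] = df["den"] > 0
    return df


class TestFstWindows:
    def test_site_appears_in_both_overlapping_windows(self):
        df = _site_frame([("chr1", 30_001, 0.5, 1.0)])
        w = fst_windows(df, 50_000, 25_000)
        assert [(r.start, r.end) for r in w.itertuples()] == [
            (0, 50_000),
            (25_000, 75_000),
        ]

    def test_ratio_of_sums_not_mean_of_ratios(self):
        df = _site_frame([("chr1", 100, 1.0, 1.0), ("chr1", 200, 0.0, 1.0)])
        w = fst_windows(df, 50_000, 25_000)
        assert w.at[0, "fst"] == pytest.approx(0.5)
        # mean of site ratios would also be 0.5 here; unequal denominators
        # must follow the ratio-of-sums
        df = _site_frame([("chr1", 100, 1.0, 1.0), ("chr1", 200, 0.0, 3.0)])
        w = fst_windows(df, 50_000, 25_000)
        assert w.at[0, "fst"] == pytest.approx(0.25)
        assert w.at[0, "fst"] != pytest.approx(0.5)

    def test_single_site_window_equals_site_fst(self):
        df = _site_frame([("chr1", 10, 0.63, 0.82)])
        w = fst_windows(df, 50_000, 25_000)
        assert w.at[0, "fst"] == pytest.approx(0.63 / 0.82)

    def test_undefined_sites_omitted(self):
        df = _site_frame([("chr1", 100, 0.2, 0.0)])
        assert fst_windows(df).empty

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            fst_windows(_site_frame([("chr1", 1, 1, 1)]), 10_000, 20_000)


class TestPercentileOutliers:
    def test_values_1_to_1000(self):
        mask = percentile_outliers(np.arange(1, 1001, dtype=float), q=0.99)
        assert list(np.flatnonzero(mask) + 1) == list(range(991, 1001))

    def test_all_equal_flags_none(self):
        assert not percentile_outliers(np.ones(500)).any()

    def test_continuous_flagged_fraction_near_one_percent(self):
        rng = np.random.default_rng(0)
        mask = percentile_outliers(rng.normal(size=50_000))
        assert np.abs(mask.mean() - 0.01) < 0.002

    def test_too_few_values_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            mask = percentile_outliers(np.arange(50, dtype=float), q=0.99)
        assert not mask.any()

    @given(st.permutations(list(range(200))))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance(self, perm):
        values = np.asarray(perm, dtype=float)
        mask = percentile_outliers(values)
        flagged = set(values[mask])
        assert flagged == set(range(199, 197, -1)) or flagged == {198.0, 199.0}


class TestPcaSelectionScan:
    def test_null_pvalues_uniform(self):
        # sites with no structure: chi-square calibration must hold
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.5, 8_000)
        D = rng.binomial(2, p, size=(50, 8_000)).astype(float)
        scan = pca_selection_scan(make_geno(D, positions=np.arange(1, 8_001)))
        pv = scan.loc[scan["defined"], "pvalue"].to_numpy()
        assert stats.kstest(pv, "uniform").pvalue > 0.01

    def test_structured_site_has_largest_statistic(self):
        rng = np.random.default_rng(2)
        # two clusters with mildly shifted frequencies so PC1 is the split,
        # plus site 0 perfectly tracking it
        p = np.vstack([np.full(500, 0.25), np.full(500, 0.35)])
        D = np.vstack(
            [rng.binomial(2, p[0], size=(20, 500)), rng.binomial(2, p[1], size=(20, 500))]
        ).astype(float)
        D[:, 0] = np.repeat([0.0, 2.0], 20)
        scan = pca_selection_scan(make_geno(D, positions=np.arange(1, 501)))
        assert scan["stat"].idxmax() == 0

    def test_constant_site_excluded(self):
        rng = np.random.default_rng(3)
        D = rng.binomial(2, 0.4, size=(20, 50)).astype(float)
        D[:, 10] = 2.0
        scan = pca_selection_scan(make_geno(D, positions=np.arange(1, 51)))
        assert not scan.at[10, "defined"]
        assert np.isnan(scan.at[10, "stat"])


def _hap(rows, positions=None):
    A = np.asarray(rows, dtype=np.int8)
    return A, (np.arange(1, A.shape[1] + 1) * 10.0 if positions is None
               else np.asarray(positions, dtype=float))


class TestEhh:
    def test_identical_carriers_stay_at_one(self):
        A, _ = _hap([[0, 1, 0, 1]] * 5)
        curve = ehh_curve(A, core=0, direction=1, include_core=False)
        np.testing.assert_array_equal(curve, np.ones(4))

    def test_two_two_split_gives_one_third(self):
        A, _ = _hap([[1, 0], [1, 0], [1, 1], [1, 1]])
        curve = ehh_curve(A, core=0, direction=1, include_core=False)
        assert curve[0] == 1.0
        assert curve[1] == pytest.approx((1 + 1) / 6)

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            A = rng.integers(0, 2, size=(10, 15)).astype(np.int8)
            for direction in (+1, -1):
                core = 7
                curve = ehh_curve(A, core, direction, include_core=True)
                assert (np.diff(curve) <= 1e-12).all()

    def test_fewer_than_two_carriers_rejected(self):
        A, _ = _hap([[0, 1]])
        with pytest.raises(ValueError):
            ehh_curve(A, 0, 1)


class TestXpehh:
    def test_identical_populations_score_zero(self):
        rng = np.random.default_rng(5)
        A = rng.integers(0, 2, size=(8, 12)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 500), 12, replace=False)).astype(float)
        raw = xpehh_raw(A, A.copy(), pos)
        assert np.allclose(raw[np.isfinite(raw)], 0.0)

    def test_swapping_populations_negates_scores(self):
        rng = np.random.default_rng(6)
        A = rng.integers(0, 2, size=(8, 12)).astype(np.int8)
        B = rng.integers(0, 2, size=(6, 12)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 500), 12, replace=False)).astype(float)
        fwd = xpehh_raw(A, B, pos)
        rev = xpehh_raw(B, A, pos)
        both = np.isfinite(fwd) & np.isfinite(rev)
        np.testing.assert_allclose(fwd[both], -rev[both], atol=1e-12)

    def test_matches_exhaustive_oracle_on_random_toys(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            m_a = rng.integers(3, 17)
            m_b = rng.integers(3, 17)
            L = rng.integers(4, 21)
            pos = np.sort(rng.choice(np.arange(1, 2000), L, replace=False)).astype(float)
            A = rng.integers(0, 2, size=(m_a, L)).astype(np.int8)
            B = rng.integers(0, 2, size=(m_b, L)).astype(np.int8)
            got = xpehh_raw(A, B, pos)
            want = oracles.xpehh_exhaustive(A, B, pos)
            np.testing.assert_array_equal(np.isfinite(got), np.isfinite(want))
            both = np.isfinite(got)
            np.testing.assert_allclose(got[both], want[both], atol=1e-10)


class TestRankPvalues:
    def test_thousand_distinct_scores_give_nine_significant(self):
        rng = np.random.default_rng(8)
        scores = rng.permutation(np.linspace(0.5, 5.0, 1000))
        pv = rank_pvalues(scores)
        sig = -np.log10(pv) > 2.0
        assert sig.sum() == 9
        # the 9 largest |score| values are the significant ones
        top9 = set(np.argsort(-np.abs(scores))[:9])
        assert set(np.flatnonzero(sig)) == top9

    def test_all_tied_scores_none_significant(self):
        pv = rank_pvalues(np.ones(500))
        assert ((-np.log10(pv)) <= 2.0).all()

    def test_monotone_transform_preserves_significance_set(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=300)
        s1 = -np.log10(rank_pvalues(scores)) > 2
        s2 = -np.log10(rank_pvalues(np.sign(scores) * np.abs(scores) ** 3)) > 2
        np.testing.assert_array_equal(s1, s2)

    def test_needs_hundred_scores(self):
        with pytest.raises(ValueError):
            rank_pvalues(np.arange(50))


class TestGenomeWideFst:
    def test_window_and_site_estimates_agree_on_simulated_drift(self):
        from migrascan.scanstats import fst_table

        cfg = two_pop_config(F_pop=0.05, n_diploids=25, L=5_000, seed=12)
        freqs, pos, _ = simulate_frequencies(cfg, np.random.default_rng(12))
        geno = simulate_genotypes(freqs, pos, cfg, np.random.default_rng(13))
        t = fst_table(geno, cfg.popmap(), ("P1",), ("P2",))
        d = t.loc[t["defined"]]
        genome = d["num"].sum() / d["den"].sum()
        assert genome == pytest.approx(0.05, abs=0.02)
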