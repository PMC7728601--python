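import numpy as np
import pandas as pd
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from malus import ancestry
from malus.ancestry import (
    SIEVERSII,
    SYLVESTRIS,
    UNCLEAR,
    ClassificationThresholds,
    SaturationError,
    classify_window,
    classify_windows,
    intersect_regions_with_ancestry,
    inverse_jukes_cantor,
    jukes_cantor_distance,
    paint_haplome,
    project_to_windows,
    recombination_boundaries,
    sensitivity_scan,
    summarize_painting,
)


def window_frame(d_pairs, window=50_000, chrom="chr1"):
    rows = []
    for i, (d_sie, d_syl) in enumerate(d_pairs):
        rows.append({
            "chrom": chrom, "start": i * window, "end": (i + 1) * window,
            "d_sie": d_sie, "d_syl": d_syl,
        })
    return pd.DataFrame(rows)


class TestJukesCantor:
    def test_identity(self):
        assert jukes_cantor_distance(0.0) == 0.0

    @pytest.mark.parametrize("p", [0.0139, 0.006, 0.1, 0.5, 0.7])
    def test_against_arbitrary_precision(self, p):
        expected = float(-sympy.Rational(3, 4) * sympy.log(1 - sympy.Rational(4, 3) * sympy.Rational(str(p))))
        assert jukes_cantor_distance(p) == pytest.approx(expected, rel=1e-14)

    def test_monotone_and_dominates_identity(self):
        assert jukes_cantor_distance(0.02) > jukes_cantor_distance(0.01) > 0.01

    def test_saturation_and_domain_errors(self):
        with pytest.raises(SaturationError):
            jukes_cantor_distance(0.75)
        with pytest.raises(ValueError):
            jukes_cantor_distance(-0.01)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=0.7))
    def test_round_trip(self, p):
        assert inverse_jukes_cantor(jukes_cantor_distance(p)) == pytest.approx(p, abs=1e-12)


class TestClassifyWindow:
    def test_clear_sieversii_call(self):
        # smaller divergence 0.8% < 1.4% and gap 0.6% > 0.2%
        assert classify_window(0.008, 0.014) == SIEVERSII

    def test_small_gap_is_unclear(self):
        assert classify_window(0.010, 0.0115) == UNCLEAR

    def test_equal_divergences_unclear_and_swap_symmetry(self):
        assert classify_window(0.01, 0.01) == UNCLEAR
        assert classify_window(0.008, 0.012) == SIEVERSII
        assert classify_window(0.012, 0.008) == SYLVESTRIS

    def test_undefined_divergence_unclear(self):
        assert classify_window(np.nan, 0.01) == UNCLEAR
        assert classify_window(0.01, None) == UNCLEAR

    def test_boundary_equality_is_unclear(self):
        thr = ClassificationThresholds()
        assert classify_window(0.014, 0.02, thr) == UNCLEAR  # not < 1.4%
        assert classify_window(0.008, 0.010, thr) == UNCLEAR  # gap not > 0.2%

    def test_both_bounded_option(self):
        thr = ClassificationThresholds(both_bounded=True)
        assert classify_window(0.008, 0.020, thr) == UNCLEAR
        assert classify_window(0.008, 0.0135, thr) == SIEVERSII

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(min_value=0.0, max_value=0.05),
        st.floats(min_value=0.0, max_value=0.05),
    )
    def test_species_swap_equivariance(self, d1, d2):
        swap = {SIEVERSII: SYLVESTRIS, SYLVESTRIS: SIEVERSII, UNCLEAR: UNCLEAR}
        assert classify_window(d2, d1) == swap[classify_window(d1, d2)]

    def test_vectorised_matches_scalar(self):
        df = window_frame([(0.008, 0.014), (0.010, 0.0115), (np.nan, 0.01), (0.02, 0.001)])
        calls = classify_windows(df)["call"].tolist()
        expected = [classify_window(r.d_sie, r.d_syl) for r in df.itertuples()]
        assert calls == expected


class TestProjectToWindows:
    def test_single_block_exact_window(self):
        blocks = pd.DataFrame([
            {"chrom": "chr1", "start": 0, "end": 50_000, "query": SIEVERSII,
             "aligned_columns": 50_000, "mismatches": 500},
            {"chrom": "chr1", "start": 0, "end": 50_000, "query": SYLVESTRIS,
             "aligned_columns": 50_000, "mismatches": 700},
        ])
        win = project_to_windows(blocks, 50_000)
        assert len(win) == 1
        assert win.loc[0, "mismatch_sie"] / win.loc[0, "aligned_len_sie"] == pytest.approx(0.01)
        assert win.loc[0, "d_sie"] == pytest.approx(jukes_cantor_distance(0.01))

    def test_short_alignment_undefined(self):
        blocks = pd.DataFrame([
            {"chrom": "chr1", "start": 0, "end": 80, "query": SIEVERSII,
             "aligned_columns": 80, "mismatches": 2},
        ])
        win = project_to_windows(blocks, 50_000, min_aligned=100, chrom_sizes={"chr1": 50_000})
        assert np.isnan(win.loc[0, "d_sie"])

    def test_empty_blocks_all_unalignable(self):
        blocks = pd.DataFrame(columns=["chrom", "start", "end", "query", "aligned_columns", "mismatches"])
        win = project_to_windows(blocks, 50_000, chrom_sizes={"chr1": 150_000})
        assert len(win) == 3
        assert win["d_sie"].isna().all() and win["d_syl"].isna().all()

    def test_block_prorated_across_boundary(self):
        # 100 mismatches over [25k, 75k): half land in each 50-kb window
        blocks = pd.DataFrame([
            {"chrom": "chr1", "start": 25_000, "end": 75_000, "query": SIEVERSII,
             "aligned_columns": 50_000, "mismatches": 100},
        ])
        win = project_to_windows(blocks, 50_000, chrom_sizes={"chr1": 100_000})
        assert win["mismatch_sie"].tolist() == [50, 50]
        assert win["aligned_len_sie"].tolist() == [25_000, 25_000]

    def test_overlapping_blocks_warn_first_precedence(self):
        blocks = pd.DataFrame([
            {"chrom": "chr1", "start": 0, "end": 40_000, "query": SIEVERSII,
             "aligned_columns": 40_000, "mismatches": 0},
            {"chrom": "chr1", "start": 30_000, "end": 50_000, "query": SIEVERSII,
             "aligned_columns": 20_000, "mismatches": 20_000},
        ])
        with pytest.warns(UserWarning, match="overlapping"):
            win = project_to_windows(blocks, 50_000)
        # only the [40k, 50k) half of the second block counts: 10k of its
        # 20k bp, pro-rated mismatches 10k
        assert win.loc[0, "aligned_len_sie"] == 50_000
        assert win.loc[0, "mismatch_sie"] == 10_000


class TestPaintAndSummary:
    def test_uniform_calls_merge_to_single_tract(self):
        df = window_frame([(0.005, 0.02)] * 10)
        calls, tracts = paint_haplome(df)
        assert len(tracts) == 1
        assert tracts.loc[0, "origin"] == SIEVERSII
        assert tracts.loc[0, "n_windows"] == 10
        assert recombination_boundaries(tracts).empty

    def test_alternating_calls_one_tract_per_window(self):
        df = window_frame([(0.005, 0.02), (0.02, 0.005)] * 5)
        calls, tracts = paint_haplome(df)
        assert len(tracts) == 10
        bounds = recombination_boundaries(tracts)
        assert len(bounds) == 9
        assert (tracts["origin"].to_numpy()[:-1] != tracts["origin"].to_numpy()[1:]).all()

    def test_tracts_conserve_bp(self):
        rng = np.random.default_rng(5)
        pairs = [(rng.uniform(0, 0.02), rng.uniform(0, 0.02)) for _ in range(50)]
        df = window_frame(pairs)
        calls, tracts = paint_haplome(df)
        assert (tracts["end"] - tracts["start"]).sum() == (df["end"] - df["start"]).sum()

    def test_fully_hybrid_diploid(self):
        a, _ = paint_haplome(window_frame([(0.005, 0.02)] * 4))
        b, _ = paint_haplome(window_frame([(0.02, 0.005)] * 4))
        summary = summarize_painting(a, b)
        assert summary.fraction_hybrid == 1.0
        assert summary.fraction_unresolved == 0.0

    def test_identical_haplomes_zero_hybrid(self):
        a, _ = paint_haplome(window_frame([(0.005, 0.02)] * 4))
        summary = summarize_painting(a, a)
        assert summary.fraction_hybrid == 0.0
        assert summary.fraction_homo_sie == 1.0

    def test_fraction_sums(self):
        rng = np.random.default_rng(0)
        pairs_a = [(rng.uniform(0, 0.03), rng.uniform(0, 0.03)) for _ in range(40)]
        pairs_b = [(rng.uniform(0, 0.03), rng.uniform(0, 0.03)) for _ in range(40)]
        a, _ = paint_haplome(window_frame(pairs_a))
        b, _ = paint_haplome(window_frame(pairs_b))
        s = summarize_painting(a, b)
        for hap in (0, 1):
            total = s.fraction_sieversii[hap] + s.fraction_sylvestris[hap] + s.fraction_unclear[hap]
            assert total == pytest.approx(1.0, abs=1e-9)
        diploid = s.fraction_hybrid + s.fraction_homo_sie + s.fraction_homo_syl + s.fraction_unresolved
        assert diploid == pytest.approx(1.0, abs=1e-9)

    def test_grid_mismatch_rejected(self):
        a, _ = paint_haplome(window_frame([(0.005, 0.02)] * 4))
        b, _ = paint_haplome(window_frame([(0.005, 0.02)] * 5))
        with pytest.raises(ValueError, match="grid"):
            summarize_painting(a, b)


class TestSensitivityScan:
    @staticmethod
    def blocks_fixture():
        rows = []
        for i in range(20):  # 100 kb of 5-kb blocks, sieversii-like
            rows.append({"chrom": "chr1", "start": i * 5_000, "end": (i + 1) * 5_000,
                         "query": SIEVERSII, "aligned_columns": 5_000, "mismatches": 30})
            rows.append({"chrom": "chr1", "start": i * 5_000, "end": (i + 1) * 5_000,
                         "query": SYLVESTRIS, "aligned_columns": 5_000, "mismatches": 100})
        return pd.DataFrame(rows)

    def test_single_combination_matches_direct_painting(self):
        blocks = self.blocks_fixture()
        scan = sensitivity_scan(blocks, window_sizes=[50_000], min_aligned_list=[100])
        win = project_to_windows(blocks, 50_000, min_aligned=100)
        calls = classify_windows(win)
        frac_sie = ((calls["call"] == SIEVERSII) * (calls["end"] - calls["start"])).sum() / (
            calls["end"] - calls["start"]
        ).sum()
        assert scan.loc[0, "fraction_sieversii"] == pytest.approx(frac_sie)

    def test_window_larger_than_chromosome(self):
        blocks = self.blocks_fixture()
        win = project_to_windows(blocks, 10_000_000)
        assert len(win) == 1

    def test_empty_parameter_lists_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_scan(self.blocks_fixture(), window_sizes=[])


class TestIntersectRegions:
    tracts = pd.DataFrame([
        {"chrom": "chr1", "start": 0, "end": 100_000, "origin": SIEVERSII, "n_windows": 2},
        {"chrom": "chr1", "start": 100_000, "end": 200_000, "origin": SYLVESTRIS, "n_windows": 2},
        {"chrom": "chr1", "start": 200_000, "end": 300_000, "origin": UNCLEAR, "n_windows": 2},
    ])

    def test_region_inside_single_tract(self):
        regions = pd.DataFrame([{"chrom": "chr1", "start": 10_000, "end": 20_000}])
        out = intersect_regions_with_ancestry(regions, self.tracts)
        assert out.loc[0, "origin"] == SIEVERSII

    def test_majority_rule_60_40(self):
        regions = pd.DataFrame([{"chrom": "chr1", "start": 40_000, "end": 140_000}])
        out = intersect_regions_with_ancestry(regions, self.tracts)
        assert out.loc[0, "origin"] == SIEVERSII  # 60 kb vs 40 kb

    def test_tie_is_unclear(self):
        regions = pd.DataFrame([{"chrom": "chr1", "start": 50_000, "end": 150_000}])
        out = intersect_regions_with_ancestry(regions, self.tracts)
        assert out.loc[0, "origin"] == UNCLEAR

    def test_unclear_tract(self):
        regions = pd.DataFrame([{"chrom": "chr1", "start": 210_000, "end": 220_000}])
        out = intersect_regions_with_ancestry(regions, self.tracts)
        assert out.loc[0, "origin"] == UNCLEAR

    def test_unknown_chromosome_skipped(self):
        regions = pd.DataFrame([{"chrom": "chr9", "start": 0, "end": 10}])
        with pytest.warns(UserWarning, match="unknown chromosome"):
            out = intersect_regions_with_ancestry(regions, self.tracts)
        assert out.empty


def test_smooth_divergence_is_display_only_and_tracks_signal():
    x = np.arange(200, dtype=float)
    y = np.where(x < 100, 0.006, 0.02) + np.random.default_rng(1).normal(0, 0.001, 200)
    sm = ancestry.smooth_divergence(x, y, span=0.2)
    assert abs(sm[:80].mean() - 0.006) < 0.002
    assert abs(sm[120:].mean() - 0.02) < 0.002
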