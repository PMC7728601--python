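import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from malus.popgen import (
    MISSING,
    GenotypeMatrix,
    allele_frequency,
    genotype_class_proportions,
    hard_filter_variant,
    neighbor_joining,
    nucleotide_diversity_windows,
    p_distance_matrix,
    population_filter,
    round_half_away,
    tajima_constants,
    window_stats,
)


class TestHardFilter:
    base = {"qual": 200.0, "info": {"QD": 20.0, "SOR": 1.0, "FS": 5.0, "MQ": 60.0,
                                    "MQRankSum": 0.0, "ReadPosRankSum": 0.0},
            "ad_ref": 30, "ad_alt": 25}

    def test_comfortable_record_passes(self):
        assert hard_filter_variant(self.base)

    def test_low_qd_fails(self):
        rec = dict(self.base, info=dict(self.base["info"], QD=1.5))
        res = hard_filter_variant(rec)
        assert not res and "QD" in res.reasons

    def test_boundary_allele_support_inclusive(self):
        rec = dict(self.base, ad_ref=5, ad_alt=5)
        assert hard_filter_variant(rec)

    def test_four_alt_reads_fail(self):
        rec = dict(self.base, ad_alt=4)
        res = hard_filter_variant(rec)
        assert not res and "allele_support" in res.reasons

    def test_missing_annotation_does_not_fail(self):
        rec = {"qual": 100.0, "info": {}, "ad_ref": 10, "ad_alt": 10}
        assert hard_filter_variant(rec)

    @pytest.mark.parametrize(
        "key,value",
        [("SOR", 3.5), ("FS", 61.0), ("MQ", 39.0), ("MQRankSum", -13.0),
         ("ReadPosRankSum", -8.5)],
    )
    def test_each_exclusion_rule(self, key, value):
        rec = dict(self.base, info=dict(self.base["info"], **{key: value}))
        res = hard_filter_variant(rec)
        assert not res and key in res.reasons

    def test_low_qual_fails(self):
        res = hard_filter_variant(dict(self.base, qual=59.0))
        assert not res and "QUAL" in res.reasons


class TestPopulationFilter:
    def test_high_missingness_removed(self):
        g = np.full((1, 20), MISSING, dtype=np.int8)
        g[0, 0] = 1
        gm = make_matrix(g)
        assert population_filter(gm).n_sites == 0

    def test_maf_boundary_inclusive(self):
        # 20 samples, 40 alleles: 2 alt alleles -> MAF exactly 0.05
        g = np.zeros((1, 20), dtype=np.int8)
        g[0, 0] = 2
        gm = make_matrix(g)
        assert population_filter(gm).n_sites == 1

    def test_monomorphic_removed(self):
        gm = make_matrix(np.zeros((1, 20), dtype=np.int8))
        assert population_filter(gm).n_sites == 0

    def test_qual_threshold(self):
        g = np.array([[0, 1, 1, 0, 1, 0, 0, 1, 0, 0]], dtype=np.int8)
        gm = make_matrix(g, qual=np.array([29.0]))
        assert population_filter(gm).n_sites == 0
        gm2 = make_matrix(g, qual=np.array([30.0]))
        assert population_filter(gm2).n_sites == 1

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        g = rng.integers(-1, 3, size=(50, 30)).astype(np.int8)
        gm = make_matrix(g)
        once = population_filter(gm)
        twice = population_filter(once)
        assert np.array_equal(once.genotypes, twice.genotypes)


class TestFrequencies:
    def test_rounding_half_away_from_zero(self):
        assert round_half_away(55.55) == 55.6
        assert round_half_away(4.545454, 1) == 4.5
        assert round_half_away(-2.25, 1) == -2.3

    def test_fixation(self):
        gm = make_matrix(np.full((1, 10), 2, dtype=np.int8))
        assert allele_frequency(gm, None, 0) == 100.0

    def test_all_hom_ref_proportions(self):
        gm = make_matrix(np.zeros((1, 12), dtype=np.int8))
        assert genotype_class_proportions(gm, None, 0) == (100.0, 0.0, 0.0)

    def test_consistency_freq_equals_homalt_plus_half_het(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(1, 40)).astype(np.int8)
        gm = make_matrix(g)
        hom_ref, het, hom_alt = genotype_class_proportions(gm, None, 0)
        freq_exact = 100.0 * (2 * (g[0] == 2).sum() + (g[0] == 1).sum()) / (2 * g.shape[1])
        assert allele_frequency(gm, None, 0) == round_half_away(freq_exact)
        assert freq_exact == pytest.approx(
            100.0 * (g[0] == 2).mean() + 50.0 * (g[0] == 1).mean()
        )

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, size=(1, 30)).astype(np.int8)
        gm = make_matrix(g)
        perm = make_matrix(g[:, rng.permutation(30)])
        assert allele_frequency(gm, None, 0) == allele_frequency(perm, None, 0)

    def test_all_missing_undefined(self):
        gm = make_matrix(np.full((1, 5), MISSING, dtype=np.int8))
        with pytest.raises(ValueError, match="missing"):
            allele_frequency(gm, None, 0)


def brute_force_pi_D(haplotypes, positions, window, step, extent):
    """Independent enumeration oracle: pairwise haplotype differences for pi,
    Tajima's constants recomputed from scratch for D."""
    n = haplotypes.shape[0]
    out = []
    start = 0
    while start < extent:
        idx = [i for i, p in enumerate(positions) if start <= p - 1 < start + window]
        pi_total = 0.0
        for i, j in itertools.combinations(range(n), 2):
            pi_total += int(np.sum(haplotypes[i, idx] != haplotypes[j, idx]))
        pi_total /= math.comb(n, 2)
        S = sum(1 for k in idx if 0 < haplotypes[:, k].sum() < n)
        D = float("nan")
        if S >= 3 and n >= 4:
            a1 = sum(1.0 / i for i in range(1, n))
            a2 = sum(1.0 / i**2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            e1, e2 = c1 / a1, c2 / (a1**2 + a2)
            D = (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        out.append((pi_total / window, D, S))
        start += step
    return out


class TestWindowedDiversity:
    def test_no_segregation_zero_pi(self):
        gm = make_matrix(np.ones((5, 8), dtype=np.int8) * 2, positions=np.arange(1, 6) * 10)
        stats = nucleotide_diversity_windows(gm, window=100, step=100)
        assert (stats["pi"] == 0).all()

    def test_single_site_two_two_split(self):
        """4 haplotypes split 2/2: site pi = 2*(1/2)*(1/2)*(4/3) = 2/3."""
        gm = make_matrix(np.array([[2, 0]], dtype=np.int8), positions=np.array([50]))
        stats = nucleotide_diversity_windows(gm, window=100, step=100)
        assert stats.loc[0, "pi"] == pytest.approx((2.0 / 3.0) / 100.0)

    def test_all_singletons_negative_D(self):
        n_samples, n_sites = 10, 12
        g = np.zeros((n_sites, n_samples), dtype=np.int8)
        for k in range(n_sites):
            g[k, k % n_samples] = 1  # every site a singleton haplotype
        gm = make_matrix(g, positions=np.arange(1, n_sites + 1) * 5)
        stats = window_stats(gm, window=100, step=100)
        assert stats.loc[0, "tajima_d"] < 0

    def test_undefined_windows_flagged_not_dropped(self):
        gm = make_matrix(np.array([[1, 0, 1]], dtype=np.int8), positions=np.array([10]))
        stats = window_stats(gm, window=100, step=100)
        assert len(stats) == 1 and np.isnan(stats.loc[0, "tajima_d"])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n_samples = int(rng.integers(2, 6))
            n_sites = int(rng.integers(5, 40))
            haps = rng.integers(0, 2, size=(2 * n_samples, n_sites))
            g = (haps[0::2] + haps[1::2]).T.astype(np.int8)
            positions = np.sort(rng.choice(np.arange(1, 1500), size=n_sites, replace=False))
            gm = make_matrix(g, positions=positions)
            got = window_stats(gm, window=400, step=200)
            want = brute_force_pi_D(haps, positions, 400, 200, int(positions.max()))
            assert len(got) == len(want)
            for row, (pi, D, S) in zip(got.itertuples(), want):
                assert row.pi == pytest.approx(pi, abs=1e-10)
                assert row.n_segregating == S
                if math.isnan(D):
                    assert np.isnan(row.tajima_d)
                else:
                    assert row.tajima_d == pytest.approx(D, abs=1e-10)

    def test_constants_match_published_small_n(self):
        # a1 for n=4 is 1 + 1/2 + 1/3
        k = tajima_constants(4)
        assert k["a1"] == pytest.approx(11.0 / 6.0)


class TestPDistance:
    def test_identical_samples_zero(self):
        g = np.tile(np.array([[1], [2], [0]], dtype=np.int8), (1, 3))
        dm = p_distance_matrix(make_matrix(g))
        assert np.allclose(dm.to_numpy(), 0.0)

    def test_opposite_homozygotes_distance_one(self):
        g = np.array([[0, 2], [0, 2], [2, 0]], dtype=np.int8)
        dm = p_distance_matrix(make_matrix(g))
        assert dm.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_computed_three_samples(self):
        # sites x samples; sample pairs (0,1): |0-1|+|2-1|+|1-0| = 3 -> 3/6
        g = np.array([[0, 1, 2], [2, 1, 0], [1, 0, 1]], dtype=np.int8)
        dm = p_distance_matrix(make_matrix(g))
        assert dm.iloc[0, 1] == pytest.approx(0.5)
        assert dm.iloc[0, 2] == pytest.approx((2 + 2 + 0) / 6)
        assert dm.iloc[1, 2] == pytest.approx((1 + 1 + 1) / 6)

    def test_pairwise_deletion(self):
        g = np.array([[0, 2], [MISSING, 2], [2, 0]], dtype=np.int8)
        dm = p_distance_matrix(make_matrix(g))
        # only sites 0 and 2 compared: (2 + 2)/ (2*2)
        assert dm.iloc[0, 1] == pytest.approx(1.0)


def tree_path_distances(newick, taxa):
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    pdm = tree.phylogenetic_distance_matrix()
    labels = {t.label: t for t in tns}
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pdm.distance(labels[taxa[i]], labels[taxa[j]])
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        nwk = neighbor_joining(D, ["a", "b", "c"])
        got = tree_path_distances(nwk, ["a", "b", "c"])
        assert np.allclose(got, D, atol=1e-12)

    def test_additive_four_taxon_recovery(self):
        # tree ((a:2,b:3):1,(c:4,d:5)); path distances are additive
        D = np.array([
            [0.0, 5.0, 7.0, 8.0],
            [5.0, 0.0, 8.0, 9.0],
            [7.0, 8.0, 0.0, 9.0],
            [8.0, 9.0, 9.0, 0.0],
        ])
        nwk = neighbor_joining(D, list("abcd"))
        got = tree_path_distances(nwk, list("abcd"))
        assert np.allclose(got, D, atol=1e-9)

    def test_label_permutation_isomorphic(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.1, 1.0, size=(6, 6))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"t{i}" for i in range(6)]
        perm = rng.permutation(6)
        nwk1 = neighbor_joining(D, labels)
        nwk2 = neighbor_joining(D[np.ix_(perm, perm)], [labels[i] for i in perm])
        d1 = tree_path_distances(nwk1, labels)
        d2 = tree_path_distances(nwk2, labels)
        assert np.allclose(d1, d2, atol=1e-9)

    def test_nan_rejected(self):
        D = np.array([[0.0, np.nan, 1.0], [np.nan, 0.0, 1.0], [1.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            neighbor_joining(D)

    def test_agrees_with_scikit_bio_topology(self):
        import skbio

        rng = np.random.default_rng(10)
        base = rng.uniform(0.2, 1.0, size=(7, 7))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"x{i}" for i in range(7)]
        ours = dendropy.Tree.get(data=neighbor_joining(D, labels), schema="newick")
        ref_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        theirs = dendropy.Tree.get(data=str(ref_tree), schema="newick",
                                   taxon_namespace=ours.taxon_namespace)
        ours.encode_bipartitions()
        theirs.encode_bipartitions()
        ours_bips = {b.split_as_bitstring() for b in ours.bipartition_encoding}
        theirs_bips = {b.split_as_bitstring() for b in theirs.bipartition_encoding}
        assert ours_bips == theirs_bips
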