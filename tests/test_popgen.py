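"""Allele frequencies, Hardy-Weinberg tests and Tajima's D."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from methylpop import popgen
from methylpop.popgen import (
    GenotypeCounts, HaplotypeMatrix, MonomorphicError,
    allele_freq_from_genotype_freqs, allele_frequencies,
    counts_from_proportions, drop_high_missing_sites, filter_by_maf,
    genotype_pi, hwe_chisq, hwe_expected, maf, pairwise_pi,
    tajima_constants, tajimas_d,
)

from conftest import brute_force_pi


def oracle_constants(n):
    """Direct re-evaluation of the Tajima constant chain."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return a1, a2, b1, b2, c1, c2, c1 / a1, c2 / (a1**2 + a2)


def oracle_d(hap):
    """Independent Tajima's D: brute-force pi + direct constants."""
    a1, *_, e1, e2 = oracle_constants(hap.n)
    seg = [j for j in range(hap.S)
           if 0 < (hap.alleles[:, j] == 1).sum() < hap.n]
    S = len(seg)
    pi = brute_force_pi(hap)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestAlleleFrequencies:
    @pytest.mark.parametrize("counts,p", [
        ((10, 6, 8), 26 / 48),   # high-altitude Andean reconstruction
        ((5, 0, 0), 1.0),
        ((1, 2, 1), 0.5),
    ])
    def test_from_counts(self, counts, p):
        freqs = allele_frequencies(GenotypeCounts("x", *counts))
        assert freqs.p == pytest.approx(p, abs=1e-12)
        assert freqs.p + freqs.q == pytest.approx(1.0, abs=1e-12)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            allele_frequencies(GenotypeCounts("x", 0, 0, 0))

    @pytest.mark.parametrize("f_hom,f_het,p", [
        (0.46, 0.26, 0.59),  # pooled high-altitude, A orientation
        (0.31, 0.54, 0.58),  # pooled low-altitude, G orientation
        (0.25, 0.50, 0.50),
    ])
    def test_from_proportions(self, f_hom, f_het, p):
        assert allele_freq_from_genotype_freqs(f_hom, f_het) == pytest.approx(
            p, abs=1e-9)

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError):
            allele_freq_from_genotype_freqs(-0.1, 0.5)

    def test_count_reconstruction_round_half_away(self):
        c = counts_from_proportions(0.42, 0.25, 0.33, 24, "HA")
        assert (c.n_hom_ref, c.n_het, c.n_hom_alt) == (10, 6, 8)


class TestHardyWeinberg:
    def test_expected_counts(self, andean_high_counts):
        exp = hwe_expected(andean_high_counts)
        p = 26 / 48
        assert exp == pytest.approx(
            (24 * p**2, 48 * p * (1 - p), 24 * (1 - p) ** 2), abs=1e-9)
        assert sum(exp) == pytest.approx(24, abs=1e-9)

    def test_exact_equilibrium(self):
        res = hwe_chisq(GenotypeCounts("x", 25, 50, 25))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.f_hat == pytest.approx(0.0, abs=1e-12)

    def test_published_andean_statistic(self, andean_high_counts):
        res = hwe_chisq(andean_high_counts)
        assert res.chi2 == pytest.approx(5.916, abs=5e-4)
        assert res.p_value == pytest.approx(0.015, abs=5e-4)
        assert res.df == 1
        assert res.f_hat > 0  # heterozygote deficit

    def test_hand_evaluated_example(self):
        # p=0.7, n=50: expected (24.5, 21, 4.5).
        res = hwe_chisq(GenotypeCounts("x", 30, 10, 10))
        assert res.chi2 == pytest.approx(
            5.5**2 / 24.5 + 11**2 / 21 + 5.5**2 / 4.5, abs=1e-9)

    def test_monomorphic_undefined(self):
        with pytest.raises(MonomorphicError):
            hwe_chisq(GenotypeCounts("x", 12, 0, 0))

    def test_matches_scipy_over_random_counts(self, rng):
        for _ in range(300):
            c = GenotypeCounts("x", *rng.integers(0, 40, 3))
            freqs_ok = 0 < 2 * c.n_hom_ref + c.n_het < 2 * c.n
            if not freqs_ok:
                continue
            res = hwe_chisq(c)
            expected = hwe_expected(c)
            ref_chi2, ref_p = stats.chisquare(
                [c.n_hom_ref, c.n_het, c.n_hom_alt], expected, ddof=1)
            assert res.chi2 == pytest.approx(ref_chi2, abs=1e-9)
            assert res.p_value == pytest.approx(ref_p, abs=1e-9)


class TestSiteFilters:
    def test_maf_examples(self):
        assert maf(np.array([0, 0, 0, 1])) == 0.25
        assert maf(np.array([0, 1, 0, 1])) == 0.5
        assert maf(np.array([0, 0, 0, 0])) == 0.0

    def test_maf_ignores_missing(self):
        assert maf(np.array([0, 1, -1, -1, 1, 1])) == 0.25

    def test_maf_all_missing(self):
        with pytest.raises(ValueError):
            maf(np.array([-1, -1]))

    def test_strict_threshold(self):
        # 20 haplotypes: singleton site has MAF exactly 0.05.
        a = np.zeros((20, 3), dtype=np.int8)
        a[0, 0] = 1            # MAF 0.05 -> removed at threshold 0.05
        a[:2, 1] = 1           # MAF 0.10 -> retained
        a[:10, 2] = 1          # MAF 0.50 -> retained
        hap = HaplotypeMatrix([5, 9, 14], a)
        out = filter_by_maf(hap, 0.05)
        assert list(out.positions) == [9, 14]
        out_all = filter_by_maf(hap, 0.0)
        assert out_all.S == 3  # threshold 0 keeps all polymorphic sites

    def test_high_missingness_dropped(self):
        a = np.zeros((10, 2), dtype=np.int8)
        a[:5, 0] = 1
        a[:3, 1] = -1
        a[5, 1] = 1
        hap = drop_high_missing_sites(HaplotypeMatrix([1, 2], a))
        assert list(hap.positions) == [1]


class TestTajimaConstants:
    def test_small_n(self):
        assert tajima_constants(2)[0] == 1.0
        assert tajima_constants(20)[0] == pytest.approx(
            sum(1 / i for i in range(1, 20)), abs=1e-12)
        assert tajima_constants(24)[2] == pytest.approx(25 / 69, abs=1e-12)

    def test_reproduce_defining_formulas(self):
        for n in range(4, 201):
            ours = tajima_constants(n)
            np.testing.assert_allclose(ours, oracle_constants(n), atol=1e-12)
            assert ours[6] > 0 and ours[7] > 0  # e1, e2 positive

    def test_rejects_single_haplotype(self):
        with pytest.raises(ValueError):
            tajima_constants(1)


class TestPi:
    def test_single_difference(self):
        hap = HaplotypeMatrix([3], np.array([[0], [1]], dtype=np.int8))
        assert pairwise_pi(hap) == 1.0

    def test_balanced_split(self, split_matrix):
        one_site = split_matrix.take_sites(np.array([0]))
        assert pairwise_pi(one_site) == pytest.approx(100 / 190, abs=1e-12)

    def test_identical_haplotypes(self):
        hap = HaplotypeMatrix([1, 2], np.zeros((4, 2), dtype=np.int8))
        assert pairwise_pi(hap) == 0.0

    def test_matches_brute_force_random_matrices(self, rng):
        for _ in range(15):
            n = int(rng.integers(2, 31))
            S = int(rng.integers(1, 51))
            a = rng.integers(0, 2, size=(n, S)).astype(np.int8)
            hap = HaplotypeMatrix(np.arange(1, S + 1), a)
            assert pairwise_pi(hap) == pytest.approx(brute_force_pi(hap),
                                                     abs=1e-9)
            # closed form on complete data
            p = a.mean(axis=0)
            closed = np.sum(2 * p * (1 - p)) * n / (n - 1)
            assert pairwise_pi(hap) == pytest.approx(closed, abs=1e-9)

    def test_missing_excluded_pairwise(self, rng):
        a = rng.integers(0, 2, size=(8, 10)).astype(np.int8)
        a[rng.random((8, 10)) < 0.2] = -1
        hap = HaplotypeMatrix(np.arange(1, 11), a)
        assert pairwise_pi(hap) == pytest.approx(brute_force_pi(hap), abs=1e-9)


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        hap = HaplotypeMatrix(np.empty(0, int), np.zeros((5, 0), np.int8))
        with pytest.warns(UserWarning, match="undefined"):
            comp = tajimas_d(hap)
        assert math.isnan(comp.D)
        assert comp.S == 0

    def test_intermediate_frequency_sites_inflate_d(self, split_matrix):
        comp = tajimas_d(split_matrix)
        assert comp.D == pytest.approx(oracle_d(split_matrix), abs=1e-9)
        assert comp.D > 2  # strong intermediate-frequency excess

    def test_singletons_depress_d(self):
        hap = HaplotypeMatrix(np.arange(1, 21), np.eye(20, dtype=np.int8))
        comp = tajimas_d(hap)
        assert comp.D < 0
        assert comp.D == pytest.approx(oracle_d(hap), abs=1e-9)

    def test_component_identity(self, split_matrix):
        c = tajimas_d(split_matrix)
        assert c.D == pytest.approx(
            (c.pi - c.S / c.a1) / math.sqrt(c.e1 * c.S + c.e2 * c.S * (c.S - 1)),
            abs=1e-12)
        assert c.theta_w == pytest.approx(c.S / c.a1, abs=1e-12)

    def test_monotone_in_site_frequency_class(self, rng):
        base = rng.integers(0, 2, size=(10, 8)).astype(np.int8)
        hap = HaplotypeMatrix(np.arange(1, 9), base)
        d0 = tajimas_d(hap).D
        split = np.zeros((10, 1), np.int8)
        split[:5] = 1
        with_split = HaplotypeMatrix(np.arange(1, 10),
                                     np.hstack([base, split]))
        singleton = np.zeros((10, 1), np.int8)
        singleton[0] = 1
        with_single = HaplotypeMatrix(np.arange(1, 10),
                                      np.hstack([base, singleton]))
        assert tajimas_d(with_split).D >= d0 - 1e-12
        assert tajimas_d(with_single).D <= d0 + 1e-12
        assert tajimas_d(with_split).D == pytest.approx(
            oracle_d(with_split), abs=1e-9)

    def test_warns_below_four_haplotypes(self):
        # At n=3 the variance constants e1, e2 are exactly zero, so D is
        # undefined as well as unreliable.
        hap = HaplotypeMatrix([1], np.array([[0], [1], [1]], dtype=np.int8))
        with pytest.warns(UserWarning, match="unreliable"):
            comp = tajimas_d(hap)
        assert math.isnan(comp.D)
        assert comp.pi == pytest.approx(2 / 3, abs=1e-12)


class TestGenotypePi:
    def test_two_heterozygotes(self):
        d = np.array([[1], [1]])
        assert genotype_pi(d) == pytest.approx(2 * 0.25 * 4 / 3, abs=1e-9)

    def test_monomorphic(self):
        assert genotype_pi(np.zeros((5, 3), int)) == 0.0

    def test_agrees_with_haplotype_pi_on_phased_data(self, rng):
        hap_alleles = rng.integers(0, 2, size=(12, 9)).astype(np.int8)
        hap = HaplotypeMatrix(np.arange(1, 10), hap_alleles)
        dosages = hap_alleles[0::2] + hap_alleles[1::2]
        assert genotype_pi(dosages) == pytest.approx(
            pairwise_pi(hap) , abs=1e-9)
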