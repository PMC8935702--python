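import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from cfspectrum import (
    HaplotypeDistribution,
    InvalidEntryError,
    SimulationConfig,
    SnpSite,
    collapse_top_k,
    combined_top_share,
    compare_block_distributions,
    filter_snps,
    haplotype_frequencies,
    hwe_exact_test,
    joint_genotype_association,
    simulate_phased_cohort,
)

from conftest import make_phased


def hwe_exact_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Full exact-rational enumeration of the conditional HWE distribution."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        # multinomial genotype arrangements × 2^het allele orderings,
        # over the C(2n, rare) ways to place the rare alleles
        probs[het] = Fraction(
            math.factorial(n) * 2**het,
            math.factorial(hom_rare) * math.factorial(het) * math.factorial(hom_common),
        ) * Fraction(
            math.factorial(rare) * math.factorial(2 * n - rare), math.factorial(2 * n)
        )
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration with exact rationals."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(r2, c1 - k), comb(n, c1))
        for k in range(lo, hi + 1)
    }
    obs = probs[a]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHWEExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(25, 0, 0) == 1.0

    def test_extreme_heterozygote_excess(self):
        assert hwe_exact_test(0, 100, 0) < 1e-20
        assert hwe_exact_test(57, 14, 50) < 1e-10

    def test_matches_enumeration_for_all_small_tables(self):
        for n in range(1, 31):
            for n_aa in range(n + 1):
                for n_Aa in range(n - n_aa + 1):
                    n_AA = n - n_aa - n_Aa
                    got = hwe_exact_test(n_AA, n_Aa, n_aa)
                    want = hwe_exact_enumeration(n_AA, n_Aa, n_aa)
                    assert got == pytest.approx(want, abs=1e-12), (n_AA, n_Aa, n_aa)

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidEntryError):
            hwe_exact_test(0, 0, 0)


class TestFilterSnps:
    def _cohort_with_planted_failures(self):
        snps = [
            SnpSite("7", 1, "A", "G", id="ok"),
            SnpSite("7", 2, "A", "G", id="rare"),     # MAF < 0.01
            SnpSite("7", 3, "A", "G", id="het_all"),  # HWE failure
        ]
        rng = np.random.default_rng(42)
        n = 200
        ok = rng.random((2 * n,)) < 0.3
        rare = np.zeros(2 * n, dtype=bool)
        rare[0] = True  # MAF 1/400 = 0.0025
        het = np.tile([True, False], n)  # every individual heterozygous
        alleles = np.where(
            np.stack([ok, rare, het], axis=1), "G", "A"
        )
        from cfspectrum import PhasedCohort

        return PhasedCohort(snps=snps, alleles=alleles)

    def test_planted_failures_removed(self):
        cohort = self._cohort_with_planted_failures()
        kept = filter_snps(cohort, maf_min=0.01, hwe_min=0.001)
        assert [s.id for s in kept.snps] == ["ok"]
        assert kept.alleles.shape == (cohort.n_haplotypes, 1)

    def test_survivors_match_per_snp_brute_force(self):
        cohort = self._cohort_with_planted_failures()
        kept = filter_snps(cohort, maf_min=0.01, hwe_min=0.001)
        expected = [
            s.id
            for j, s in enumerate(cohort.snps)
            if cohort.maf(j) >= 0.01
            and hwe_exact_enumeration(*cohort.genotype_counts(j)) >= 0.001
        ]
        assert [s.id for s in kept.snps] == expected

    def test_maf_boundary_is_inclusive(self, two_snp_sites):
        # one alt among 100 haplotypes at snp1: MAF exactly 0.01
        haps = ["GT"] * 99 + ["AT"]
        cohort = make_phased(two_snp_sites, haps)
        kept = filter_snps(cohort, maf_min=0.01, hwe_min=0.0)
        assert "rs213950" in [s.id for s in kept.snps]

    def test_all_filtered_warns_and_empties(self, two_snp_sites):
        cohort = make_phased(two_snp_sites, ["GT"] * 10)
        with pytest.warns(UserWarning):
            kept = filter_snps(cohort, maf_min=0.01)
        assert kept.snps == []


class TestHaplotypeFrequencies:
    def test_all_ref_cohort(self, two_snp_sites):
        cohort = make_phased(two_snp_sites, ["GT"] * 4)
        d = haplotype_frequencies(cohort, ["rs213950", "rs1042077"])
        assert d.counts == {"GT": 4}
        assert d.frequencies == {"GT": 1.0}

    def test_frequencies_sum_to_one(self, tiny_phased):
        d = haplotype_frequencies(tiny_phased, ["rs213950", "rs1042077"])
        assert sum(d.frequencies.values()) == pytest.approx(1.0)
        assert d.total == tiny_phased.n_haplotypes

    def test_unknown_snp_rejected(self, tiny_phased):
        with pytest.raises(InvalidEntryError):
            haplotype_frequencies(tiny_phased, ["rs000000"])

    def test_sampling_recovers_pool_within_3sd(self):
        pool = {"AG": 0.5, "GT": 0.3, "GG": 0.2}
        n = 5000
        cfg = SimulationConfig(
            n_individuals=n, haplotype_pool=pool, plp_rate=0.0, seed=7
        )
        cohort = simulate_phased_cohort(cfg)
        d = haplotype_frequencies(cohort, ["rs213950", "rs1042077"])
        freqs = d.frequencies
        for hap, p in pool.items():
            sd = math.sqrt(p * (1 - p) / (2 * n))
            assert abs(freqs[hap] - p) <= 3 * sd


class TestCollapseTopK:
    def test_fewer_than_k_unchanged_with_zero_other(self):
        d = HaplotypeDistribution("b", {"AA": 5, "AB": 3})
        out = collapse_top_k(d, k=5)
        assert out.counts == {"AA": 5, "AB": 3}

    def test_seven_haplotypes_collapse_to_six_categories(self):
        counts = {f"H{i}": 10 - i for i in range(7)}
        out = collapse_top_k(HaplotypeDistribution("b", counts), k=5)
        assert len(out.counts) == 6
        assert out.total == sum(counts.values())
        assert out.counts["other"] == counts["H5"] + counts["H6"]

    def test_tie_at_rank_k_breaks_lexicographically(self):
        d = HaplotypeDistribution("b", {"B": 3, "A": 3, "C": 3})
        out = collapse_top_k(d, k=2)
        assert set(out.counts) == {"A", "B", "other"}
        assert out.counts["other"] == 3


class TestCompareBlockDistributions:
    def test_identical_distributions(self):
        d = HaplotypeDistribution("b", {"AA": 40, "AB": 60})
        assert compare_block_distributions(d, d) == pytest.approx(1.0)

    def test_disjoint_supports_highly_significant(self):
        d1 = HaplotypeDistribution("b", {"AA": 500})
        d2 = HaplotypeDistribution("b", {"AB": 500})
        assert compare_block_distributions(d1, d2) < 1e-100

    def test_matches_closed_form_chi2(self):
        d1 = HaplotypeDistribution("b", {"AA": 30, "AB": 70})
        d2 = HaplotypeDistribution("b", {"AA": 50, "AB": 50})
        n = 200
        stat = n * (30 * 50 - 70 * 50) ** 2 / (100 * 100 * 80 * 120)
        assert compare_block_distributions(d1, d2) == pytest.approx(
            float(stats.chi2.sf(stat, 1)), rel=1e-12
        )

    def test_symmetric_in_arguments(self):
        d1 = HaplotypeDistribution("b", {"AA": 30, "AB": 70, "BB": 10})
        d2 = HaplotypeDistribution("b", {"AA": 55, "AB": 45})
        assert compare_block_distributions(d1, d2) == pytest.approx(
            compare_block_distributions(d2, d1), rel=1e-12
        )

    def test_single_shared_category_rejected(self):
        d1 = HaplotypeDistribution("b", {"AA": 10})
        d2 = HaplotypeDistribution("b", {"AA": 20})
        with pytest.raises(InvalidEntryError):
            compare_block_distributions(d1, d2)


class TestCombinedTopShare:
    def test_single_block_equals_top_frequency(self, tiny_phased):
        block = ["rs213950", "rs1042077"]
        d = haplotype_frequencies(tiny_phased, block)
        top = max(d.frequencies.values())
        assert combined_top_share(tiny_phased, [block]) == pytest.approx(top)

    def test_identical_haplotypes_share_one(self, two_snp_sites):
        cohort = make_phased(two_snp_sites, ["AG"] * 8)
        assert combined_top_share(cohort, [["rs213950"], ["rs1042077"]]) == 1.0

    def test_two_block_toy_matches_enumeration(self, two_snp_sites):
        haps = ["GT", "GT", "GG", "AT", "AG", "GT", "AG", "AG"]
        cohort = make_phased(two_snp_sites, haps)
        from collections import Counter

        want = Counter(haps).most_common(1)[0][1] / len(haps)
        got = combined_top_share(cohort, [["rs213950"], ["rs1042077"]])
        assert got == pytest.approx(want)

    def test_bounded_by_per_block_top_shares(self):
        cfg = SimulationConfig(
            n_individuals=500,
            haplotype_pool={"AG": 0.4, "AT": 0.25, "GT": 0.2, "GG": 0.15},
            plp_rate=0.0,
            seed=5,
        )
        cohort = simulate_phased_cohort(cfg)
        blocks = [["rs213950"], ["rs1042077"]]
        combined = combined_top_share(cohort, blocks)
        for b in blocks:
            d = haplotype_frequencies(cohort, b)
            assert combined <= max(d.frequencies.values()) + 1e-12

    def test_empty_block_list_rejected(self, tiny_phased):
        with pytest.raises(InvalidEntryError):
            combined_top_share(tiny_phased, [])


class TestJointGenotypeAssociation:
    def test_fisher_matches_hypergeometric_enumeration(self):
        got = float(stats.fisher_exact([[3, 1], [1, 3]])[1])
        assert got == pytest.approx(fisher_two_sided_enumeration(3, 1, 1, 3), abs=1e-12)

    def test_labels_cover_four_joint_genotypes(self, tiny_phased):
        res = joint_genotype_association(tiny_phased, "rs213950", "rs1042077")
        assert set(res) == {"G-T", "G-G", "A-T", "A-G"}

    def test_perfect_association_tiny_cohort(self, two_snp_sites):
        # all P/LP flags sit on the A-G background
        haps = ["AG", "GT"] * 6
        flags = [h == "AG" for h in haps]
        cohort = make_phased(two_snp_sites, haps, plp_flags=flags)
        orv, p = joint_genotype_association(cohort, "rs213950", "rs1042077")["A-G"]
        assert math.isinf(orv)
        # two-sided Fisher on [[6,0],[0,6]]: p = 2/C(12,6) = 2/924
        assert p == pytest.approx(2 / 924, abs=1e-12)

    def test_no_flags_rejected(self, two_snp_sites):
        cohort = make_phased(two_snp_sites, ["AG", "GT"])
        with pytest.raises(InvalidEntryError):
            joint_genotype_association(cohort, "rs213950", "rs1042077")
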