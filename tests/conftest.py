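import numpy as np
import pytest

from cfspectrum import CohortCounts, PhasedCohort, SnpSite


@pytest.fixture(scope="session")
def children_counts() -> CohortCounts:
    """Published children-cohort tallies: 110 carriers among 20,905."""
    return CohortCounts(
        N=20905, N_male=12773, N_female=8132, C=110, C_male=73, C_female=37
    )


@pytest.fixture(scope="session")
def parents_counts() -> CohortCounts:
    """Published parents-cohort tallies: 60 carriers among 10,038."""
    return CohortCounts(
        N=10038, N_male=5012, N_female=5026, C=60, C_male=38, C_female=22
    )


@pytest.fixture
def two_snp_sites() -> list[SnpSite]:
    return [
        SnpSite(chrom="7", pos=117199644, ref="G", alt="A", id="rs213950"),
        SnpSite(chrom="7", pos=117227792, ref="T", alt="G", id="rs1042077"),
    ]


def make_phased(snps, hap_strings, plp_flags=None) -> PhasedCohort:
    """Build a PhasedCohort from explicit haplotype strings (2 per individual)."""
    alleles = np.array([list(h) for h in hap_strings], dtype="<U1")
    flags = None if plp_flags is None else np.asarray(plp_flags, dtype=bool)
    return PhasedCohort(snps=snps, alleles=alleles, plp_flags=flags)


@pytest.fixture
def tiny_phased(two_snp_sites) -> PhasedCohort:
    """3 individuals / 6 haplotypes over the two tag SNPs."""
    return make_phased(
        two_snp_sites,
        ["GT", "AG", "GT", "GT", "AG", "GG"],
        plp_flags=[False, True, False, False, True, False],
    )
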