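"""Haplotype-block frequency spectra and founder-genotype association.

Works on phased cohorts: each individual contributes two haplotypes (allele
strings over an ordered SNP set, e.g. from a phased VCF).  SNPs are filtered
on minor allele frequency and an exact Hardy–Weinberg test before block
analysis.  Per-block haplotype distributions are collapsed to the top-k most
frequent classes plus "other", and compared across cohorts by Pearson χ².
The joint genotype at two tag SNPs (e.g. rs213950–rs1042077 in CFTR exons)
is tested for association with pathogenic-allele backgrounds by Fisher's
exact test, the classic signature of a founder mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .core import InvalidEntryError, VariantKey


@dataclass(frozen=True, slots=True)
class SnpSite:
    """One biallelic SNP: VCF-style key plus an optional rsID."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def name(self) -> str:
        return self.id if self.id not in (".", "") else f"{self.chrom}:{self.pos}"


class PhasedCohort:
    """N individuals × 2 phased haplotypes over an ordered SNP set.

    ``alleles`` is a (2N, S) array of single-character bases; haplotypes
    2i and 2i+1 belong to individual i.  ``plp_flags`` marks haplotypes
    carrying a pathogenic / likely-pathogenic variant (outside the SNP set).
    """

    def __init__(
        self,
        snps: Sequence[SnpSite],
        alleles: np.ndarray,
        plp_flags: np.ndarray | None = None,
    ) -> None:
        alleles = np.asarray(alleles, dtype="<U1")
        if alleles.ndim != 2 or alleles.shape[1] != len(snps):
            raise InvalidEntryError(
                f"alleles shape {alleles.shape} does not match {len(snps)} SNPs"
            )
        if alleles.shape[0] % 2 != 0:
            raise InvalidEntryError("odd number of haplotypes: expected 2 per individual")
        for j, snp in enumerate(snps):
            col = alleles[:, j]
            bad = ~np.isin(col, [snp.ref, snp.alt])
            if bad.any():
                raise InvalidEntryError(
                    f"allele {col[bad][0]!r} at {snp.name} is neither "
                    f"ref {snp.ref!r} nor alt {snp.alt!r}"
                )
        if plp_flags is None:
            plp_flags = np.zeros(alleles.shape[0], dtype=bool)
        plp_flags = np.asarray(plp_flags, dtype=bool)
        if plp_flags.shape != (alleles.shape[0],):
            raise InvalidEntryError("plp_flags length must equal haplotype count")
        self.snps = list(snps)
        self.alleles = alleles
        self.plp_flags = plp_flags

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    def snp_index(self, snp: str | SnpSite) -> int:
        """Index of a SNP by SnpSite, rsID or 'chrom:pos' name."""
        if isinstance(snp, SnpSite):
            for i, s in enumerate(self.snps):
                if s.key == snp.key:
                    return i
            raise InvalidEntryError(f"SNP {snp.name} not in cohort")
        for i, s in enumerate(self.snps):
            if snp in (s.id, s.name):
                return i
        raise InvalidEntryError(f"SNP {snp!r} not in cohort")

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(hom-ref, het, hom-alt) individual counts at SNP index j."""
        is_alt = self.alleles[:, j] == self.snps[j].alt
        per_ind = is_alt.reshape(-1, 2).sum(axis=1)
        return (
            int((per_ind == 0).sum()),
            int((per_ind == 1).sum()),
            int((per_ind == 2).sum()),
        )

    def maf(self, j: int) -> float:
        af = float((self.alleles[:, j] == self.snps[j].alt).mean())
        return min(af, 1.0 - af)


@dataclass(frozen=True)
class HaplotypeDistribution:
    """Haplotype allele counts within one block of one cohort."""

    block_id: str
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise InvalidEntryError("negative haplotype count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        t = self.total
        return {h: c / t for h, c in self.counts.items()}


@dataclass(frozen=True, slots=True)
class JointGenotypeLabel:
    """Ordered allele pair at two tag SNPs on one haplotype, e.g. "A-G"."""

    allele_1: str
    allele_2: str

    @property
    def label(self) -> str:
        return f"{self.allele_1}-{self.allele_2}"


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more likely than the observed one — the
    probability-sum form of the exact test.  Returns 1.0 for monomorphic
    sites.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise InvalidEntryError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise InvalidEntryError("empty genotype table")
    n_a = 2 * n_aa + n_Aa  # count of the 'a' allele
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-12)].sum()))


def filter_snps(
    cohort: PhasedCohort, maf_min: float = 0.01, hwe_min: float = 0.001
) -> PhasedCohort:
    """Retain SNPs with MAF ≥ maf_min and HWE exact p ≥ hwe_min (inclusive).

    Haplotypes are re-projected onto the surviving SNPs; P/LP flags are kept.
    """
    keep = []
    for j in range(len(cohort.snps)):
        if cohort.maf(j) < maf_min:
            continue
        if hwe_exact_test(*cohort.genotype_counts(j)) < hwe_min:
            continue
        keep.append(j)
    if not keep:
        import warnings

        warnings.warn("all SNPs removed by MAF/HWE filtering", stacklevel=2)
    return PhasedCohort(
        snps=[cohort.snps[j] for j in keep],
        alleles=cohort.alleles[:, keep],
        plp_flags=cohort.plp_flags.copy(),
    )


def _block_strings(cohort: PhasedCohort, block_snps: Sequence[str | SnpSite]) -> np.ndarray:
    idx = [cohort.snp_index(s) for s in block_snps]
    cols = cohort.alleles[:, idx]
    return np.array(["".join(row) for row in cols])


def haplotype_frequencies(
    cohort: PhasedCohort,
    block_snps: Sequence[str | SnpSite],
    block_id: str = "block",
) -> HaplotypeDistribution:
    """Count each distinct allele string over the block's SNPs across 2N haplotypes."""
    strings = _block_strings(cohort, block_snps)
    haps, counts = np.unique(strings, return_counts=True)
    return HaplotypeDistribution(
        block_id=block_id, counts={h: int(c) for h, c in zip(haps, counts)}
    )


def collapse_top_k(d: HaplotypeDistribution, k: int = 5) -> HaplotypeDistribution:
    """Keep the k most frequent haplotypes; merge the rest into "other".

    Ties at rank k break lexicographically on the haplotype string, so the
    result is deterministic.  Total count is conserved.
    """
    if k < 1:
        raise InvalidEntryError(f"k must be >= 1, got {k}")
    ranked = sorted(d.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = dict(ranked[:k])
    rest = sum(c for _, c in ranked[k:])
    if rest or len(ranked) > k:
        top["other"] = rest
    return HaplotypeDistribution(block_id=d.block_id, counts=top)


def compare_block_distributions(
    d1: HaplotypeDistribution, d2: HaplotypeDistribution
) -> float:
    """Pearson χ² p-value for a haplotype-spectrum difference between cohorts.

    Uses the union of both distributions' categories, dropping categories
    with zero combined count; requires at least two shared categories.
    """
    if d1.total == 0 or d2.total == 0:
        raise InvalidEntryError("cannot compare an empty distribution")
    cats = sorted(set(d1.counts) | set(d2.counts))
    r1 = np.array([d1.counts.get(c, 0) for c in cats], dtype=float)
    r2 = np.array([d2.counts.get(c, 0) for c in cats], dtype=float)
    nz = (r1 + r2) > 0
    r1, r2 = r1[nz], r2[nz]
    if nz.sum() < 2:
        raise InvalidEntryError("only one haplotype category shared: test undefined")
    return float(stats.chi2_contingency(np.vstack([r1, r2]), correction=False)[1])


def combined_top_share(
    cohort: PhasedCohort, blocks: Sequence[Sequence[str | SnpSite]]
) -> float:
    """Frequency of the modal concatenated cross-block haplotype.

    Concatenates each haplotype's allele strings across all blocks and
    returns the frequency of the most common combination among 2N
    haplotypes.  Always ≤ each single block's top share.
    """
    if not blocks:
        raise InvalidEntryError("no blocks given")
    parts = [_block_strings(cohort, b) for b in blocks]
    combined = parts[0]
    for p in parts[1:]:
        combined = np.char.add(np.char.add(combined, "|"), p)
    _, counts = np.unique(combined, return_counts=True)
    return float(counts.max() / combined.shape[0])


def joint_genotype_association(
    cohort: PhasedCohort, snp1: str | SnpSite, snp2: str | SnpSite
) -> dict[str, tuple[float, float]]:
    """Fisher's exact association of each two-SNP joint genotype with P/LP alleles.

    For each of the four ordered allele pairs at (snp1, snp2) — labelled e.g.
    "A-G" — builds the 2×2 table of P/LP-carrying vs non-carrying haplotypes
    with vs without the label, and returns {label: (odds_ratio, two-sided
    Fisher p)}.  Requires at least one P/LP-carrying haplotype.
    """
    flags = cohort.plp_flags
    if not flags.any():
        raise InvalidEntryError("no P/LP-carrying haplotypes in cohort")
    i1, i2 = cohort.snp_index(snp1), cohort.snp_index(snp2)
    s1, s2 = cohort.snps[i1], cohort.snps[i2]
    a1 = cohort.alleles[:, i1]
    a2 = cohort.alleles[:, i2]
    results: dict[str, tuple[float, float]] = {}
    for b1 in (s1.ref, s1.alt):
        for b2 in (s2.ref, s2.alt):
            lbl = JointGenotypeLabel(b1, b2).label
            has = (a1 == b1) & (a2 == b2)
            table = np.array(
                [
                    [int((flags & has).sum()), int((flags & ~has).sum())],
                    [int((~flags & has).sum()), int((~flags & ~has).sum())],
                ]
            )
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            results[lbl] = (float(odds), float(p))
    return results
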