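"""Synthetic cohorts with the statistical structure the estimators assume.

Generates (a) gender-stratified carrier-count cohorts with genotypes drawn
under Hardy–Weinberg equilibrium at configured pathogenic allele
frequencies, and (b) phased cohorts whose haplotypes are drawn from an
explicit pool, optionally with pathogenic-allele flags enriched on a chosen
haplotype background at a configured odds ratio.  A single seeded
:class:`numpy.random.Generator` drives every draw, so fixed seeds give
bit-identical outputs.

Genotypes are drawn *under* HWE deliberately — the generator tests the
estimators on their own assumptions; an inbreeding-style ``excess_homozygosity``
knob breaks HWE for robustness studies.  Homozygous-affected individuals are
excluded by default, mirroring a screening cohort from which diagnosed
patients have been removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import optimize

from .core import CohortCounts, InvalidEntryError, VariantKey
from .haplotypes import PhasedCohort, SnpSite

#: Default tag SNPs for joint-genotype simulations: rs213950 (c.1408G>A)
#: and rs1042077 (c.2562T>G) in CFTR exons, hg19 coordinates.
DEFAULT_TAG_SNPS = (
    SnpSite(chrom="7", pos=117199644, ref="G", alt="A", id="rs213950"),
    SnpSite(chrom="7", pos=117227792, ref="T", alt="G", id="rs1042077"),
)

#: Default joint-genotype haplotype pool over the two tag SNPs, patterned on
#: East-Asian-like frequencies ("A-G" common, "A-T" rare).
DEFAULT_JOINT_POOL = {"AG": 0.425, "AT": 0.005, "GT": 0.370, "GG": 0.200}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``variant_afs`` maps variant keys to pathogenic allele frequencies for
    carrier-count simulation; ``haplotype_pool`` maps allele strings to
    frequencies for phased simulation.  ``plp_background`` = (haplotype
    string, odds ratio) enriches P/LP flags on that background;
    ``plp_rate`` is the marginal fraction of haplotypes flagged.
    """

    n_individuals: int
    male_fraction: float = 0.5
    variant_afs: dict[VariantKey, float] = field(default_factory=dict)
    haplotype_pool: dict[str, float] = field(default_factory=dict)
    snps: tuple[SnpSite, ...] = DEFAULT_TAG_SNPS
    plp_background: Optional[tuple[str, float]] = None
    plp_rate: float = 110 / 41810
    excess_homozygosity: float = 0.0
    exclude_homozygous: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise InvalidEntryError("n_individuals must be >= 1")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise InvalidEntryError("male_fraction must lie in [0, 1]")
        for key, q in self.variant_afs.items():
            if not 0.0 <= q <= 0.5:
                raise InvalidEntryError(f"allele frequency {q} for {key} outside [0, 0.5]")
        if self.haplotype_pool:
            s = sum(self.haplotype_pool.values())
            if abs(s - 1.0) > 1e-9:
                raise InvalidEntryError(f"haplotype pool frequencies sum to {s}, not 1")
            width = len(self.snps)
            for h in self.haplotype_pool:
                if len(h) != width:
                    raise InvalidEntryError(
                        f"haplotype {h!r} length != {width} SNPs"
                    )
        if self.plp_background is not None:
            label, ratio = self.plp_background
            if ratio <= 0:
                raise InvalidEntryError("enrichment odds ratio must be positive")
            if self.haplotype_pool and label not in self.haplotype_pool:
                raise InvalidEntryError(f"background haplotype {label!r} not in pool")
        if not 0.0 <= self.plp_rate < 1.0:
            raise InvalidEntryError("plp_rate must lie in [0, 1)")
        if not 0.0 <= self.excess_homozygosity <= 1.0:
            raise InvalidEntryError("excess_homozygosity must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[CohortCounts, dict[VariantKey, int]]:
    """Draw a gender-stratified carrier-count cohort.

    Per individual: gender ~ Bernoulli(male_fraction); per variant, genotype
    drawn with hom-alt probability q² + F·q(1−q) and het probability
    2q(1−q)(1−F) where F is ``excess_homozygosity`` (F = 0 is HWE).
    Homozygous-affected individuals (hom-alt at any pathogenic variant) are
    dropped when ``exclude_homozygous``.  Returns the cohort tallies and the
    per-variant heterozygous-carrier map.
    """
    rng = cfg.rng()
    n = cfg.n_individuals
    male = rng.random(n) < cfg.male_fraction
    het_any = np.zeros(n, dtype=bool)
    hom_any = np.zeros(n, dtype=bool)
    het_by_variant: dict[VariantKey, np.ndarray] = {}
    f = cfg.excess_homozygosity
    for key, q in cfg.variant_afs.items():
        p_hom = q * q + f * q * (1.0 - q)
        p_het = 2.0 * q * (1.0 - q) * (1.0 - f)
        u = rng.random(n)
        hom = u < p_hom
        het = (~hom) & (u < p_hom + p_het)
        het_by_variant[key] = het
        het_any |= het
        hom_any |= hom
    keep = ~hom_any if cfg.exclude_homozygous else np.ones(n, dtype=bool)
    male_k, het_k = male[keep], het_any[keep]
    counts = CohortCounts(
        N=int(keep.sum()),
        N_male=int(male_k.sum()),
        N_female=int((~male_k).sum()),
        C=int(het_k.sum()),
        C_male=int((het_k & male_k).sum()),
        C_female=int((het_k & ~male_k).sum()),
    )
    carrier_map = {k: int(v[keep].sum()) for k, v in het_by_variant.items()}
    return counts, carrier_map


def _background_rates(p_marg: float, frac_bg: float, ratio: float) -> tuple[float, float]:
    """Solve per-background flag rates from the marginal rate and odds ratio.

    Finds (p_bg, p_other) with odds(p_bg)/odds(p_other) = ratio and
    frac_bg·p_bg + (1−frac_bg)·p_other = p_marg.
    """
    if p_marg == 0.0:
        return 0.0, 0.0
    if ratio == 1.0 or frac_bg in (0.0, 1.0):
        return p_marg, p_marg

    def gap(p_other: float) -> float:
        odds = ratio * p_other / (1.0 - p_other)
        p_bg = odds / (1.0 + odds)
        return frac_bg * p_bg + (1.0 - frac_bg) * p_other - p_marg

    hi = min(1.0 - 1e-12, p_marg / (1.0 - frac_bg) if frac_bg < 1 else 1.0)
    p_other = float(optimize.brentq(gap, 1e-15, hi))
    odds = ratio * p_other / (1.0 - p_other)
    return odds / (1.0 + odds), p_other


def simulate_phased_cohort(cfg: SimulationConfig) -> PhasedCohort:
    """Draw 2N haplotypes independently from the configured pool.

    If ``plp_background`` is set, P/LP flags are planted on haplotypes so
    that the flag odds on the named background vs all others equal the
    configured odds ratio, with marginal rate ``plp_rate``.
    """
    if not cfg.haplotype_pool:
        raise InvalidEntryError("haplotype_pool is empty")
    rng = cfg.rng()
    haps = sorted(cfg.haplotype_pool)
    freqs = np.array([cfg.haplotype_pool[h] for h in haps])
    draws = rng.choice(len(haps), size=2 * cfg.n_individuals, p=freqs / freqs.sum())
    strings = np.array(haps)[draws]
    alleles = strings.view("<U1").reshape(len(strings), len(cfg.snps))

    flags = np.zeros(len(strings), dtype=bool)
    if cfg.plp_rate > 0:
        if cfg.plp_background is None:
            flags = rng.random(len(strings)) < cfg.plp_rate
        else:
            label, ratio = cfg.plp_background
            frac_bg = cfg.haplotype_pool[label]
            p_bg, p_other = _background_rates(cfg.plp_rate, frac_bg, ratio)
            on_bg = strings == label
            u = rng.random(len(strings))
            flags = np.where(on_bg, u < p_bg, u < p_other)
    return PhasedCohort(snps=list(cfg.snps), alleles=alleles, plp_flags=flags)


def write_fixture_bundle(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate one cohort and write it in every input format the pipeline reads.

    Emits cohort-counts TSV, allele-count TSV, a panel TSV over the
    simulated variants, and a phased VCF; all four round-trip through the
    ``io`` readers unchanged.  Returns {kind: path}.
    """
    from . import io as cfio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, carrier_map = simulate_cohort(cfg)
    paths: dict[str, Path] = {}

    paths["cohort_counts"] = outdir / "cohort_counts.tsv"
    cfio.write_cohort_counts_tsv(paths["cohort_counts"], {"simulated": counts})

    entries = [
        cfio.core.AlleleCountEntry(variant=k, AC=c, AN=2 * counts.N)
        for k, c in sorted(carrier_map.items())
    ]
    paths["allele_counts"] = outdir / "allele_counts.tsv"
    cfio.write_allele_counts_tsv(paths["allele_counts"], entries, population="simulated")

    records = [
        cfio.core.VariantRecord(
            chrom=k[0], pos=k[1], ref=k[2], alt=k[3],
            hgvs_c=f"c.{k[1]}{k[2]}>{k[3]}", legacy="", domain="none", pclass="P",
        )
        for k in sorted(cfg.variant_afs)
    ]
    paths["panel"] = outdir / "panel.tsv"
    cfio.write_panel_tsv(paths["panel"], records)

    if cfg.haplotype_pool:
        phased = simulate_phased_cohort(cfg)
        paths["phased_vcf"] = outdir / "phased.vcf"
        cfio.write_phased_vcf(paths["phased_vcf"], phased)
    return paths
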