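"""Domain types shared by every analysis stage.

Variants are identified by the VCF-style key ``(chrom, pos, ref, alt)`` with
1-based positions; HGVS and legacy names are display-only aliases.  A
*carrier* is an individual with at least one pathogenic / likely-pathogenic
(P/LP) allele; in summary-count mode each carrier contributes exactly one
pathogenic allele (reasonable for a disease-free cohort where compound
genotypes are vanishingly rare).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

VariantKey = tuple[str, int, str, str]

#: Pathogenicity classes: pathogenic, likely pathogenic, uncertain
#: significance, likely benign, benign.
PATHOGENICITY_CLASSES = frozenset({"P", "LP", "VUS", "LB", "B"})

#: CFTR protein domains (two transmembrane domains, two nucleotide-binding
#: domains, the regulatory domain) plus "none" for variants outside them.
PROTEIN_DOMAINS = frozenset({"TMD1", "NBD1", "R", "TMD2", "NBD2", "none"})


class InvalidEntryError(ValueError):
    """Raised when a record violates its construction invariants."""


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """A single sequence variant with its annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    hgvs_c: str = ""
    legacy: str = ""
    domain: str = "none"
    pclass: str = "VUS"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InvalidEntryError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise InvalidEntryError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pclass not in PATHOGENICITY_CLASSES:
            raise InvalidEntryError(f"unknown pathogenicity class {self.pclass!r}")
        if self.domain not in PROTEIN_DOMAINS:
            raise InvalidEntryError(f"unknown protein domain {self.domain!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_plp(self) -> bool:
        return self.pclass in ("P", "LP")


@dataclass(frozen=True, slots=True)
class ScreeningPanel:
    """A named set of variants genotyped to detect carriers."""

    name: str
    variants: frozenset[VariantKey] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.variants

    @property
    def is_empty(self) -> bool:
        return not self.variants


def intersect_panels(a: ScreeningPanel, b: ScreeningPanel) -> ScreeningPanel:
    """Set intersection of two screening panels, named ``a∩b``.

    An empty intersection is a valid result (``is_empty`` flags it).
    """
    return ScreeningPanel(name=f"{a.name}∩{b.name}", variants=a.variants & b.variants)


def carriers_in_panel(
    per_variant_carriers: Mapping[VariantKey, int], panel: ScreeningPanel
) -> int:
    """Total carriers detectable through *panel*.

    Sums carrier counts over variants present in the panel; variants absent
    from the map contribute zero.  Valid under the one-pathogenic-allele-
    per-carrier summary assumption (no individual counted twice).
    """
    for key, count in per_variant_carriers.items():
        if count < 0:
            raise InvalidEntryError(f"negative carrier count {count} for {key}")
    return sum(
        count for key, count in per_variant_carriers.items() if key in panel.variants
    )


@dataclass(frozen=True, slots=True)
class CohortCounts:
    """Gender-stratified individual and heterozygous-carrier tallies.

    The raw material of all three prevalence estimators: ``N`` individuals
    (``N_male`` + ``N_female``) of whom ``C`` carry at least one P/LP allele.
    """

    N: int
    N_male: int
    N_female: int
    C: int
    C_male: int
    C_female: int

    def __post_init__(self) -> None:
        if self.N != self.N_male + self.N_female:
            raise InvalidEntryError(
                f"N ({self.N}) != N_male + N_female ({self.N_male}+{self.N_female})"
            )
        if self.C != self.C_male + self.C_female:
            raise InvalidEntryError(
                f"C ({self.C}) != C_male + C_female ({self.C_male}+{self.C_female})"
            )
        for c, n, label in (
            (self.C, self.N, "total"),
            (self.C_male, self.N_male, "male"),
            (self.C_female, self.N_female, "female"),
        ):
            if not 0 <= c <= n:
                raise InvalidEntryError(f"{label} carriers {c} outside [0, {n}]")

    @property
    def allele_counts(self) -> tuple[int, int]:
        """(pathogenic allele count x, total allele count n) = (C, 2N)."""
        return self.C, 2 * self.N


@dataclass(frozen=True, slots=True)
class AlleleCountEntry:
    """Alternate-allele count ``AC`` out of ``AN`` total alleles for one variant."""

    variant: VariantKey
    AC: int
    AN: int

    def __post_init__(self) -> None:
        if self.AN <= 0:
            raise InvalidEntryError(f"AN must be positive, got {self.AN}")
        if not 0 <= self.AC <= self.AN:
            raise InvalidEntryError(f"AC {self.AC} outside [0, AN={self.AN}]")

    @property
    def AF(self) -> float:
        return self.AC / self.AN

    @property
    def MAF(self) -> float:
        return min(self.AF, 1.0 - self.AF)


def af_of(entry: AlleleCountEntry) -> float:
    """Allele frequency AC/AN of an entry (AN > 0 enforced on construction)."""
    return entry.AF
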