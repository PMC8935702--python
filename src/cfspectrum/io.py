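"""Readers and writers for the pipeline's standard formats.

TSV dialect: tab-separated, UTF-8, mandatory header, ``#``-prefixed comment
lines ignored.  Readers validate and reject — they never silently repair —
schema violations.  Phased VCF is read through cyvcf2 (biallelic SNPs only;
indels and multi-allelic records are skipped with a logged count; any
unphased genotype is an error naming the sample and position).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import core
from .core import AlleleCountEntry, CohortCounts, InvalidEntryError, VariantRecord
from .haplotypes import PhasedCohort, SnpSite

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ["chrom", "pos", "ref", "alt", "hgvs_c", "legacy", "pclass", "domain"]
ALLELE_COLUMNS = ["chrom", "pos", "ref", "alt", "population", "AC", "AN"]
COHORT_COLUMNS = ["cohort", "N", "N_male", "N_female", "C", "C_male", "C_female"]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidEntryError(f"{path}: missing columns {missing}")
    return df


def read_panel_tsv(path: str | Path) -> list[VariantRecord]:
    """Read a screening-panel variant table; duplicate keys are rejected."""
    df = _read_tsv(path, PANEL_COLUMNS)
    records: list[VariantRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = VariantRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                hgvs_c=str(row.hgvs_c),
                legacy=str(row.legacy),
                domain=str(row.domain),
                pclass=str(row.pclass),
            )
        except (ValueError, InvalidEntryError) as exc:
            raise InvalidEntryError(f"{path} line {i}: {exc}") from exc
        if rec.key in seen:
            raise InvalidEntryError(f"{path} line {i}: duplicate variant key {rec.key}")
        seen.add(rec.key)
        records.append(rec)
    return records


def write_panel_tsv(path: str | Path, records: Iterable[VariantRecord]) -> None:
    rows = [
        {
            "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "hgvs_c": r.hgvs_c, "legacy": r.legacy,
            "pclass": r.pclass, "domain": r.domain,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cohort_counts_tsv(path: str | Path) -> dict[str, CohortCounts]:
    """Read gender-stratified cohort tallies, one named cohort per row."""
    df = _read_tsv(path, COHORT_COLUMNS)
    out: dict[str, CohortCounts] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        name = str(row.cohort)
        if name in out:
            raise InvalidEntryError(f"{path} line {i}: duplicate cohort {name!r}")
        try:
            out[name] = CohortCounts(
                N=int(row.N), N_male=int(row.N_male), N_female=int(row.N_female),
                C=int(row.C), C_male=int(row.C_male), C_female=int(row.C_female),
            )
        except (ValueError, InvalidEntryError) as exc:
            raise InvalidEntryError(f"{path} line {i}: {exc}") from exc
    return out


def write_cohort_counts_tsv(
    path: str | Path, cohorts: Mapping[str, CohortCounts]
) -> None:
    rows = [
        {
            "cohort": name, "N": c.N, "N_male": c.N_male, "N_female": c.N_female,
            "C": c.C, "C_male": c.C_male, "C_female": c.C_female,
        }
        for name, c in cohorts.items()
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_allele_counts_tsv(
    path: str | Path, population: str
) -> list[AlleleCountEntry]:
    """Read gnomAD-style per-population allele counts.

    AF is always recomputed from AC/AN, never trusted from the file.  A
    missing population yields an empty list with a warning; AC = AN is
    accepted with a warning (a non-SNP sanity flag).
    """
    df = _read_tsv(path, ALLELE_COLUMNS)
    sub = df[df["population"] == population]
    if sub.empty:
        logger.warning("population %r not found in %s", population, path)
        return []
    entries: list[AlleleCountEntry] = []
    for row in sub.itertuples(index=False):
        entry = AlleleCountEntry(
            variant=(str(row.chrom), int(row.pos), str(row.ref), str(row.alt)),
            AC=int(row.AC),
            AN=int(row.AN),
        )
        if entry.AC == entry.AN:
            logger.warning("AC == AN (%d) at %s: monomorphic alt", entry.AC, entry.variant)
        entries.append(entry)
    return entries


def write_allele_counts_tsv(
    path: str | Path, entries: Iterable[AlleleCountEntry], population: str
) -> None:
    rows = [
        {
            "chrom": e.variant[0], "pos": e.variant[1],
            "ref": e.variant[2], "alt": e.variant[3],
            "population": population, "AC": e.AC, "AN": e.AN,
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=ALLELE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_phased_vcf(path: str | Path) -> PhasedCohort:
    """Load a phased VCF into a :class:`PhasedCohort`.

    Only biallelic SNP records are kept (others are counted and logged).
    Every genotype must be phased ("|" separator) and non-missing.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = vcf.samples
    if not samples:
        raise InvalidEntryError(f"{path}: no samples")
    snps: list[SnpSite] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        site = SnpSite(
            chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
            id=rec.ID or ".",
        )
        col = np.empty(2 * len(samples), dtype="<U1")
        for si, gt in enumerate(rec.genotypes):  # [allele_a, allele_b, phased]
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise InvalidEntryError(
                    f"{path}: missing genotype for sample {samples[si]} at "
                    f"{rec.CHROM}:{rec.POS}"
                )
            if not phased:
                raise InvalidEntryError(
                    f"{path}: unphased genotype for sample {samples[si]} at "
                    f"{rec.CHROM}:{rec.POS}"
                )
            col[2 * si] = site.alt if a else site.ref
            col[2 * si + 1] = site.alt if b else site.ref
        snps.append(site)
        columns.append(col)
    vcf.close()
    if skipped:
        logger.info("%s: skipped %d non-biallelic-SNP records", path, skipped)
    if not snps:
        raise InvalidEntryError(f"{path}: no biallelic SNP records")
    alleles = np.stack(columns, axis=1)
    return PhasedCohort(snps=snps, alleles=alleles)


def write_phased_vcf(path: str | Path, cohort: PhasedCohort) -> None:
    """Write a cohort as minimal phased VCF 4.2 text (GT only)."""
    n = cohort.n_individuals
    sample_names = [f"S{i + 1}" for i in range(n)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = {s.chrom for s in cohort.snps}
        for c in sorted(chroms):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names) + "\n"
        )
        order = sorted(range(len(cohort.snps)),
                       key=lambda j: (cohort.snps[j].chrom, cohort.snps[j].pos))
        for j in order:
            s = cohort.snps[j]
            col = cohort.alleles[:, j]
            gts = [
                f"{int(col[2 * i] == s.alt)}|{int(col[2 * i + 1] == s.alt)}"
                for i in range(n)
            ]
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.id}\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def read_blocks_det(path: str | Path) -> list[list[str]]:
    """Read plink ``.blocks.det`` haplotype-block output: one SNP list per block.

    Expects whitespace-delimited columns with a header containing ``SNPS``;
    SNP ids within a block are '|'-separated.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    if "SNPS" not in df.columns:
        raise InvalidEntryError(f"{path}: no SNPS column (not a .blocks.det file?)")
    return [str(s).split("|") for s in df["SNPS"]]
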