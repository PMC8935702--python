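"""Cross-cohort allele-frequency statistics and screening-panel comparison.

Per-variant allele counts from two cohorts form a 2×2 contingency table
(alt/ref × cohort); association is tested by Pearson χ² without continuity
correction by default, or Fisher's exact test for small expected cells.
Odds ratios at zero cells follow the population-genetics reporting
convention (±infinity) unless the Haldane–Anscombe correction is requested.
Panel-restricted prevalence comparison re-estimates the affected frequency
under each panel's captured pathogenic alleles with the Bayesian estimator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .core import AlleleCountEntry, InvalidEntryError, VariantRecord
from .prevalence import BayesPrior, JEFFREYS, PrevalenceEstimate, estimate_method3

logger = logging.getLogger(__name__)

TestChoice = Literal["chisq", "fisher", "auto"]


@dataclass(frozen=True, slots=True)
class ContingencyTable2x2:
    """Allele counts (a, b) = cohort-1 alt/ref, (c, d) = cohort-2 alt/ref."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InvalidEntryError("contingency counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise InvalidEntryError("all-zero contingency table")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swapped(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True, slots=True)
class AFComparisonResult:
    odds_ratio: float
    p_raw: float
    p_adj: float
    test: Literal["chisq", "fisher"]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= 1.0 or not 0.0 <= self.p_adj <= 1.0:
            raise InvalidEntryError("p-values must lie in [0, 1]")
        if self.p_adj < self.p_raw - 1e-12:
            raise InvalidEntryError("adjusted p below raw p")


def build_allele_table(
    e1: AlleleCountEntry, e2: AlleleCountEntry
) -> ContingencyTable2x2:
    """2×2 table of alt/ref allele counts for the same variant in two cohorts."""
    if e1.variant != e2.variant:
        raise InvalidEntryError(
            f"variant keys differ: {e1.variant} vs {e2.variant}"
        )
    return ContingencyTable2x2(e1.AC, e1.AN - e1.AC, e2.AC, e2.AN - e2.AC)


def odds_ratio(t: ContingencyTable2x2, haldane: bool = False) -> float:
    """(a·d)/(b·c), with +inf when c=0 (and a>0) and 0 when a=0 (and c>0).

    ``haldane=True`` adds 0.5 to every cell (Haldane–Anscombe) for users who
    need a finite estimate at zero cells.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        if a * d == 0:
            return math.nan if (a == 0 and c == 0) else math.inf
        return math.inf
    return (a * d) / (b * c)


def _expected_cells(t: ContingencyTable2x2) -> np.ndarray:
    arr = t.as_array
    total = arr.sum()
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total


def compare_af(
    t: ContingencyTable2x2,
    test: TestChoice = "chisq",
    haldane: bool = False,
    n_tests: int = 1,
) -> AFComparisonResult:
    """Test whether two cohorts' allele frequencies differ.

    Default is Pearson χ² without Yates correction; ``test="auto"`` switches
    to Fisher's exact test when any expected cell is below 5 (logged).
    ``n_tests`` applies a Bonferroni adjustment for a batch of this size.
    """
    chosen: Literal["chisq", "fisher"]
    if test == "auto":
        if (_expected_cells(t) < 5).any():
            chosen = "fisher"
            logger.info("expected cell < 5: selecting Fisher's exact test")
        else:
            chosen = "chisq"
    elif test in ("chisq", "fisher"):
        chosen = test
    else:
        raise InvalidEntryError(f"unknown test {test!r}")

    arr = t.as_array
    if chosen == "fisher":
        p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    else:
        # A zero column margin (no alt allele in either cohort, or no ref)
        # means identical frequencies: statistic 0 by convention.
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            p = 1.0
        else:
            p = float(stats.chi2_contingency(arr, correction=False)[1])
    return AFComparisonResult(
        odds_ratio=odds_ratio(t, haldane=haldane),
        p_raw=p,
        p_adj=adjust_pvalues([p] * n_tests, "bonferroni")[0] if n_tests > 1 else p,
        test=chosen,
    )


def adjust_pvalues(ps: Sequence[float], method: str = "bonferroni") -> list[float]:
    """Bonferroni family-wise correction: each p × m, capped at 1; order kept."""
    if method != "bonferroni":
        raise InvalidEntryError(f"unsupported adjustment method {method!r}")
    m = len(ps)
    out = []
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise InvalidEntryError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out


def domain_af_total(
    entries: Iterable[AlleleCountEntry],
    variants: Iterable[VariantRecord],
    domain: str,
) -> float:
    """Summed allele frequency of the variants mapping to one protein domain."""
    by_key = {v.key: v for v in variants}
    total = 0.0
    for e in entries:
        rec = by_key.get(e.variant)
        if rec is None:
            raise InvalidEntryError(f"no variant record for {e.variant}")
        if rec.domain == domain:
            total += e.AF
    return total


@dataclass(frozen=True, slots=True)
class PanelComparison:
    """Bayesian affected-frequency estimates under two screening panels."""

    estimate_a: PrevalenceEstimate
    estimate_b: PrevalenceEstimate
    odds_ratio: float
    p_value: float

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise InvalidEntryError("panel odds ratio must be positive")


def compare_panel_estimates(
    x_a: int,
    x_b: int,
    n: int,
    prior: BayesPrior = JEFFREYS,
    level: float = 0.95,
) -> PanelComparison:
    """How much a restricted panel shifts the estimated affected frequency.

    ``x_a`` pathogenic alleles are captured by the full panel and ``x_b`` by
    the restricted panel (x_b ≤ x_a), out of the same ``n`` total alleles.
    Both affected frequencies come from the Bayesian estimator; the summary
    odds ratio is φ_a/φ_b.  The p-value is a two-proportion Pearson χ² on
    (x_a vs x_b out of n) — a documented default; the choice of significance
    test for this contrast is a convention of this package.
    """
    if not 0 <= x_b <= x_a <= n:
        raise InvalidEntryError(
            f"need 0 <= x_b <= x_a <= n, got x_a={x_a}, x_b={x_b}, n={n}"
        )
    est_a = estimate_method3(x_a, n, prior=prior, level=level)
    est_b = estimate_method3(x_b, n, prior=prior, level=level)
    if est_b.phi == 0:
        ratio = math.inf
        logger.warning("restricted panel captures no alleles: odds ratio infinite")
    else:
        ratio = est_a.phi / est_b.phi
    table = np.array([[x_a, n - x_a], [x_b, n - x_b]], dtype=float)
    if x_a == x_b:
        p = 1.0
    elif x_a == 0:  # both zero handled above; only reachable when x_b=0 too
        p = 1.0
    else:
        p = float(stats.chi2_contingency(table, correction=False)[1])
    return PanelComparison(
        estimate_a=est_a, estimate_b=est_b, odds_ratio=ratio, p_value=p
    )
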