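"""Affected-frequency (prevalence) estimators for an autosomal recessive disease.

Three estimators of the affected frequency φ = q² (q = pathogenic allele
frequency under Hardy–Weinberg equilibrium):

1. **carrier frequency** — φ = (C/N)²/4: the couple's carrier risk (product of
   two carrier frequencies) divided by 4 for recessive inheritance.
2. **permutation–combination** — φ = (C_m/N_m)(C_f/N_f)/4: the same risk with
   the couple drawn gender-stratified.
3. **Bayesian framework** — a conjugate Beta posterior on q from x pathogenic
   alleles out of n, with φ = (posterior mean of q)² and an equal-tailed
   credible interval mapped through the monotone q ↦ q².

All φ values are probabilities; :func:`reciprocal_render` formats them in the
conventional "1 in R" form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

from scipy import stats

from .core import CohortCounts, InvalidEntryError


@dataclass(frozen=True, slots=True)
class BayesPrior:
    """Beta prior pseudo-counts on the pathogenic allele frequency.

    The default Jeffreys prior Beta(0.5, 0.5) is the invariant reference
    prior for a binomial proportion.
    """

    alpha0: float = 0.5
    beta0: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha0 <= 0 or self.beta0 <= 0:
            raise InvalidEntryError("prior pseudo-counts must be positive")


JEFFREYS = BayesPrior(0.5, 0.5)


@dataclass(frozen=True, slots=True)
class PrevalenceEstimate:
    """A method-labelled affected frequency with optional credible interval."""

    method: Literal["carrier_frequency", "permutation_combination", "bayesian"]
    phi: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    x: Optional[int] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise InvalidEntryError(f"phi {self.phi} outside [0, 1]")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.phi <= self.ci_high:
                raise InvalidEntryError(
                    f"interval [{self.ci_low}, {self.ci_high}] does not bracket phi={self.phi}"
                )

    @property
    def reciprocal(self) -> str:
        return reciprocal_render(self.phi)


def carrier_frequency(counts: CohortCounts) -> float:
    """Fraction of individuals heterozygous for at least one P/LP variant."""
    if counts.N <= 0:
        raise InvalidEntryError("cohort has no individuals")
    return counts.C / counts.N


def couple_carrier_risk(f1: float, f2: float) -> float:
    """Probability both members of a random couple are carriers: f1·f2."""
    if not (0.0 <= f1 <= 1.0 and 0.0 <= f2 <= 1.0):
        raise InvalidEntryError("carrier frequencies must lie in [0, 1]")
    return f1 * f2


def estimate_method1(counts: CohortCounts) -> PrevalenceEstimate:
    """Carrier-frequency estimator: φ = (C/N)² / 4."""
    f = carrier_frequency(counts)
    return PrevalenceEstimate(
        method="carrier_frequency",
        phi=couple_carrier_risk(f, f) / 4.0,
        x=counts.C,
        n=counts.N,
    )


def estimate_method2(counts: CohortCounts) -> PrevalenceEstimate:
    """Gender-stratified estimator: φ = (C_m/N_m)·(C_f/N_f) / 4.

    Raises if either gender stratum is empty; it never silently falls back
    to the unstratified estimator.
    """
    if counts.N_male <= 0 or counts.N_female <= 0:
        raise InvalidEntryError(
            "gender-stratified estimate undefined with an empty stratum "
            f"(N_male={counts.N_male}, N_female={counts.N_female})"
        )
    f_m = counts.C_male / counts.N_male
    f_f = counts.C_female / counts.N_female
    return PrevalenceEstimate(
        method="permutation_combination",
        phi=couple_carrier_risk(f_m, f_f) / 4.0,
        x=counts.C,
        n=counts.N,
    )


PointConvention = Literal["mean_squared", "mean_of_square", "mode_squared"]


def estimate_method3(
    x: int,
    n: int,
    prior: BayesPrior = JEFFREYS,
    level: float = 0.95,
    point: PointConvention = "mean_squared",
) -> PrevalenceEstimate:
    """Bayesian estimator with credible interval.

    With x pathogenic alleles out of n, the posterior on the allele frequency
    q is Beta(x+α0, n−x+β0).  The default point estimate is the squared
    posterior mean, φ = ((x+α0)/(n+α0+β0))²; ``point`` selects the posterior
    mean of q² or the squared posterior mode instead.  The equal-tailed
    level-``level`` interval on q maps directly onto φ because q ↦ q² is
    monotone on [0, 1].
    """
    if n <= 0 or not 0 <= x <= n:
        raise InvalidEntryError(f"invalid allele counts x={x}, n={n}")
    if not 0.0 < level < 1.0:
        raise InvalidEntryError(f"coverage level {level} outside (0, 1)")
    a = x + prior.alpha0
    b = n - x + prior.beta0
    if point == "mean_squared":
        phi = (a / (a + b)) ** 2
    elif point == "mean_of_square":
        # E[q²] = Var + (E q)² = ab/((a+b)²(a+b+1)) + (a/(a+b))²
        m = a / (a + b)
        phi = a * b / ((a + b) ** 2 * (a + b + 1.0)) + m * m
    elif point == "mode_squared":
        if a <= 1.0:
            phi = 0.0
        else:
            phi = ((a - 1.0) / (a + b - 2.0)) ** 2
    else:  # pragma: no cover - guarded by Literal
        raise InvalidEntryError(f"unknown point convention {point!r}")
    tail = (1.0 - level) / 2.0
    q_low, q_high = stats.beta.ppf([tail, 1.0 - tail], a, b)
    return PrevalenceEstimate(
        method="bayesian",
        phi=phi,
        ci_low=float(q_low) ** 2,
        ci_high=float(q_high) ** 2,
        x=x,
        n=n,
    )


def average_prevalence(estimates: Iterable[float]) -> float:
    """Arithmetic mean of affected frequencies (never of the reciprocals)."""
    values = list(estimates)
    if not values:
        raise InvalidEntryError("cannot average an empty list of frequencies")
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise InvalidEntryError(f"frequency {v} outside [0, 1]")
    return sum(values) / len(values)


def reciprocal_render(phi: float) -> str:
    """Format a frequency in the "1/R" convention, e.g. 6.92e-6 → "1/144,469".

    R is 1/φ rounded half away from zero to the nearest integer; φ = 0
    renders as "0".
    """
    if phi < 0:
        raise InvalidEntryError(f"negative frequency {phi}")
    if phi == 0:
        return "0"
    r = math.floor(1.0 / phi + 0.5)
    return f"1/{r:,}"
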