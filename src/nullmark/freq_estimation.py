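"""Allele-frequency estimation for dominant null markers under Hardy-Weinberg.

With a dominant presence/absence assay only the homozygous-null class is
directly observable: carriers of one functional copy look identical to
functional homozygotes.  Under random mating the genotype classes follow
p^2 + 2pq + q^2 = 1, so the null-allele frequency is estimated as

    q = sqrt(f_null),    p = 1 - q,

where ``f_null`` is the observed null-genotype proportion.  This square-root
estimator is the standard for deletion polymorphisms typed by conventional
PCR.  Note that HWE itself is *untestable* from such data: the three genotype
classes collapse to two observable phenotype classes, leaving zero degrees of
freedom after estimating q.  This module therefore performs no HWE test; the
equilibrium is an assumption, not a finding.

Uncertainty for q is available two ways:

* a delta-method standard error,
  se(q) = sqrt(f(1-f)/n) / (2 sqrt(f)), with a Wald interval truncated to
  [0, 1]; undefined at f in {0, 1};
* a seeded percentile bootstrap over the n phenotype calls, which also covers
  the boundary cases (at f = 0 or 1 a Clopper-Pearson bound on f is
  square-root transformed instead of the delta method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .cohort_io import Cohort

__all__ = [
    "LocusFrequency",
    "CombinationTable",
    "phenotype_frequencies",
    "locus_frequency_from_counts",
    "estimate_null_allele",
    "combination_frequencies",
    "allele_uncertainty",
    "round_half_up",
    "format_percent",
    "format_allele_pair",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(fraction: float, ndigits: int = 2) -> str:
    """Render a proportion as a percentage string, half-up at ``ndigits``."""
    q = Decimal(1).scaleb(-ndigits)
    return str((Decimal(repr(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP))

def format_allele_pair(q: float, ndigits: int = 4) -> tuple[str, str]:
    """Render (q, p) the way null-marker tables conventionally print them.

    q is truncated at ``ndigits`` decimals and p printed as the complement of
    the *printed* q, so the displayed pair sums exactly to 1.  (Half-up
    rounding of q and p independently can produce pairs like 0.6219/0.3781
    that disagree with the truncated convention by one unit in the last
    place.)
    """
    unit = Decimal(1).scaleb(-ndigits)
    q_dec = Decimal(repr(q)).quantize(unit, rounding=ROUND_DOWN)
    p_dec = Decimal(1) - q_dec
    return f"{q_dec:.{ndigits}f}", f"{p_dec:.{ndigits}f}"


@dataclass
class LocusFrequency:
    """Observed and HWE-derived frequencies for one locus in one population."""

    locus: str
    n: int
    n_null: int
    f_null: float
    q: float
    p: float
    se_q: float | None = None
    ci_q: tuple[float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.n_null <= self.n:
            raise ValueError(f"{self.locus}: n_null={self.n_null} outside [0, n={self.n}]")


def estimate_null_allele(f_null: float) -> tuple[float, float]:
    """HWE point estimate (q, p) from a null-genotype frequency.

    q = sqrt(f_null), p = 1 - q.  Full precision; rounding happens only at the
    presentation layer (:func:`format_allele_pair`).
    """
    if not (0.0 <= f_null <= 1.0) or math.isnan(f_null):
        raise ValueError(f"null genotype frequency outside [0,1]: {f_null}")
    q = math.sqrt(f_null)
    return q, 1.0 - q


def locus_frequency_from_counts(
    locus: str, n: int, n_null: int, *, label: str = ""
) -> LocusFrequency:
    """Build a :class:`LocusFrequency` from raw counts."""
    if n < 1:
        raise ValueError(f"{locus}: n must be >= 1")
    f_null = n_null / n
    q, p = estimate_null_allele(f_null)
    return LocusFrequency(locus=locus, n=n, n_null=n_null, f_null=f_null, q=q, p=p, label=label)


def phenotype_frequencies(cohort: Cohort, locus: str, *, label: str = "") -> LocusFrequency:
    """Tabulate null/present phenotypes at one locus and derive (q, p)."""
    cohort.require_locus(locus)
    if cohort.n == 0:
        raise ValueError(f"{locus}: cohort is empty")
    return locus_frequency_from_counts(locus, cohort.n, cohort.null_count(locus), label=label)


@dataclass
class CombinationTable:
    """Joint phenotype counts for two loci: (+,+), (+,null), (null,+), (null,null)."""

    locus_a: str
    locus_b: str
    counts: dict[tuple[str, str], int]
    n: int

    KEYS = (
        ("present", "present"),
        ("present", "null"),
        ("null", "present"),
        ("null", "null"),
    )

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n:
            raise ValueError("combination counts do not sum to cohort size")

    @property
    def frequencies(self) -> dict[tuple[str, str], float]:
        return {k: v / self.n for k, v in self.counts.items()}


def combination_frequencies(cohort: Cohort, locus_a: str, locus_b: str) -> CombinationTable:
    """Direct joint tabulation of two-locus phenotype combinations."""
    cohort.require_locus(locus_a)
    cohort.require_locus(locus_b)
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    a_null = cohort.calls[locus_a].to_numpy()
    b_null = cohort.calls[locus_b].to_numpy()
    counts = {
        ("present", "present"): int(np.sum(~a_null & ~b_null)),
        ("present", "null"): int(np.sum(~a_null & b_null)),
        ("null", "present"): int(np.sum(a_null & ~b_null)),
        ("null", "null"): int(np.sum(a_null & b_null)),
    }
    return CombinationTable(locus_a=locus_a, locus_b=locus_b, counts=counts, n=cohort.n)


def allele_uncertainty(
    n: int,
    f_null: float,
    *,
    level: float = 0.95,
    method: str = "delta",
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Standard error and confidence interval for q = sqrt(f_null).

    ``method='delta'``: first-order Taylor (delta-method) SE with a Wald
    interval, truncated to [0, 1]; requires 0 < f_null < 1.  At the boundary
    a one-sided Clopper-Pearson interval on f_null is square-root transformed
    (SE reported as nan there, since q has no two-sided normal scale).

    ``method='bootstrap'``: percentile bootstrap over the n binary calls,
    seeded and therefore bit-reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= f_null <= 1.0):
        raise ValueError(f"f_null outside [0,1]: {f_null}")
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must be in (0,1)")
    alpha = 1.0 - level

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        boot_f = rng.binomial(n, f_null, size=n_boot) / n
        boot_q = np.sqrt(boot_f)
        lo, hi = np.quantile(boot_q, [alpha / 2, 1 - alpha / 2])
        return float(boot_q.std(ddof=1)), (float(lo), float(hi))
    if method != "delta":
        raise ValueError(f"unknown method {method!r}")

    if f_null in (0.0, 1.0):
        # Delta method degenerates; bound f by Clopper-Pearson, then transform.
        k = round(n * f_null)
        lo_f, hi_f = _clopper_pearson(k, n, level)
        return math.nan, (math.sqrt(lo_f), math.sqrt(hi_f))

    se_q = math.sqrt(f_null * (1.0 - f_null) / n) / (2.0 * math.sqrt(f_null))
    z = stats.norm.ppf(1 - alpha / 2)
    q = math.sqrt(f_null)
    lo = max(0.0, q - z * se_q)
    hi = min(1.0, q + z * se_q)
    return se_q, (lo, hi)


def _clopper_pearson(k: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)
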