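"""Two-population contingency comparisons for null-genotype frequencies.

Published panels store (n, null-genotype frequency) pairs rather than raw
counts, so a 2x2 table (rows = populations, columns = null/positive) is first
reconstructed.  Reconstruction policy matters and is tracked: nearest-integer
rounding is the default and the only policy valid for Fisher's exact test;
``exact_fractional`` keeps n*f unrounded, which is admissible for the Pearson
statistic but meaningless for an exact hypergeometric test.

Test statistics:

* Pearson chi-square on the 2x2 table (df = 1), optionally with Yates'
  continuity correction (|O - E| reduced by 0.5, floored at 0).  The default
  is the *uncorrected* statistic.
* Fisher's exact test, two-sided by the point-probability criterion (sum of
  hypergeometric probabilities of all same-margin tables no more probable
  than the observed one), delegated to :func:`scipy.stats.fisher_exact`.

Method auto-selection for panel sweeps follows the classical rule of thumb:
Fisher when the smallest expected cell count is below 5, Pearson otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_io import ReferencePanel
from .freq_estimation import LocusFrequency

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "reconstruct_counts",
    "table_from_frequencies",
    "pearson_chi2",
    "fisher_exact",
    "compare_panel",
    "adjust_p_values",
]

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable2x2:
    """Null/positive counts for two populations at one locus.

    Layout: rows are populations (a, b), columns are (null, positive); so the
    cells are ``(a_null, a_pos, b_null, b_pos)``.  ``provenance`` records
    whether counts were observed directly or reconstructed from a published
    frequency.
    """

    label_a: str
    label_b: str
    a_null: float
    a_pos: float
    b_null: float
    b_pos: float
    provenance: str = "observed"

    def __post_init__(self) -> None:
        for v in self.cells:
            if v < 0:
                raise ValueError("contingency counts must be non-negative")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.a_null, self.a_pos, self.b_null, self.b_pos)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a_null, self.a_pos], [self.b_null, self.b_pos]], dtype=float)

    @property
    def is_integer(self) -> bool:
        return all(float(v).is_integer() for v in self.cells)

    @property
    def min_expected(self) -> float:
        obs = self.as_array()
        total = obs.sum()
        if total == 0:
            return math.nan
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
        return float(expected.min())


@dataclass
class TestResult:
    """Outcome of one two-population comparison."""

    label_a: str
    label_b: str
    method: str  # 'pearson' | 'pearson_yates' | 'fisher'
    p_value: float
    statistic: float | None = None
    df: int | None = None
    min_expected: float | None = None
    provenance: str = "observed"
    p_adjusted: float | None = None


def reconstruct_counts(
    n: int, f_null: float, policy: str = "round_nearest"
) -> tuple[float, float]:
    """Recover (n_null, n_positive) from a published size and frequency.

    ``round_nearest`` gives integers (half away from zero); ``floor`` truncates;
    ``exact_fractional`` keeps n*f unrounded and is rejected downstream by
    Fisher's exact test.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= f_null <= 1.0):
        raise ValueError(f"f_null outside [0,1]: {f_null}")
    raw = n * f_null
    if policy == "round_nearest":
        n_null: float = float(math.floor(raw + 0.5))
    elif policy == "floor":
        n_null = float(math.floor(raw))
    elif policy == "exact_fractional":
        n_null = raw
    else:
        raise ValueError(f"unknown reconstruction policy {policy!r}")
    return n_null, n - n_null


def table_from_frequencies(
    label_a: str,
    n_a: int,
    f_a: float,
    label_b: str,
    n_b: int,
    f_b: float,
    *,
    policy: str = "round_nearest",
) -> ContingencyTable2x2:
    """Build a reconstructed 2x2 table from two (n, f_null) pairs."""
    a_null, a_pos = reconstruct_counts(n_a, f_a, policy)
    b_null, b_pos = reconstruct_counts(n_b, f_b, policy)
    return ContingencyTable2x2(
        label_a=label_a,
        label_b=label_b,
        a_null=a_null,
        a_pos=a_pos,
        b_null=b_null,
        b_pos=b_pos,
        provenance="reconstructed" if policy != "exact_fractional" else "reconstructed_fractional",
    )


def pearson_chi2(table: ContingencyTable2x2, *, yates: bool = False) -> TestResult:
    """Pearson chi-square test of homogeneity on a 2x2 table (df = 1).

    statistic = sum (O-E)^2 / E with E from the product of the margins; with
    ``yates`` each |O-E| is shrunk by 0.5 (never below 0).  Requires all four
    margins positive, otherwise the statistic is undefined and Fisher's exact
    test is the appropriate tool.
    """
    obs = table.as_array()
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    if np.any(row_sums <= 0) or np.any(col_sums <= 0):
        raise ValueError(
            "zero marginal total: Pearson chi-square undefined, use fisher_exact"
        )
    total = obs.sum()
    expected = np.outer(row_sums, col_sums) / total
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return TestResult(
        label_a=table.label_a,
        label_b=table.label_b,
        method="pearson_yates" if yates else "pearson",
        statistic=statistic,
        df=1,
        p_value=p,
        min_expected=float(expected.min()),
        provenance=table.provenance,
    )


def fisher_exact(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test (point-probability criterion)."""
    if not table.is_integer:
        raise ValueError(
            "Fisher's exact test requires integer counts; "
            "fractional reconstruction is only valid for Pearson chi-square"
        )
    res = stats.fisher_exact(table.as_array().astype(int), alternative="two-sided")
    return TestResult(
        label_a=table.label_a,
        label_b=table.label_b,
        method="fisher",
        statistic=None,
        df=None,
        p_value=float(res.pvalue),
        min_expected=table.min_expected,
        provenance=table.provenance,
    )


def compare_panel(
    current: LocusFrequency,
    panel: ReferencePanel,
    locus: str,
    *,
    method_policy: str = "auto",
    count_policy: str = "round_nearest",
    yates: bool = False,
    adjust: str | None = None,
) -> list[TestResult]:
    """Compare one cohort's locus against every comparable panel row.

    Rows lacking a published sample size or lacking the locus are skipped with
    a logged notice — a frequency without an n cannot be turned into counts.
    ``method_policy``: 'auto' (Fisher when the smallest expected count < 5),
    'pearson', or 'fisher'.  ``adjust`` optionally adds multiplicity-adjusted
    p-values ('bonferroni' or 'bh'); none are applied by default.
    """
    if method_policy not in {"auto", "pearson", "fisher"}:
        raise ValueError(f"unknown method policy {method_policy!r}")
    current_label = current.label or "current study"
    results: list[TestResult] = []
    for rec in panel:
        if not rec.has(locus):
            logger.info("skipping %s at %s: no published frequency", rec.population, locus)
            continue
        if rec.n is None:
            logger.info("skipping %s at %s: sample size not published", rec.population, locus)
            continue
        table = table_from_frequencies(
            current_label,
            current.n,
            current.f_null,
            rec.population,
            rec.n,
            rec.null_freq[locus],
            policy=count_policy,
        )
        # The focal cohort has true observed counts; only row b is reconstructed.
        table.a_null, table.a_pos = float(current.n_null), float(current.n - current.n_null)
        method = method_policy
        if method == "auto":
            method = "fisher" if table.min_expected < 5 else "pearson"
        if method == "fisher":
            results.append(fisher_exact(table))
        else:
            results.append(pearson_chi2(table, yates=yates))
    if adjust is not None:
        adjust_p_values(results, method=adjust)
    return results


def adjust_p_values(results: list[TestResult], method: str = "bonferroni") -> None:
    """Attach multiplicity-adjusted p-values in place (Bonferroni or BH)."""
    if not results:
        return
    from statsmodels.stats.multitest import multipletests

    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment {method!r}")
    adjusted = multipletests([r.p_value for r in results], method=key)[1]
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
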