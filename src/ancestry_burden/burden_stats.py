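"""Burden statistics across ancestry groups.

The central comparisons are:

* a Pearson chi-square test of independence on the gene x ancestry
  contingency table, after merging the less-represented ancestry groups
  (eas, mid, sas, oth) into one column and iteratively merging the
  smallest-total gene rows into one row until every expected cell count
  is >= 5;
* a pooled two-proportion z-test,

      Z = (p1_hat - p2_hat) / sqrt(p_hat (1 - p_hat) (1/n1 + 1/n2)),
      p_hat = (Y1 + Y2) / (n1 + n2),

  with a two-tailed normal p-value, used both for gene-level outlier scans
  against the European-ancestry reference rate (Bonferroni-controlled) and
  for external allele-frequency comparisons;
* per-group positive rates with Wilson score confidence intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger("ancestry_burden")

#: Ancestry groups merged into one column before the chi-square test.
DEFAULT_COLLAPSE_GROUPS = frozenset({"eas", "mid", "sas", "oth"})
AGGREGATED_LABEL = "aggregated"
DEFAULT_MIN_EXPECTED = 5.0
DEFAULT_REFERENCE_GROUP = "eur"


class StatsError(ValueError):
    """Raised for invalid inputs to the burden statistics."""


# ---------------------------------------------------------------------------
# Burden table
# ---------------------------------------------------------------------------


@dataclass
class BurdenTable:
    """Gene x ancestry counts of participants with qualifying findings.

    ``counts`` is a genes x groups integer DataFrame; ``denominators`` holds
    the per-group participant totals. ``overall_positive`` counts distinct
    participants with >= 1 finding in any gene (participant mode) and
    ``category_counts`` resolves the counts by finding category.
    """

    counts: pd.DataFrame
    denominators: pd.Series
    overall_positive: pd.Series | None = None
    category_counts: dict[str, pd.DataFrame] | None = None
    mode: str = "participant"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise StatsError("negative counts in burden table")
        for group in self.counts.columns:
            if group not in self.denominators.index:
                raise StatsError(f"no denominator for group {group!r}")
            if self.mode == "participant" and (
                self.counts[group] > self.denominators[group]
            ).any():
                raise StatsError(
                    f"counts exceed denominator for group {group!r}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def groups(self) -> list[str]:
        return list(self.counts.columns)

    def positive_rates(self) -> pd.Series:
        """Overall per-group positive rate (distinct carriers / group size)."""
        if self.overall_positive is None:
            raise StatsError("table carries no overall positive counts")
        return self.overall_positive / self.denominators.reindex(
            self.overall_positive.index
        )


# ---------------------------------------------------------------------------
# Chi-square with aggregation
# ---------------------------------------------------------------------------


def _expected(table: pd.DataFrame) -> np.ndarray:
    arr = table.to_numpy(dtype=float)
    total = arr.sum()
    if total <= 0:
        raise StatsError("empty contingency table")
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total


def aggregate_for_chisq(
    table: "BurdenTable | pd.DataFrame",
    min_expected: float = DEFAULT_MIN_EXPECTED,
    collapse_groups: frozenset[str] = DEFAULT_COLLAPSE_GROUPS,
) -> pd.DataFrame:
    """Collapse sparse groups and genes until all expected counts are >= 5.

    The listed ancestry groups are merged into a single ``aggregated`` column
    first; then gene rows are merged (smallest row total first, ties broken by
    gene name) into a single ``aggregated`` row until every expected cell
    count under independence reaches ``min_expected``. The grand total and all
    retained-group totals are conserved.
    """
    counts = table.counts if isinstance(table, BurdenTable) else table
    df = counts.copy().astype(float)

    merge_cols = [c for c in df.columns if c in collapse_groups]
    if merge_cols:
        agg = df[merge_cols].sum(axis=1)
        df = df.drop(columns=merge_cols)
        df[AGGREGATED_LABEL] = agg

    def satisfied(d: pd.DataFrame) -> bool:
        return bool((_expected(d) >= min_expected).all())

    while not satisfied(df):
        candidates = [g for g in df.index if g != AGGREGATED_LABEL]
        # merging the last candidate into an existing aggregated row would
        # leave a single row, which cannot form a contingency table
        if not candidates or (AGGREGATED_LABEL in df.index and len(df.index) <= 2):
            raise StatsError(
                "contingency table cannot satisfy the minimum expected count "
                f"of {min_expected} even when fully aggregated"
            )
        row_totals = df.loc[candidates].sum(axis=1)
        smallest = sorted(candidates, key=lambda g: (row_totals[g], g))[0]
        if AGGREGATED_LABEL not in df.index:
            df.loc[AGGREGATED_LABEL] = 0.0
        df.loc[AGGREGATED_LABEL] += df.loc[smallest]
        df = df.drop(index=smallest)
    return df.astype(int) if np.allclose(df, df.round()) else df


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    p_value: float
    expected: pd.DataFrame


def chisq_independence(table: pd.DataFrame) -> ChisqResult:
    """Pearson chi-square test of independence, no continuity correction.

    Requires a table with >= 2 rows and columns, no zero row/column, and all
    expected counts >= 5 (run :func:`aggregate_for_chisq` first otherwise).
    """
    arr = table.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise StatsError("chi-square needs at least a 2x2 table")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise StatsError("chi-square table has a zero row or column")
    expected = _expected(table)
    if (expected < DEFAULT_MIN_EXPECTED).any():
        raise StatsError(
            "expected cell count below 5; aggregate the table first "
            "(aggregate_for_chisq)"
        )
    res = stats.chi2_contingency(arr, correction=False)
    return ChisqResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        expected=pd.DataFrame(expected, index=table.index, columns=table.columns),
    )


def positive_negative_table(table: BurdenTable) -> pd.DataFrame:
    """2 x groups table of participants with/without any qualifying finding.

    Alternative contingency construction to the gene x group counts.
    """
    if table.overall_positive is None:
        raise StatsError("table carries no overall positive counts")
    pos = table.overall_positive.reindex(table.groups)
    neg = table.denominators.reindex(table.groups) - pos
    return pd.DataFrame({g: [pos[g], neg[g]] for g in table.groups},
                        index=["positive", "negative"])


# ---------------------------------------------------------------------------
# Pooled two-proportion z-test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoProportionResult:
    """Pooled two-proportion z-test result (Y1/n1 vs Y2/n2)."""

    y1: int
    n1: int
    y2: int
    n2: int
    p_hat1: float
    p_hat2: float
    p_hat: float
    z: float
    p_value: float
    degenerate: bool = False
    m: int = 1
    alpha_adjusted: float | None = None


def two_proportion_z(y1: int, n1: int, y2: int, n2: int) -> TwoProportionResult:
    """Two-tailed pooled two-proportion z-test.

    The test statistic uses the pooled proportion
    ``p_hat = (y1 + y2) / (n1 + n2)`` in its standard error and the p-value is
    ``2 * (1 - Phi(|z|))``. When the pooled proportion is 0 or 1 the variance
    vanishes: the result is flagged degenerate with z = 0 and p = 1 rather
    than raising a division error.
    """
    if n1 <= 0 or n2 <= 0:
        raise StatsError("group sizes must be positive")
    if not (0 <= y1 <= n1) or not (0 <= y2 <= n2):
        raise StatsError("counts must lie within [0, n]")
    p1 = y1 / n1
    p2 = y2 / n2
    pooled = (y1 + y2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TwoProportionResult(y1, n1, y2, n2, p1, p2, pooled,
                                   z=0.0, p_value=1.0, degenerate=True)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    return TwoProportionResult(y1, n1, y2, n2, p1, p2, pooled,
                               z=float(z), p_value=p_value)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance threshold alpha / m."""
    if m < 1:
        raise StatsError("family size m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Gene-level outlier scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneComparison:
    gene: str
    group: str
    result: TwoProportionResult
    significant: bool


@dataclass
class OutlierScan:
    comparisons: list[GeneComparison]
    skipped: list[tuple[str, str, str]]  # (gene, group, reason)
    alpha: float
    m: int
    alpha_adjusted: float
    reference_group: str

    @property
    def flagged(self) -> list[GeneComparison]:
        return [c for c in self.comparisons if c.significant]


def gene_outlier_scan(
    table: BurdenTable,
    reference_group: str = DEFAULT_REFERENCE_GROUP,
    alpha: float = 0.05,
    m: int | None = None,
) -> OutlierScan:
    """Scan every gene x non-reference group against the reference rate.

    Each comparison is a pooled two-proportion z-test of the group's per-gene
    carrier count against the reference group's. The Bonferroni family size
    defaults to the number of comparisons actually performed; a (gene, group)
    pair with zero counts on both sides is skipped with a note. Raw p-values
    are reported unadjusted, alongside the adjusted significance flag
    (p < alpha / m).
    """
    if reference_group not in table.groups:
        raise StatsError(f"reference group {reference_group!r} not in table")
    n_ref = int(table.denominators[reference_group])
    tests: list[tuple[str, str, TwoProportionResult]] = []
    skipped: list[tuple[str, str, str]] = []
    for gene in table.genes:
        y_ref = int(table.counts.loc[gene, reference_group])
        for group in table.groups:
            if group == reference_group:
                continue
            y = int(table.counts.loc[gene, group])
            if y == 0 and y_ref == 0:
                skipped.append((gene, group, "zero counts in both groups"))
                continue
            n = int(table.denominators[group])
            tests.append((gene, group,
                          two_proportion_z(y, n, y_ref, n_ref)))
    family = m if m is not None else max(len(tests), 1)
    threshold = bonferroni_alpha(alpha, family)
    comparisons = [
        GeneComparison(gene, group,
                       result=_with_family(res, family, threshold),
                       significant=res.p_value < threshold)
        for gene, group, res in tests
    ]
    return OutlierScan(comparisons=comparisons, skipped=skipped, alpha=alpha,
                       m=family, alpha_adjusted=threshold,
                       reference_group=reference_group)


def _with_family(res: TwoProportionResult, m: int,
                 alpha_adjusted: float) -> TwoProportionResult:
    return TwoProportionResult(
        res.y1, res.n1, res.y2, res.n2, res.p_hat1, res.p_hat2, res.p_hat,
        res.z, res.p_value, res.degenerate, m=m, alpha_adjusted=alpha_adjusted,
    )


# ---------------------------------------------------------------------------
# Rates with confidence intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateCI:
    count: int
    n: int
    rate: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "wilson"


def rate_with_ci(count: int, n: int, level: float = 0.95,
                 method: str = "wilson") -> RateCI:
    """Positive rate with a Wilson score (default) or normal-approx CI."""
    if n <= 0:
        raise StatsError("n must be positive")
    if not 0 <= count <= n:
        raise StatsError("count must lie within [0, n]")
    if method not in ("wilson", "normal"):
        raise StatsError(f"unknown CI method {method!r}")
    low, high = proportion_confint(count, n, alpha=1.0 - level, method=method)
    low = 0.0 if count == 0 else min(max(float(low), 0.0), 1.0)
    high = 1.0 if count == n else min(max(float(high), 0.0), 1.0)
    return RateCI(count=count, n=n, rate=count / n, ci_low=low, ci_high=high,
                  level=level, method=method)


def group_rate_table(table: BurdenTable, level: float = 0.95) -> pd.DataFrame:
    """Per-ancestry overall positive rate with CIs (error-bar style report)."""
    if table.overall_positive is None:
        raise StatsError("table carries no overall positive counts")
    rows = []
    for group in table.groups:
        ci = rate_with_ci(int(table.overall_positive[group]),
                          int(table.denominators[group]), level=level)
        rows.append({"group": group, "count": ci.count, "n": ci.n,
                     "rate": ci.rate, "ci_low": ci.ci_low,
                     "ci_high": ci.ci_high, "method": ci.method})
    return pd.DataFrame(rows)
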