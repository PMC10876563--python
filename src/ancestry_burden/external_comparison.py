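"""Cohort vs reference-database per-gene P/LP rate comparisons.

Gene-level rates on the reference side follow the published recipe: sum the
alternate allele counts of the gene's P/LP variants as the numerator and take
the maximum total allele number observed in the gene as the denominator.
Cohort rates for these comparisons are allele-frequency style (alt alleles
over 2N chromosomes), so the two sides are commensurable; a participant-rate
mode is available but labeled distinctly.

Reference databases ship in several subsets (e.g. full, non-cancer,
non-TopMed); disease-ascertained samples inflate the full subset for disease
genes, so the subset report flags which subset best matches the cohort rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .knowledgebase import VariantKey
from .variant_selection import Panel, ParticipantCall, Zygosity

logger = logging.getLogger("ancestry_burden")


class ComparisonError(ValueError):
    """Raised for invalid comparison inputs."""


@dataclass(frozen=True)
class GeneRateRecord:
    """Per-gene P/LP allele rate in one population/subset of a reference DB."""

    gene: str
    population: str
    subset: str
    numerator: int
    denominator: int
    rate: float
    empty_gene: bool = False
    undefined: bool = False


def gene_level_rate(
    joined_records: pd.DataFrame,
    gene: str,
    population: str,
    subset: str = "full",
) -> GeneRateRecord:
    """Gene-level P/LP rate: sum of AC over max of AN.

    ``joined_records`` is the output of
    :func:`~.knowledgebase.join_frequencies`. A gene with no P/LP variants
    gets rate 0 with an empty-gene flag; a gene whose rows all have AN = 0
    gets an undefined-rate flag.
    """
    sub = joined_records[
        (joined_records["gene"] == gene)
        & (joined_records["population"] == population)
        & (joined_records["subset"] == subset)
    ]
    if len(sub) == 0:
        return GeneRateRecord(gene, population, subset, 0, 0, 0.0,
                              empty_gene=True)
    numerator = int(sub["ac"].sum())
    denominator = int(sub["an"].max())
    if denominator == 0:
        return GeneRateRecord(gene, population, subset, numerator, 0, 0.0,
                              undefined=True)
    return GeneRateRecord(gene, population, subset, numerator, denominator,
                          numerator / denominator)


def gene_rates(joined_records: pd.DataFrame) -> list[GeneRateRecord]:
    """Gene-level rates for every (gene, population, subset) present."""
    combos = joined_records[["gene", "population", "subset"]].drop_duplicates()
    return [
        gene_level_rate(joined_records, row.gene, row.population, row.subset)
        for row in combos.itertuples(index=False)
    ]


def relative_rate_difference(
    cohort_rate: float, reference_rate: float
) -> float | None:
    """Signed relative difference (cohort - reference) / reference.

    Returns 0 when both are 0 and None ("defined missing") when the
    reference rate is 0 but the cohort rate is not.
    """
    if reference_rate < 0:
        raise ComparisonError("reference rate must be non-negative")
    if reference_rate == 0:
        return 0.0 if cohort_rate == 0 else None
    return (cohort_rate - reference_rate) / reference_rate


def absolute_rate_difference(cohort_rate: float, reference_rate: float) -> float:
    """Plain difference cohort - reference (alternative comparison mode)."""
    return cohort_rate - reference_rate


@dataclass(frozen=True)
class CorrelationResult:
    r: float | None
    n: int
    genes: tuple[str, ...]
    undefined: bool = False


def rate_correlation(
    gene_rates_a: Mapping[str, float],
    gene_rates_b: Mapping[str, float],
) -> CorrelationResult:
    """Pearson correlation of per-gene rates over genes present in both.

    Requires at least 3 shared genes with finite rates; zero variance on
    either side yields an undefined result with a flag.
    """
    shared = sorted(
        g
        for g in set(gene_rates_a) & set(gene_rates_b)
        if math.isfinite(gene_rates_a[g]) and math.isfinite(gene_rates_b[g])
    )
    if len(shared) < 3:
        raise ComparisonError(
            f"need >= 3 shared genes with finite rates, have {len(shared)}"
        )
    a = np.array([gene_rates_a[g] for g in shared], dtype=float)
    b = np.array([gene_rates_b[g] for g in shared], dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult(r=None, n=len(shared), genes=tuple(shared),
                                 undefined=True)
    r = float(stats.pearsonr(a, b).statistic)
    return CorrelationResult(r=r, n=len(shared), genes=tuple(shared))


@dataclass
class SubsetReport:
    """Side-by-side per-subset rates for one gene/population vs the cohort."""

    gene: str
    population: str
    cohort_rate: float
    records: list[GeneRateRecord]
    closest_subset: str | None
    tie: bool = False


def subset_resolution_report(
    gene: str,
    population: str,
    cohort_rate: float,
    subset_records: Sequence[GeneRateRecord],
) -> SubsetReport:
    """Flag which reference subset best matches the cohort rate.

    The flagged subset minimizes |relative difference| to the cohort rate
    (absolute difference where the relative one is undefined); ties are broken
    by subset name and noted. With a single subset no flag is set.
    """
    records = [r for r in subset_records
               if r.gene == gene and r.population == population]
    if not records:
        raise ComparisonError(f"no subset records for {gene}/{population}")
    if len(records) < 2:
        return SubsetReport(gene, population, cohort_rate, records,
                            closest_subset=None)

    def distance(rec: GeneRateRecord) -> float:
        rel = relative_rate_difference(cohort_rate, rec.rate)
        if rel is None:
            return abs(absolute_rate_difference(cohort_rate, rec.rate))
        return abs(rel)

    ranked = sorted(records, key=lambda r: (distance(r), r.subset))
    best = ranked[0]
    tie = len(ranked) > 1 and math.isclose(
        distance(ranked[0]), distance(ranked[1]), rel_tol=0.0, abs_tol=1e-12
    )
    return SubsetReport(gene, population, cohort_rate, records,
                        closest_subset=best.subset, tie=tie)


# ---------------------------------------------------------------------------
# Cohort-side rates
# ---------------------------------------------------------------------------


def cohort_allele_rates(
    calls: Iterable[ParticipantCall],
    plp_keys: Iterable[VariantKey],
    panel: Panel,
    n_participants: int,
) -> dict[str, float]:
    """Allele-frequency-style per-gene cohort rates at known P/LP sites.

    Numerator = alt allele count (1 per het, 2 per hom) over the gene's P/LP
    variants among GQ-passing in-panel calls; denominator = 2N chromosomes.
    Commensurable with the reference-side allele rates of
    :func:`gene_level_rate`.
    """
    if n_participants <= 0:
        raise ComparisonError("n_participants must be positive")
    keys = frozenset(plp_keys)
    alleles: dict[str, int] = {g: 0 for g in panel.genes}
    for call in calls:
        if call.key not in keys:
            continue
        gene = panel.gene_at(call.key.chrom, call.key.pos)
        if gene is None:
            continue
        alleles[gene] += 2 if call.zygosity is Zygosity.HOM_ALT else 1
    denom = 2 * n_participants
    return {g: c / denom for g, c in alleles.items()}


def cohort_participant_rates(table) -> dict[str, float]:
    """Participant-level per-gene rates (carriers / participants), all groups.

    Not commensurable with reference allele rates; provided as a distinctly
    labeled alternative comparison mode.
    """
    total_n = int(table.denominators.sum())
    if total_n <= 0:
        raise ComparisonError("burden table has empty denominators")
    return {g: int(table.counts.loc[g].sum()) / total_n for g in table.genes}


def compare_gene_rates(
    cohort_rates: Mapping[str, float],
    reference_rates: Mapping[str, float],
) -> pd.DataFrame:
    """Per-gene comparison table with relative differences and shared genes."""
    rows = []
    for gene in sorted(set(cohort_rates) & set(reference_rates)):
        c, r = cohort_rates[gene], reference_rates[gene]
        rel = relative_rate_difference(c, r)
        rows.append(
            {"gene": gene, "cohort_rate": c, "reference_rate": r,
             "relative_difference": rel,
             "reference_rate_missing": rel is None and c > 0}
        )
    return pd.DataFrame(
        rows, columns=["gene", "cohort_rate", "reference_rate",
                       "relative_difference", "reference_rate_missing"]
    )
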