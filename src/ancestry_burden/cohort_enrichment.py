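"""Phenotype-defined sub-cohorts and P/LP enrichment tests.

A phenotype cohort is selected by OR-ing coded EHR conditions (e.g. SNOMED
breast-cancer codes) with literal survey answers, then intersected with the
genotyped participant set. Enrichment of qualifying P/LP findings in the
cohort is tested against the full genotyped background (which, matching the
published convention, includes the phenotype cohort; a complement-background
mode is available) with the pooled two-proportion z-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .burden_stats import StatsError, TwoProportionResult, two_proportion_z

logger = logging.getLogger("ancestry_burden")

KNOWN_CODE_SYSTEMS = frozenset({"SNOMED", "ICD9CM", "ICD10CM", "LOINC"})


class EnrichmentError(ValueError):
    """Raised for invalid phenotype-selection inputs."""


@dataclass(frozen=True)
class PhenotypeCriteria:
    """OR-combined selection criteria: coded conditions and survey answers."""

    condition_codes: frozenset[tuple[str, str]] = frozenset()  # (system, code)
    survey_matches: frozenset[tuple[str, str]] = frozenset()  # (question, answer)

    def __post_init__(self) -> None:
        if not self.condition_codes and not self.survey_matches:
            raise EnrichmentError("criteria must include at least one condition"
                                  " code or survey match")
        for system, _ in self.condition_codes:
            if system not in KNOWN_CODE_SYSTEMS:
                raise EnrichmentError(f"unknown code system {system!r}")


@dataclass
class CohortSelection:
    """Selected participant sets: all matches, and those with genotype data."""

    selected: frozenset[str]
    genotyped: frozenset[str]

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    @property
    def n_genotyped(self) -> int:
        return len(self.genotyped)


def select_cohort(
    participants: Iterable[str],
    ehr_table: pd.DataFrame,
    survey_table: pd.DataFrame,
    criteria: PhenotypeCriteria,
) -> CohortSelection:
    """Select the phenotype cohort by OR semantics over all criteria.

    ``participants`` is the set with genotype data; ``ehr_table`` has columns
    (participant_id, code_system, code) and ``survey_table``
    (participant_id, question_id, answer). Survey answers match exact-string,
    case-insensitively. The returned selection reports both the full match set
    and its intersection with the genotyped set.
    """
    matched: set[str] = set()
    if criteria.condition_codes and len(ehr_table):
        wanted = {(s, str(c)) for s, c in criteria.condition_codes}
        for row in ehr_table.itertuples(index=False):
            if (str(row.code_system), str(row.code)) in wanted:
                matched.add(str(row.participant_id))
    if criteria.survey_matches and len(survey_table):
        wanted_sv = {(str(q), a.lower()) for q, a in criteria.survey_matches}
        for row in survey_table.itertuples(index=False):
            if (str(row.question_id), str(row.answer).lower()) in wanted_sv:
                matched.add(str(row.participant_id))
    genotyped = frozenset(str(p) for p in participants)
    return CohortSelection(selected=frozenset(matched),
                           genotyped=frozenset(matched & genotyped))


@dataclass(frozen=True)
class EnrichmentResult:
    cohort_positive: int
    cohort_n: int
    background_positive: int
    background_n: int
    cohort_rate: float
    background_rate: float
    test: TwoProportionResult


def enrichment_test(
    cohort_positive: int,
    cohort_n: int,
    background_positive: int,
    background_n: int,
) -> EnrichmentResult:
    """P/LP enrichment of a phenotype cohort vs the background cohort.

    Reports both rates and the pooled two-proportion z-test (two-tailed;
    a one-sided reading is left to the caller). Shares the
    :func:`~.burden_stats.two_proportion_z` code path bit-for-bit.
    """
    if cohort_n <= 0:
        raise EnrichmentError("cohort_n must be positive")
    result = two_proportion_z(cohort_positive, cohort_n,
                              background_positive, background_n)
    return EnrichmentResult(
        cohort_positive=cohort_positive,
        cohort_n=cohort_n,
        background_positive=background_positive,
        background_n=background_n,
        cohort_rate=cohort_positive / cohort_n,
        background_rate=background_positive / background_n,
        test=result,
    )


def phenotype_enrichment(
    selection: CohortSelection,
    positive_participants: Iterable[str],
    all_genotyped: Iterable[str],
    background: str = "full",
) -> EnrichmentResult:
    """Convenience wrapper: count positives inside/outside the selection.

    ``background="full"`` (default) tests the cohort against the entire
    genotyped cohort including the cohort itself (the published convention);
    ``background="complement"`` tests against the non-cohort remainder.
    """
    if background not in ("full", "complement"):
        raise EnrichmentError(f"unknown background mode {background!r}")
    positives = {str(p) for p in positive_participants}
    genotyped = {str(p) for p in all_genotyped}
    cohort = set(selection.genotyped)
    cohort_pos = len(cohort & positives)
    if background == "full":
        bg, bg_pos = genotyped, len(genotyped & positives)
    else:
        bg = genotyped - cohort
        bg_pos = len(bg & positives)
    if not bg:
        raise EnrichmentError("background cohort is empty")
    return enrichment_test(cohort_pos, len(cohort), bg_pos, len(bg))
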