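"""Independent oracles shared across test modules.

These deliberately re-derive expected results by the most direct route
possible (nested loops, closed forms) and never call the code paths they
check.
"""

from __future__ import annotations

import math

import numpy as np

from ancestry_burden.knowledgebase import VariantKey
from ancestry_burden.variant_selection import (
    GeneRegion,
    Inheritance,
    ParticipantCall,
    Zygosity,
    pad_region,
)

LOF_TERMS = {
    "frameshift_variant", "stop_gained", "stop_lost",
    "splice_acceptor_variant", "splice_donor_variant", "start_lost",
}


def wilson_interval(count: int, n: int, level: float = 0.95):
    """Closed-form Wilson score interval (independent of statsmodels)."""
    from scipy.stats import norm

    z = norm.ppf(1 - (1 - level) / 2)
    p = count / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return centre - half, centre + half


def pearson_chisq_2x2(a: int, b: int, c: int, d: int) -> float:
    """Brute-force Pearson statistic on [[a, b], [c, d]] via expected counts."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    return float(((obs - expected) ** 2 / expected).sum())


def oracle_call_qualifies(
    call: ParticipantCall,
    region: GeneRegion,
    plp: set[VariantKey],
    hfe_target: VariantKey,
    gq_threshold: int = 20,
    af_threshold: float = 1e-3,
) -> str | None:
    """Rule-by-rule re-derivation of one call's finding category.

    Returns the category string or None, evaluating every published rule
    independently of the pipeline implementation.
    """
    if call.gq <= gq_threshold:
        return None
    known = call.key in plp
    known_ok = False
    if known:
        if region.inheritance is Inheritance.DOMINANT:
            known_ok = True
        elif region.inheritance is Inheritance.RECESSIVE:
            known_ok = call.zygosity is Zygosity.HOM_ALT
        else:
            known_ok = (call.zygosity is Zygosity.HOM_ALT
                        and call.key == hfe_target)
    ann = call.annotation
    plof_ok = (
        region.lof_mechanism
        and ann.most_severe_consequence in LOF_TERMS
        and ann.lof_confidence == "high"
        and (ann.popmax_af is None or ann.popmax_af < af_threshold)
    )
    if known_ok:
        return "known_plp"
    if plof_ok:
        return "plof_known_overlap" if known else "plof_novel"
    return None


def oracle_counts(
    calls: list[ParticipantCall],
    regions: dict[str, GeneRegion],
    plp: set[VariantKey],
    hfe_target: VariantKey,
    ancestry: dict[str, str],
    gq_threshold: int = 20,
) -> tuple[dict[tuple[str, str], int], dict[str, int]]:
    """Nested-loop oracle: gene x group distinct-participant counts and
    per-group overall positive counts."""
    found: set[tuple[str, str, str]] = set()  # (pid, gene, keystr)
    for call in calls:
        for gene, region in regions.items():
            start, end = pad_region(region)
            if call.key.chrom != region.chrom or not start <= call.key.pos <= end:
                continue
            cat = oracle_call_qualifies(call, region, plp, hfe_target,
                                        gq_threshold)
            if cat is not None:
                found.add((call.participant_id, gene, str(call.key)))
    cells: dict[tuple[str, str], int] = {}
    overall: dict[str, set] = {}
    per_gene_participants = {(pid, gene) for pid, gene, _ in found}
    for pid, gene in per_gene_participants:
        group = ancestry[pid]
        cells[(gene, group)] = cells.get((gene, group), 0) + 1
        overall.setdefault(group, set()).add(pid)
    return cells, {g: len(s) for g, s in overall.items()}
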