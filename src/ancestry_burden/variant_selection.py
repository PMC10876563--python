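"""Per-participant qualifying-variant selection over an actionable gene panel.

The selection pipeline mirrors a clinical secondary-findings screen:

1. subset calls to panel gene regions padded 2000 bp upstream and 1000 bp
   downstream of the coding envelope (strand-aware by default);
2. drop calls with genotype quality GQ <= 20 (the filter is strictly
   ``GQ > 20``);
3. match calls against the known-P/LP key set with inheritance-aware zygosity
   rules: heterozygous suffices for dominant-acting genes, homozygous is
   required for the recessive trio (MUTYH, ATP7B, KCNQ1), and for HFE only the
   configured c.845G>A key (rs1800562) in the homozygous state counts;
4. classify rare high-confidence predicted loss-of-function calls
   (six consequence terms, LOFTEE-style high confidence, popmax AF < 0.001)
   in the genes where loss of function is a recognized disease mechanism.

Each (participant, gene, variant) yields at most one finding, with
precedence known_plp > plof_known_overlap > plof_novel.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .knowledgebase import (
    ANCESTRY_GROUPS,
    KBVariant,
    VariantKey,
    canonicalize_key,
    parse_key,
)

logger = logging.getLogger("ancestry_burden")


class SelectionError(ValueError):
    """Raised for calls or regions that violate the selection contracts."""


class Inheritance(enum.Enum):
    DOMINANT = "dominant_like"
    RECESSIVE = "recessive_homozygous_only"
    HFE = "hfe_special"


class Zygosity(enum.Enum):
    HET = "het"
    HOM_ALT = "hom_alt"


class Category(enum.Enum):
    KNOWN_PLP = "known_plp"
    PLOF_NOVEL = "plof_novel"
    PLOF_KNOWN_OVERLAP = "plof_known_overlap"


#: Consequence terms treated as loss of function.
LOF_CONSEQUENCES = frozenset(
    {
        "frameshift_variant",
        "stop_gained",
        "stop_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "start_lost",
    }
)

#: Genes where only homozygous known-P/LP genotypes qualify.
RECESSIVE_HOMOZYGOUS_GENES = frozenset({"MUTYH", "ATP7B", "KCNQ1"})

#: rs1800562 / HFE c.845G>A on GRCh38 — the only qualifying HFE variant,
#: and only in the homozygous state. Overridable via the panel file.
DEFAULT_HFE_TARGET = VariantKey("chr6", 26092913, "G", "A")

DEFAULT_GQ_THRESHOLD = 20
DEFAULT_PLOF_AF_THRESHOLD = 1e-3
UPSTREAM_PAD_BP = 2000
DOWNSTREAM_PAD_BP = 1000


# ---------------------------------------------------------------------------
# Panel regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRegion:
    """One panel gene: coding intervals (1-based closed), strand and rules."""

    gene: str
    chrom: str
    coding_intervals: tuple[tuple[int, int], ...]
    strand: str  # "+" | "-"
    inheritance: Inheritance
    lof_mechanism: bool

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise SelectionError(f"{self.gene}: strand must be '+' or '-'")
        ivs = self.coding_intervals
        if not ivs:
            raise SelectionError(f"{self.gene}: no coding intervals")
        for (s, e) in ivs:
            if not (1 <= s <= e):
                raise SelectionError(f"{self.gene}: bad interval ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise SelectionError(
                    f"{self.gene}: intervals must be sorted and non-overlapping"
                )


def pad_region(
    region: GeneRegion,
    upstream_bp: int = UPSTREAM_PAD_BP,
    downstream_bp: int = DOWNSTREAM_PAD_BP,
    strand_aware: bool = True,
) -> tuple[int, int]:
    """Padded (start, end) envelope of a gene's coding intervals.

    Padding is applied to the union envelope. With ``strand_aware`` (default)
    "upstream" means the 5' side of the transcription strand, so a minus-strand
    gene is padded ``downstream_bp`` on the left and ``upstream_bp`` on the
    right. With ``strand_aware=False`` the left pad is always ``upstream_bp``
    (coordinate-symmetric mode). The left edge is clipped at position 1.
    """
    start = min(s for s, _ in region.coding_intervals)
    end = max(e for _, e in region.coding_intervals)
    if strand_aware and region.strand == "-":
        left, right = downstream_bp, upstream_bp
    else:
        left, right = upstream_bp, downstream_bp
    return (max(1, start - left), end + right)


@dataclass
class Panel:
    """The actionable gene panel: regions plus the HFE target key."""

    regions: dict[str, GeneRegion]
    hfe_target: VariantKey = DEFAULT_HFE_TARGET
    strand_aware_padding: bool = True

    def padded(self) -> dict[str, tuple[str, int, int]]:
        """gene -> (chrom, padded start, padded end)."""
        return {
            g: (r.chrom, *pad_region(r, strand_aware=self.strand_aware_padding))
            for g, r in self.regions.items()
        }

    def gene_at(self, chrom: str, pos: int) -> str | None:
        """Panel gene whose padded region contains (chrom, pos), else None."""
        for gene, (c, s, e) in self.padded().items():
            if c == chrom and s <= pos <= e:
                return gene
        return None

    @property
    def genes(self) -> list[str]:
        return sorted(self.regions)


def load_panel(path: str | Path, strand_aware: bool = True) -> Panel:
    """Load a BED-like panel TSV.

    Columns: chrom, start (0-based half-open, BED convention), end, gene,
    strand, inheritance, lof_mechanism (0/1). A ``##hfe_target=chrom:pos:ref:alt``
    comment line overrides the default rs1800562 key. Multiple rows per gene
    become that gene's coding intervals.
    """
    hfe_target = DEFAULT_HFE_TARGET
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                if line.startswith("##hfe_target="):
                    hfe_target = parse_key(line.split("=", 1)[1])
                continue
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    by_gene: dict[str, dict] = {}
    for chrom, start, end, gene, strand, inh, lof in rows:
        slot = by_gene.setdefault(
            gene,
            {"chrom": chrom, "strand": strand,
             "inheritance": Inheritance(inh), "lof": lof not in ("0", "false", "False"),
             "intervals": []},
        )
        # BED half-open -> 1-based closed
        slot["intervals"].append((int(start) + 1, int(end)))
    regions = {}
    for gene, slot in by_gene.items():
        regions[gene] = GeneRegion(
            gene=gene,
            chrom=slot["chrom"],
            coding_intervals=tuple(sorted(slot["intervals"])),
            strand=slot["strand"],
            inheritance=slot["inheritance"],
            lof_mechanism=slot["lof"],
        )
    return Panel(regions=regions, hfe_target=hfe_target,
                 strand_aware_padding=strand_aware)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel back to the BED-like TSV dialect of :func:`load_panel`."""
    with open(path, "w") as fh:
        fh.write(f"##hfe_target={panel.hfe_target}\n")
        fh.write("#chrom\tstart\tend\tgene\tstrand\tinheritance\tlof_mechanism\n")
        for gene in panel.genes:
            r = panel.regions[gene]
            for (s, e) in r.coding_intervals:
                fh.write(
                    f"{r.chrom}\t{s - 1}\t{e}\t{gene}\t{r.strand}\t"
                    f"{r.inheritance.value}\t{int(r.lof_mechanism)}\n"
                )


# ---------------------------------------------------------------------------
# Calls and annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConsequenceAnnotation:
    """VEP/LOFTEE-style annotation consumed as input fields."""

    most_severe_consequence: str | None = None
    lof_confidence: str = "missing"  # "high" | "low" | "missing"
    popmax_af: float | None = None


@dataclass(frozen=True)
class ParticipantCall:
    """One participant's non-reference genotype at one variant."""

    participant_id: str
    key: VariantKey
    zygosity: Zygosity
    gq: int
    annotation: ConsequenceAnnotation = ConsequenceAnnotation()

    def __post_init__(self) -> None:
        if self.gq < 0:
            raise SelectionError(f"negative GQ for {self.participant_id}")


@dataclass(frozen=True)
class Finding:
    """A qualifying (participant, gene, variant) with its category."""

    participant_id: str
    gene: str
    key: VariantKey
    category: Category


def passes_gq(call: ParticipantCall, threshold: int = DEFAULT_GQ_THRESHOLD) -> bool:
    """True iff GQ is strictly greater than the threshold (GQ > 20)."""
    return call.gq > threshold


def is_plof(
    annotation: ConsequenceAnnotation,
    af_threshold: float = DEFAULT_PLOF_AF_THRESHOLD,
) -> bool:
    """Rare high-confidence predicted loss of function?

    True iff the most severe consequence is one of the six LoF terms, the
    LOFTEE-style confidence is "high", and the popmax allele frequency is
    strictly below ``af_threshold``. A missing popmax AF passes the rarity
    filter: absence from the reference database implies rarity.
    """
    if annotation.most_severe_consequence not in LOF_CONSEQUENCES:
        return False
    if annotation.lof_confidence != "high":
        return False
    if annotation.popmax_af is not None and annotation.popmax_af >= af_threshold:
        return False
    return True


_CATEGORY_PRECEDENCE = {
    Category.KNOWN_PLP: 0,
    Category.PLOF_KNOWN_OVERLAP: 1,
    Category.PLOF_NOVEL: 2,
}


def qualifying_findings(
    calls: Iterable[ParticipantCall],
    plp_kb: Iterable[VariantKey] | Mapping[VariantKey, KBVariant],
    region: GeneRegion,
    hfe_target: VariantKey = DEFAULT_HFE_TARGET,
    af_threshold: float = DEFAULT_PLOF_AF_THRESHOLD,
    strand_aware_padding: bool = True,
) -> list[Finding]:
    """Qualifying findings for one participant-gene's calls.

    Callers must pre-filter on GQ and pre-subset to the padded region; a call
    outside the region raises. Zygosity rules follow ``region.inheritance``;
    pLoF classification applies only when ``region.lof_mechanism``. Each
    (participant, key) yields at most one finding, best category wins.
    """
    keys = frozenset(plp_kb)
    start, end = pad_region(region, strand_aware=strand_aware_padding)
    best: dict[tuple[str, VariantKey], Finding] = {}

    def offer(f: Finding) -> None:
        cur = best.get((f.participant_id, f.key))
        if cur is None or (
            _CATEGORY_PRECEDENCE[f.category] < _CATEGORY_PRECEDENCE[cur.category]
        ):
            best[(f.participant_id, f.key)] = f

    for call in calls:
        if call.key.chrom != region.chrom or not (start <= call.key.pos <= end):
            raise SelectionError(
                f"call {call.key} lies outside the padded region of "
                f"{region.gene} ({region.chrom}:{start}-{end}); pre-subset calls"
            )
        known = call.key in keys
        if known:
            if region.inheritance is Inheritance.DOMINANT:
                zyg_ok = True
            elif region.inheritance is Inheritance.RECESSIVE:
                zyg_ok = call.zygosity is Zygosity.HOM_ALT
            else:  # HFE special case
                zyg_ok = (
                    call.zygosity is Zygosity.HOM_ALT and call.key == hfe_target
                )
            if zyg_ok:
                offer(Finding(call.participant_id, region.gene, call.key,
                              Category.KNOWN_PLP))
        if region.lof_mechanism and is_plof(call.annotation, af_threshold):
            cat = Category.PLOF_KNOWN_OVERLAP if known else Category.PLOF_NOVEL
            offer(Finding(call.participant_id, region.gene, call.key, cat))
    return sorted(
        best.values(), key=lambda f: (f.participant_id, str(f.key))
    )


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationSpec:
    """Where consequence annotations live in the VCF INFO field.

    ``info_field`` names a CSQ-style pipe-delimited INFO key; ``subfields``
    gives the pipe-separated layout. If the VCF header's Description carries a
    ``Format: a|b|c`` clause, that layout takes precedence.
    """

    info_field: str = "CSQ"
    subfields: tuple[str, ...] = ("SYMBOL", "Consequence", "LoF", "AF_popmax")
    consequence: str = "Consequence"
    lof_flag: str = "LoF"
    popmax: str = "AF_popmax"


def _csq_layout(vcf, spec: AnnotationSpec) -> tuple[str, ...]:
    try:
        desc = vcf.get_header_type(spec.info_field).get("Description", "")
    except KeyError:
        return spec.subfields
    if "Format:" in desc:
        layout = desc.split("Format:", 1)[1].strip().strip('"').strip()
        return tuple(p.strip() for p in layout.split("|"))
    return spec.subfields


def _parse_annotation(raw: str | None, layout: tuple[str, ...],
                      spec: AnnotationSpec, alt_index: int) -> ConsequenceAnnotation:
    if not raw:
        return ConsequenceAnnotation()
    entries = str(raw).split(",")
    entry = entries[min(alt_index, len(entries) - 1)]
    fields = dict(zip(layout, entry.split("|")))
    popmax_raw = fields.get(spec.popmax, "")
    popmax = float(popmax_raw) if popmax_raw not in ("", ".", None) else None
    lof = fields.get(spec.lof_flag, "") or "missing"
    lof = {"HC": "high", "LC": "low"}.get(lof, lof)
    return ConsequenceAnnotation(
        most_severe_consequence=fields.get(spec.consequence) or None,
        lof_confidence=lof if lof in ("high", "low") else "missing",
        popmax_af=popmax,
    )


def read_cohort_calls(
    vcf_path: str | Path,
    panel: Panel,
    annotation_spec: AnnotationSpec = AnnotationSpec(),
    gq_threshold: int | None = None,
) -> list[ParticipantCall]:
    """Read per-sample non-reference calls inside the padded panel regions.

    Multi-allelic records are decomposed into one call per ALT. Calls outside
    every padded region are dropped (panel subsetting); with ``gq_threshold``
    set, calls failing ``GQ > threshold`` are dropped too.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = np.asarray(vcf.samples)
    layout = _csq_layout(vcf, annotation_spec)
    padded = panel.padded()
    calls: list[ParticipantCall] = []
    for v in vcf:
        chrom = v.CHROM if v.CHROM.startswith("chr") else "chr" + v.CHROM
        if not any(c == chrom and s <= v.POS <= e for c, s, e in padded.values()):
            continue
        gqs = v.gt_quals
        raw_csq = v.INFO.get(annotation_spec.info_field)
        if len(v.ALT) == 1:
            # fast path: gts012 -> 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            gt = v.gt_types
            carrier_idx = np.flatnonzero((gt == 1) | (gt == 2))
            alt_counts = {i: (1 if gt[i] == 1 else 2) for i in carrier_idx}
            alts = [(0, v.ALT[0], alt_counts)]
        else:
            alts = []
            genos = v.genotypes
            for ai, alt in enumerate(v.ALT, start=1):
                counts = {}
                for si, g in enumerate(genos):
                    n = sum(1 for a in g[:-1] if a == ai)
                    if n:
                        counts[si] = n
                alts.append((ai - 1, alt, counts))
        for alt_index, alt, counts in alts:
            if not counts:
                continue
            try:
                key = canonicalize_key(chrom, v.POS, v.REF, alt)
            except Exception:
                logger.warning("skipping unkeyable record %s:%d %s>%s",
                               chrom, v.POS, v.REF, alt)
                continue
            ann = _parse_annotation(raw_csq, layout, annotation_spec, alt_index)
            for si, n_alt in counts.items():
                gq = int(gqs[si]) if gqs is not None and gqs[si] >= 0 else 0
                if gq_threshold is not None and gq <= gq_threshold:
                    continue
                calls.append(
                    ParticipantCall(
                        participant_id=str(samples[si]),
                        key=key,
                        zygosity=Zygosity.HOM_ALT if n_alt >= 2 else Zygosity.HET,
                        gq=gq,
                        annotation=ann,
                    )
                )
    return calls


def classify_cohort(
    vcf_path: str | Path,
    panel: Panel,
    plp_kb: Iterable[VariantKey] | Mapping[VariantKey, KBVariant],
    gq_threshold: int = DEFAULT_GQ_THRESHOLD,
    af_threshold: float = DEFAULT_PLOF_AF_THRESHOLD,
    annotation_spec: AnnotationSpec = AnnotationSpec(),
    return_calls: bool = False,
):
    """Full selection pass: subset, GQ-filter, and classify a cohort VCF.

    Returns the list of findings, or ``(findings, calls)`` with
    ``return_calls`` (calls = the GQ-passing in-panel calls, for allele-level
    reporting).
    """
    calls = read_cohort_calls(vcf_path, panel, annotation_spec,
                              gq_threshold=gq_threshold)
    grouped: dict[tuple[str, str], list[ParticipantCall]] = defaultdict(list)
    for call in calls:
        gene = panel.gene_at(call.key.chrom, call.key.pos)
        if gene is None:
            continue
        grouped[(call.participant_id, gene)].append(call)
    findings: list[Finding] = []
    for (pid, gene), group in grouped.items():
        findings.extend(
            qualifying_findings(
                group,
                plp_kb,
                panel.regions[gene],
                hfe_target=panel.hfe_target,
                af_threshold=af_threshold,
                strand_aware_padding=panel.strand_aware_padding,
            )
        )
    findings.sort(key=lambda f: (f.participant_id, f.gene, str(f.key)))
    if return_calls:
        return findings, calls
    return findings


# ---------------------------------------------------------------------------
# Cohort counting
# ---------------------------------------------------------------------------


def count_cohort(
    findings: Iterable[Finding],
    ancestry_labels: Mapping[str, str] | pd.Series,
    panel: Panel,
    mode: str = "participant",
):
    """Aggregate findings into a gene x ancestry :class:`~.burden_stats.BurdenTable`.

    ``mode="participant"`` (default): cell (gene, group) counts distinct
    participants in the group with >= 1 finding in the gene; the overall
    positive count per group counts distinct participants with >= 1 finding in
    any panel gene. ``mode="instance"`` counts finding instances instead
    (allele-instance style reporting).

    Participants whose ancestry label is missing or unrecognized are excluded
    from denominators and listed in the table's diagnostics.
    """
    from .burden_stats import BurdenTable

    if mode not in ("participant", "instance"):
        raise ValueError(f"unknown counting mode {mode!r}")
    labels = dict(ancestry_labels.items()) if hasattr(ancestry_labels, "items") else dict(ancestry_labels)
    valid = {p: g for p, g in labels.items() if g in ANCESTRY_GROUPS}
    dropped = sorted(set(labels) - set(valid))

    genes = panel.genes
    groups = [g for g in ANCESTRY_GROUPS if g in set(valid.values())] or list(ANCESTRY_GROUPS)
    counts = pd.DataFrame(0, index=genes, columns=groups, dtype=int)
    denominators = pd.Series(0, index=groups, dtype=int)
    for g in valid.values():
        denominators[g] += 1

    cat_counts = {
        c.value: pd.DataFrame(0, index=genes, columns=groups, dtype=int)
        for c in Category
    }
    seen_gene: set[tuple[str, str]] = set()
    seen_cat: set[tuple[str, str, str]] = set()
    positive: dict[str, set] = {g: set() for g in groups}
    missing_with_findings: set[str] = set()

    for f in findings:
        group = valid.get(f.participant_id)
        if group is None:
            missing_with_findings.add(f.participant_id)
            continue
        if mode == "instance":
            counts.loc[f.gene, group] += 1
            cat_counts[f.category.value].loc[f.gene, group] += 1
        else:
            if (f.participant_id, f.gene) not in seen_gene:
                seen_gene.add((f.participant_id, f.gene))
                counts.loc[f.gene, group] += 1
            ck = (f.participant_id, f.gene, f.category.value)
            if ck not in seen_cat:
                seen_cat.add(ck)
                cat_counts[f.category.value].loc[f.gene, group] += 1
        positive[group].add(f.participant_id)

    overall = pd.Series({g: len(positive[g]) for g in groups}, dtype=int)
    diagnostics = {
        "participants_missing_ancestry": dropped,
        "findings_participants_missing_ancestry": sorted(missing_with_findings),
    }
    return BurdenTable(
        counts=counts,
        denominators=denominators,
        overall_positive=overall,
        category_counts=cat_counts,
        mode=mode,
        diagnostics=diagnostics,
    )
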