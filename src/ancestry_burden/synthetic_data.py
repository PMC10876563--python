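"""Fully synthetic cohorts, knowledge bases and phenotype tables.

Everything the analysis consumes — panel, VIP-style curated database, ClinVar
TSV, population frequency tables, a cohort VCF with per-sample GT/GQ and
CSQ-style annotations, ancestry labels, EHR condition codes and survey
answers — is generated from a single seed with planted parameters, so every
module is testable without any external download.

What the generator emulates:

* a cohort with the continental-ancestry composition of a large US biobank
  (eur 50.4%, afr 23.2%, amr 16.1%, eas 2.1%, sas 1.0%, mid 0.2%, oth 7.0%);
* per-gene, per-ancestry carrier rates for known P/LP variants and for rare
  high-confidence pLoF variants, with European rates summing to an overall
  qualifying rate of ~2.26% and other groups scaled down;
* inheritance-aware zygosity (recessive and HFE carriers are planted
  homozygous so planted carriers actually qualify);
* genotype-quality noise as an opt-in fraction of calls pushed below the
  GQ threshold;
* ClinVar records spanning all star levels, pre/post-cutoff dates, the six
  P/LP significance strings plus conflicting/GRCh37 decoys;
* frequency tables in three subsets, with the ``full`` subset inflated for
  designated disease genes so subset-resolution logic is exercised;
* a phenotype (breast-cancer-style) linked to carrier status in designated
  genes through a relative risk.

Variants are placed on real chromosome names with toy coordinates; no
reference sequence is needed. A truth table records every planted carrier
with its rule-level qualification status, so pipeline output can be checked
exactly.

Random-number contract: every consumer derives its own
``numpy.random.default_rng([seed, stream_id])`` stream with a fixed per-purpose
stream id, so adding or reordering generation steps never perturbs other
streams and the same seed yields byte-identical files.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .knowledgebase import (
    ANCESTRY_GROUPS,
    Classification,
    VariantKey,
)
from .variant_selection import (
    DEFAULT_HFE_TARGET,
    GeneRegion,
    Inheritance,
    LOF_CONSEQUENCES,
    Panel,
    write_panel,
)

logger = logging.getLogger("ancestry_burden")

# fixed stream ids (see module docstring)
_STREAM_KB = 1
_STREAM_ANCESTRY = 2
_STREAM_CARRIERS = 3
_STREAM_GQ = 4
_STREAM_PHENOTYPE = 5
_STREAM_CLINVAR = 6

#: Published cohort composition emulated by default.
DEFAULT_ANCESTRY_PROPORTIONS: dict[str, float] = {
    "eur": 0.504,
    "afr": 0.232,
    "amr": 0.161,
    "eas": 0.021,
    "sas": 0.010,
    "mid": 0.002,
    "oth": 0.070,
}

#: Per-ancestry scaling of the European carrier rates (Fig.-1-style gradient).
DEFAULT_ANCESTRY_RATE_SCALE: dict[str, float] = {
    "eur": 1.0,
    "oth": 0.85,
    "afr": 0.72,
    "amr": 0.62,
    "eas": 0.75,
    "sas": 0.75,
    "mid": 0.75,
}


@dataclass(frozen=True)
class GeneSimSpec:
    """One synthetic panel gene with planted carrier rates (European baseline)."""

    gene: str
    chrom: str
    strand: str
    inheritance: Inheritance
    lof_mechanism: bool
    coding_intervals: tuple[tuple[int, int], ...]
    plp_carrier_rate: float
    plof_carrier_rate: float = 0.0
    n_plp_variants: int = 4
    n_plof_variants: int = 3
    decoy_vus_rate: float = 0.001
    plant_zygosity: str | None = None  # force "het"/"hom_alt" for experiments

    def region(self) -> GeneRegion:
        return GeneRegion(
            gene=self.gene,
            chrom=self.chrom,
            coding_intervals=self.coding_intervals,
            strand=self.strand,
            inheritance=self.inheritance,
            lof_mechanism=self.lof_mechanism,
        )


def default_gene_specs() -> tuple[GeneSimSpec, ...]:
    """Nine-gene synthetic panel spanning all inheritance modes.

    European known-P/LP carrier rates sum to 1.96% and pLoF rates to 0.30%,
    yielding an overall qualifying rate of ~2.26% in the European group.
    """
    return (
        GeneSimSpec("BRCA2", "chr13", "+", Inheritance.DOMINANT, True,
                    ((32_315_000, 32_320_000), (32_330_000, 32_400_000)),
                    plp_carrier_rate=0.0056, plof_carrier_rate=0.0012),
        GeneSimSpec("LDLR", "chr19", "+", Inheritance.DOMINANT, True,
                    ((11_089_000, 11_095_000), (11_100_000, 11_133_000)),
                    plp_carrier_rate=0.0030, plof_carrier_rate=0.0008),
        GeneSimSpec("PALB2", "chr16", "-", Inheritance.DOMINANT, True,
                    ((23_600_000, 23_610_000), (23_620_000, 23_640_000)),
                    plp_carrier_rate=0.0014, plof_carrier_rate=0.0005),
        GeneSimSpec("PKP2", "chr12", "-", Inheritance.DOMINANT, True,
                    ((32_790_000, 32_800_000), (32_850_000, 32_896_000)),
                    plp_carrier_rate=0.0008, plof_carrier_rate=0.0005),
        GeneSimSpec("APOB", "chr2", "-", Inheritance.DOMINANT, False,
                    ((21_000_000, 21_010_000), (21_020_000, 21_044_000)),
                    plp_carrier_rate=0.0020),
        GeneSimSpec("MUTYH", "chr1", "-", Inheritance.RECESSIVE, False,
                    ((45_330_000, 45_332_000), (45_335_000, 45_341_000)),
                    plp_carrier_rate=0.0010),
        GeneSimSpec("ATP7B", "chr13", "-", Inheritance.RECESSIVE, False,
                    ((51_930_000, 51_940_000), (51_950_000, 52_012_000)),
                    plp_carrier_rate=0.0006),
        GeneSimSpec("KCNQ1", "chr11", "+", Inheritance.RECESSIVE, False,
                    ((2_440_000, 2_450_000), (2_800_000, 2_849_000)),
                    plp_carrier_rate=0.0008),
        GeneSimSpec("HFE", "chr6", "+", Inheritance.HFE, False,
                    ((26_087_000, 26_098_000),),
                    plp_carrier_rate=0.0044, n_plp_variants=1),
    )


@dataclass(frozen=True)
class ClinVarNoise:
    """Fractions of planted P/LP variants given non-passing ClinVar records."""

    conflicting_fraction: float = 0.10
    stale_fraction: float = 0.10  # 2-star but pre-cutoff date
    low_star_fraction: float = 0.10
    missing_date_fraction: float = 0.05


@dataclass(frozen=True)
class PhenotypeModel:
    """Carrier-linked phenotype (breast-cancer-style by default)."""

    name: str = "breast cancer"
    snomed_codes: tuple[str, ...] = ("254837009", "372064008")
    question_id: str = "cancer_condition_history"
    answer: str = "breast cancer"
    baseline_prevalence: float = 0.0168
    relative_risk: float = 4.0
    carrier_genes: tuple[str, ...] = ("BRCA2", "PALB2")


@dataclass
class SimulationConfig:
    """Everything the generator needs; the seed fully determines the output."""

    seed: int = 0
    n_participants: int = 10_000
    ancestry_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANCESTRY_PROPORTIONS)
    )
    ancestry_rate_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANCESTRY_RATE_SCALE)
    )
    genes: tuple[GeneSimSpec, ...] = field(default_factory=default_gene_specs)
    gene_rate_overrides: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )  # gene -> group -> absolute known-P/LP carrier rate
    gq_threshold: int = 20
    gq_fail_fraction: float = 0.0
    clinvar_noise: ClinVarNoise = field(default_factory=ClinVarNoise)
    inflated_full_subset_genes: tuple[str, ...] = ("BRCA2", "PALB2")
    full_subset_inflation: float = 3.0
    phenotype: PhenotypeModel = field(default_factory=PhenotypeModel)
    outside_panel_decoy_rate: float = 0.002

    def __post_init__(self) -> None:
        total = sum(self.ancestry_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ancestry proportions sum to {total}, not 1")
        for spec in self.genes:
            for rate in (spec.plp_carrier_rate, spec.plof_carrier_rate,
                         spec.decoy_vus_rate):
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"{spec.gene}: rate {rate} outside [0, 1]")
        if not 0.0 <= self.gq_fail_fraction <= 1.0:
            raise ValueError("gq_fail_fraction outside [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for scalar in ("seed", "n_participants", "gq_threshold",
                       "gq_fail_fraction", "full_subset_inflation",
                       "outside_panel_decoy_rate"):
            if scalar in raw:
                kwargs[scalar] = raw[scalar]
        for mapping in ("ancestry_proportions", "ancestry_rate_scale",
                        "gene_rate_overrides"):
            if mapping in raw:
                kwargs[mapping] = raw[mapping]
        if "inflated_full_subset_genes" in raw:
            kwargs["inflated_full_subset_genes"] = tuple(
                raw["inflated_full_subset_genes"]
            )
        if "genes" in raw:
            kwargs["genes"] = tuple(
                GeneSimSpec(
                    gene=g["gene"], chrom=g["chrom"], strand=g.get("strand", "+"),
                    inheritance=Inheritance(g.get("inheritance", "dominant_like")),
                    lof_mechanism=bool(g.get("lof_mechanism", False)),
                    coding_intervals=tuple(
                        tuple(iv) for iv in g["coding_intervals"]
                    ),
                    plp_carrier_rate=float(g.get("plp_carrier_rate", 0.0)),
                    plof_carrier_rate=float(g.get("plof_carrier_rate", 0.0)),
                    plant_zygosity=g.get("plant_zygosity"),
                )
                for g in raw["genes"]
            )
        if "phenotype" in raw:
            kwargs["phenotype"] = PhenotypeModel(**raw["phenotype"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Planted rate bookkeeping
# ---------------------------------------------------------------------------


def plp_rate(config: SimulationConfig, spec: GeneSimSpec, group: str) -> float:
    """Planted known-P/LP carrier rate for one gene and ancestry group."""
    override = config.gene_rate_overrides.get(spec.gene, {})
    if group in override:
        return float(override[group])
    return spec.plp_carrier_rate * config.ancestry_rate_scale[group]


def plof_rate(config: SimulationConfig, spec: GeneSimSpec, group: str) -> float:
    return spec.plof_carrier_rate * config.ancestry_rate_scale[group]


def _plants_qualify(spec: GeneSimSpec) -> bool:
    """Do the planted known-P/LP carriers satisfy the zygosity rule?"""
    if spec.plant_zygosity == "het" and spec.inheritance in (
        Inheritance.RECESSIVE, Inheritance.HFE
    ):
        return False
    return True


def expected_positive_rate(config: SimulationConfig, group: str) -> float:
    """Planted probability a participant of a group has >= 1 qualifying finding."""
    p_none = 1.0
    for spec in config.genes:
        q = 0.0
        if _plants_qualify(spec):
            q = plp_rate(config, spec, group)
        q = 1.0 - (1.0 - q) * (1.0 - (plof_rate(config, spec, group)
                                      if spec.lof_mechanism else 0.0))
        p_none *= 1.0 - q
    return 1.0 - p_none


# ---------------------------------------------------------------------------
# Synthetic knowledge base
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimVariant:
    """One synthetic variant with its role in the generated data."""

    key: VariantKey
    gene: str
    role: str  # plp | plof | plof_overlap | vus | benign | plof_decoy_* | outside_plp
    classification: Classification | None  # VIP row, if any
    consequence: str | None
    lof_confidence: str  # high | low | missing
    popmax_af: float | None
    in_padding: bool = False


_BASES = ("A", "C", "G", "T")
_PLOF_TERMS = tuple(sorted(LOF_CONSEQUENCES))


@dataclass
class SyntheticKB:
    variants: list[SimVariant]
    by_gene: dict[str, dict[str, list[SimVariant]]]  # gene -> role-group -> variants
    plp_keys: frozenset[VariantKey]


def _sample_variant(rng: np.random.Generator, chrom: str, lo: int, hi: int,
                    used: set[int]) -> VariantKey:
    while True:
        pos = int(rng.integers(lo, hi + 1))
        if pos not in used:
            used.add(pos)
            break
    ref, alt = rng.choice(4, size=2, replace=False)
    return VariantKey(chrom, pos, _BASES[int(ref)], _BASES[int(alt)])


def build_synthetic_kb(config: SimulationConfig) -> SyntheticKB:
    """Deterministically generate the variant content for every gene.

    Per gene: the planted P/LP set (one variant placed in the upstream
    padding to exercise region logic), a pLoF set (one shared with the P/LP
    set to exercise the overlap category), VUS/benign decoys, plus pLoF-shaped
    decoys that must fail the filter (low confidence; common, popmax 0.01).
    One P/LP-classified decoy is placed outside the panel entirely.
    """
    rng = np.random.default_rng([config.seed, _STREAM_KB])
    variants: list[SimVariant] = []
    by_gene: dict[str, dict[str, list[SimVariant]]] = {}
    for spec in config.genes:
        used: set[int] = set()
        lo = min(s for s, _ in spec.coding_intervals)
        hi = max(e for _, e in spec.coding_intervals)
        roles: dict[str, list[SimVariant]] = {"plp": [], "plof": [], "vus": []}

        if spec.inheritance is Inheritance.HFE:
            # the single qualifying HFE key is the configured target variant
            roles["plp"].append(
                SimVariant(DEFAULT_HFE_TARGET, spec.gene, "plp",
                           Classification.PATH, "missense_variant", "missing",
                           0.04)
            )
            used.add(DEFAULT_HFE_TARGET.pos)
        else:
            for i in range(spec.n_plp_variants):
                in_padding = i == 0 and spec.n_plp_variants > 1
                if in_padding:
                    # upstream padding on the transcription strand
                    if spec.strand == "+":
                        key = _sample_variant(rng, spec.chrom,
                                              max(1, lo - 1900), lo - 1, used)
                    else:
                        key = _sample_variant(rng, spec.chrom, hi + 1,
                                              hi + 1900, used)
                else:
                    key = _sample_variant(rng, spec.chrom, lo, hi, used)
                cls = Classification.PATH if i % 2 == 0 else Classification.LPATH
                roles["plp"].append(
                    SimVariant(key, spec.gene, "plp", cls, "missense_variant",
                               "missing", float(rng.uniform(0, 5e-4)),
                               in_padding=in_padding)
                )
        if spec.lof_mechanism and spec.plof_carrier_rate > 0:
            for i in range(spec.n_plof_variants):
                key = _sample_variant(rng, spec.chrom, lo, hi, used)
                term = _PLOF_TERMS[int(rng.integers(0, len(_PLOF_TERMS)))]
                overlap = i == 0
                roles["plof"].append(
                    SimVariant(key, spec.gene,
                               "plof_overlap" if overlap else "plof",
                               Classification.PATH if overlap else None,
                               term, "high", float(rng.uniform(0, 5e-4)))
                )
            # decoys that must fail the pLoF filter
            key = _sample_variant(rng, spec.chrom, lo, hi, used)
            roles.setdefault("plof_decoy", []).append(
                SimVariant(key, spec.gene, "plof_decoy_lowconf", None,
                           "stop_gained", "low", 1e-4)
            )
            key = _sample_variant(rng, spec.chrom, lo, hi, used)
            roles["plof_decoy"].append(
                SimVariant(key, spec.gene, "plof_decoy_common", None,
                           "frameshift_variant", "high", 0.01)
            )
        for cls, role in ((Classification.VUS, "vus"),
                          (Classification.BENIGN, "benign")):
            key = _sample_variant(rng, spec.chrom, lo, hi, used)
            roles.setdefault("vus", []).append(
                SimVariant(key, spec.gene, role, cls, "missense_variant",
                           "missing", float(rng.uniform(0, 1e-2)))
            )
        by_gene[spec.gene] = roles
        for group in roles.values():
            variants.extend(group)

    # P/LP-classified decoy outside every panel region: exercises subsetting
    first = config.genes[0]
    outside = SimVariant(
        VariantKey("chr20", 500_000, "G", "C"), first.gene, "outside_plp",
        Classification.PATH, "missense_variant", "missing", 1e-4,
    )
    variants.append(outside)
    by_gene.setdefault("__outside__", {})["plp"] = [outside]

    plp = frozenset(
        v.key for v in variants
        if v.classification in (Classification.PATH, Classification.LPATH)
    )
    return SyntheticKB(variants=variants, by_gene=by_gene, plp_keys=plp)


def build_panel(config: SimulationConfig) -> Panel:
    """Panel object matching the synthetic gene specs."""
    return Panel(
        regions={s.gene: s.region() for s in config.genes},
        hfe_target=DEFAULT_HFE_TARGET,
    )


# ---------------------------------------------------------------------------
# Knowledge-base files
# ---------------------------------------------------------------------------


def _clinvar_date(kind: str, i: int) -> str:
    """Deterministic LastEvaluated strings per branch ('Jan 22, 2022' style)."""
    months = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
              "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")
    if kind == "recent":
        return f"{months[i % 12]} {1 + i % 28}, {2016 + i % 6}"
    if kind == "stale":
        return f"{months[i % 12]} {1 + i % 28}, {2010 + i % 6}"
    return "-"


_PLP_SIG_CYCLE = (
    "Pathogenic",
    "Likely pathogenic",
    "Pathogenic/Likely pathogenic",
    "Pathogenic, risk factor",
    "Likely pathogenic, risk factor",
    "Pathogenic/Likely pathogenic, risk factor",
)


def simulate_knowledgebase(config: SimulationConfig, outdir: str | Path,
                           kb: SyntheticKB | None = None) -> dict[str, Path]:
    """Write vip.tsv, clinvar.tsv and freq.tsv for the synthetic variant set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kb = kb or build_synthetic_kb(config)
    rng = np.random.default_rng([config.seed, _STREAM_CLINVAR])

    vip_rows = []
    for v in kb.variants:
        if v.classification is None:
            continue
        vip_rows.append(
            {"Chrom": v.key.chrom, "Pos": v.key.pos, "Ref": v.key.ref,
             "Alt": v.key.alt, "Gene": v.gene,
             "Vip_variant_interpretation": v.classification.value}
        )
    vip_path = outdir / "vip.tsv"
    pd.DataFrame(vip_rows).to_csv(vip_path, sep="\t", index=False)

    noise = config.clinvar_noise
    branch_p = np.array([
        noise.conflicting_fraction, noise.stale_fraction,
        noise.low_star_fraction, noise.missing_date_fraction,
    ])
    pass_p = max(0.0, 1.0 - branch_p.sum())
    clinvar_rows = []
    plp_variants = [v for v in kb.variants
                    if v.classification in (Classification.PATH,
                                            Classification.LPATH)]
    for i, v in enumerate(plp_variants):
        u = rng.random()
        edges = np.cumsum(branch_p)
        if u < edges[0]:
            sig = "Conflicting interpretations of pathogenicity"
            status = "criteria provided, conflicting interpretations"
            when = _clinvar_date("recent", i)
        elif u < edges[1]:
            sig = _PLP_SIG_CYCLE[i % 6]
            status = "criteria provided, multiple submitters, no conflicts"
            when = _clinvar_date("stale", i)
        elif u < edges[2]:
            sig = _PLP_SIG_CYCLE[i % 6]
            status = "criteria provided, single submitter"
            when = _clinvar_date("recent", i)
        elif u < edges[3]:
            sig = _PLP_SIG_CYCLE[i % 6]
            status = "criteria provided, multiple submitters, no conflicts"
            when = _clinvar_date("missing", i)
        else:
            sig = _PLP_SIG_CYCLE[i % 6]
            r = rng.random()
            if r < 0.2:
                status, when = "practice guideline", _clinvar_date("stale", i)
            elif r < 0.4:
                status, when = "reviewed by expert panel", _clinvar_date("stale", i)
            else:
                status = "criteria provided, multiple submitters, no conflicts"
                when = _clinvar_date("recent", i)
        clinvar_rows.append(
            {"Assembly": "GRCh38", "GeneSymbol": v.gene,
             "ClinicalSignificance": sig, "ReviewStatus": status,
             "LastEvaluated": when, "Chromosome": v.key.chrom.removeprefix("chr"),
             "PositionVCF": v.key.pos, "ReferenceAlleleVCF": v.key.ref,
             "AlternateAlleleVCF": v.key.alt}
        )
        if i % 4 == 0:  # GRCh37 duplicate decoy, excluded by assembly
            row37 = dict(clinvar_rows[-1])
            row37["Assembly"] = "GRCh37"
            clinvar_rows.append(row37)
    clinvar_path = outdir / "clinvar.tsv"
    pd.DataFrame(clinvar_rows).to_csv(clinvar_path, sep="\t", index=False)

    freq_path = outdir / "freq.tsv"
    _write_frequencies(config, kb, freq_path)
    return {"vip": vip_path, "clinvar": clinvar_path, "freq": freq_path}


_AN_BY_POP = {"afr": 16_000, "amr": 17_000, "eas": 9_000, "eur": 113_000,
              "mid": 300, "sas": 15_000, "oth": 3_000}
_SUBSET_AN_FACTOR = {"full": 1.0, "non_cancer": 0.85, "non_topmed": 0.60}


def _write_frequencies(config: SimulationConfig, kb: SyntheticKB,
                       path: Path) -> None:
    """Reference allele counts consistent with the planted carrier rates.

    Per-variant allele frequency in a population is the planted carrier rate
    scaled to alleles and split evenly over the gene's P/LP variants. Genes
    whose carriers are planted heterozygous contribute one alt allele per two
    chromosomes (af = rate / 2); genes planted homozygous (the recessive trio
    and HFE) contribute two (af = rate), keeping reference and cohort allele
    rates commensurable. The ``full`` subset of designated genes is inflated
    to emulate disease-ascertained samples.
    """
    specs = {s.gene: s for s in config.genes}
    rows = []
    for gene, roles in kb.by_gene.items():
        spec = specs.get(gene)
        if spec is None:
            continue
        plps = roles.get("plp", [])
        if not plps:
            continue
        if spec.plant_zygosity:
            hom = spec.plant_zygosity == "hom_alt"
        else:
            hom = spec.inheritance in (Inheritance.RECESSIVE, Inheritance.HFE)
        allele_factor = 1.0 if hom else 0.5
        for v in plps:
            pop_afs = {
                pop: plp_rate(config, spec, pop) * allele_factor / len(plps)
                for pop in _AN_BY_POP
            }
            popmax = max(pop_afs.values())
            for subset, factor in _SUBSET_AN_FACTOR.items():
                inflate = (
                    config.full_subset_inflation
                    if subset == "full"
                    and gene in config.inflated_full_subset_genes
                    else 1.0
                )
                total_ac = total_an = 0
                for pop, an0 in _AN_BY_POP.items():
                    an = int(round(an0 * factor))
                    ac = int(round(pop_afs[pop] * inflate * an))
                    total_ac += ac
                    total_an += an
                    rows.append(
                        {"Chrom": v.key.chrom, "Pos": v.key.pos,
                         "Ref": v.key.ref, "Alt": v.key.alt, "Gene": gene,
                         "Population": pop, "Subset": subset, "AC": ac,
                         "AN": an, "Popmax_AF": f"{popmax:.6g}"}
                    )
                rows.append(
                    {"Chrom": v.key.chrom, "Pos": v.key.pos, "Ref": v.key.ref,
                     "Alt": v.key.alt, "Gene": gene, "Population": "all",
                     "Subset": subset, "AC": total_ac, "AN": total_an,
                     "Popmax_AF": f"{popmax:.6g}"}
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig, outdir: str | Path,
                    kb: SyntheticKB | None = None) -> dict[str, Path]:
    """Write cohort.vcf, ancestry.tsv, truth.tsv, ehr.tsv, survey.tsv, panel.tsv.

    Carrier status per gene and category is drawn per participant at the
    planted per-ancestry rate; carriers are assigned a variant from the
    synthetic knowledge base with zygosity respecting the gene's inheritance
    mode, so planted "qualifying" carriers actually qualify. GQ noise pushes
    a configured fraction of carrier calls to GQ <= threshold. The truth
    table records every planted carrier with its rule-level status.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kb = kb or build_synthetic_kb(config)
    panel = build_panel(config)
    n = config.n_participants
    groups = list(ANCESTRY_GROUPS)
    sample_ids = [f"P{i:06d}" for i in range(n)]

    rng_anc = np.random.default_rng([config.seed, _STREAM_ANCESTRY])
    props = np.array([config.ancestry_proportions.get(g, 0.0) for g in groups])
    anc_idx = rng_anc.choice(len(groups), size=n, p=props / props.sum())
    ancestry = np.array(groups)[anc_idx]
    scale = np.array([config.ancestry_rate_scale[g] for g in groups])[anc_idx]

    rng_car = np.random.default_rng([config.seed, _STREAM_CARRIERS])
    rng_gq = np.random.default_rng([config.seed, _STREAM_GQ])

    # key -> {sample_index: (n_alt, gq)}
    genotype: dict[VariantKey, dict[int, tuple[int, int]]] = defaultdict(dict)
    truth_rows: list[dict] = []
    specs = {s.gene: s for s in config.genes}

    def draw_gq(size: int) -> tuple[np.ndarray, np.ndarray]:
        fail = rng_gq.random(size) < config.gq_fail_fraction
        gq = np.where(fail,
                      rng_gq.integers(0, config.gq_threshold + 1, size),
                      rng_gq.integers(30, 100, size))
        return gq.astype(int), ~fail

    def plant(spec: GeneSimSpec, variants: Sequence[SimVariant],
              rates: np.ndarray, zygosity: str, truth_category) -> None:
        if not variants or not rates.any():
            return
        carriers = np.flatnonzero(rng_car.random(n) < rates)
        if len(carriers) == 0:
            return
        choice = rng_car.integers(0, len(variants), len(carriers))
        gqs, passed = draw_gq(len(carriers))
        for ci, (si, vi) in enumerate(zip(carriers, choice)):
            v = variants[int(vi)]
            n_alt = 2 if zygosity == "hom_alt" else 1
            prev = genotype[v.key].get(int(si))
            if prev is None or prev[0] < n_alt:
                genotype[v.key][int(si)] = (n_alt, int(gqs[ci]))
            cat = _truth_category(spec, v, zygosity, kb.plp_keys)
            truth_rows.append(
                {"participant_id": sample_ids[int(si)], "gene": v.gene,
                 "key": str(v.key), "category": cat,
                 "zygosity": zygosity, "gq": int(gqs[ci]),
                 "qualifies": cat != "none",
                 "passes_gq": bool(passed[ci])}
            )

    for spec in config.genes:
        roles = kb.by_gene[spec.gene]
        base_scaled = spec.plp_carrier_rate * scale
        override = config.gene_rate_overrides.get(spec.gene)
        if override:
            rates = base_scaled.copy()
            for g, value in override.items():
                rates[ancestry == g] = float(value)
        else:
            rates = base_scaled
        if spec.plant_zygosity:
            zyg = spec.plant_zygosity
        elif spec.inheritance in (Inheritance.RECESSIVE, Inheritance.HFE):
            zyg = "hom_alt"
        else:
            zyg = "het"
        plant(spec, roles.get("plp", []), rates, zyg, "plp")
        if spec.lof_mechanism:
            plant(spec, roles.get("plof", []),
                  spec.plof_carrier_rate * scale, "het", "plof")
            plant(spec, roles.get("plof_decoy", []),
                  spec.plof_carrier_rate * scale, "het", "decoy")
        plant(spec, roles.get("vus", []), np.full(n, spec.decoy_vus_rate),
              "het", "decoy")

    # outside-panel decoy carriers (must be excluded by region subsetting)
    outside = kb.by_gene.get("__outside__", {}).get("plp", [])
    if outside and config.outside_panel_decoy_rate > 0:
        carriers = np.flatnonzero(
            rng_car.random(n) < config.outside_panel_decoy_rate
        )
        gqs, _ = draw_gq(len(carriers))
        for ci, si in enumerate(carriers):
            genotype[outside[0].key][int(si)] = (1, int(gqs[ci]))

    vcf_path = outdir / "cohort.vcf"
    _write_vcf(vcf_path, kb, genotype, sample_ids)

    ancestry_path = outdir / "ancestry.tsv"
    pd.DataFrame({"participant_id": sample_ids, "ancestry": ancestry}).to_csv(
        ancestry_path, sep="\t", index=False
    )
    truth_path = outdir / "truth.tsv"
    truth = pd.DataFrame(
        truth_rows,
        columns=["participant_id", "gene", "key", "category", "zygosity",
                 "gq", "qualifies", "passes_gq"],
    ).sort_values(["participant_id", "gene", "key"], ignore_index=True)
    truth = truth.astype({"gq": int, "qualifies": bool, "passes_gq": bool})
    truth.to_csv(truth_path, sep="\t", index=False)

    panel_path = outdir / "panel.tsv"
    write_panel(panel, panel_path)

    ehr_path, survey_path = _write_phenotypes(config, outdir, sample_ids, truth)
    return {"vcf": vcf_path, "ancestry": ancestry_path, "truth": truth_path,
            "panel": panel_path, "ehr": ehr_path, "survey": survey_path}


def _truth_category(spec: GeneSimSpec, v: SimVariant, zygosity: str,
                    plp: frozenset[VariantKey]) -> str:
    """Apply the qualification rules to a planted carrier (bookkeeping)."""
    known = v.key in plp
    if known:
        if spec.inheritance is Inheritance.DOMINANT:
            ok = True
        elif spec.inheritance is Inheritance.RECESSIVE:
            ok = zygosity == "hom_alt"
        else:
            ok = zygosity == "hom_alt" and v.key == DEFAULT_HFE_TARGET
        if ok:
            return "known_plp"
    plof_ok = (
        spec.lof_mechanism
        and v.consequence in LOF_CONSEQUENCES
        and v.lof_confidence == "high"
        and (v.popmax_af is None or v.popmax_af < 1e-3)
    )
    if plof_ok:
        return "plof_known_overlap" if known else "plof_novel"
    return "none"


def _write_vcf(path: Path, kb: SyntheticKB,
               genotype: Mapping[VariantKey, Mapping[int, tuple[int, int]]],
               sample_ids: Sequence[str]) -> None:
    variants = sorted(kb.variants, key=lambda v: (v.key.chrom, v.key.pos,
                                                  v.key.ref, v.key.alt))
    contigs: dict[str, int] = {}
    for v in variants:
        contigs[v.key.chrom] = max(contigs.get(v.key.chrom, 0),
                                   v.key.pos + 100_000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ancestry-burden-simulator\n")
        for chrom, length in sorted(contigs.items()):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
            'annotations. Format: SYMBOL|Consequence|LoF|AF_popmax">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                 'Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for v in variants:
            lof_code = {"high": "HC", "low": "LC"}.get(v.lof_confidence, "")
            popmax = "" if v.popmax_af is None else f"{v.popmax_af:.6g}"
            csq = f"{v.gene}|{v.consequence or ''}|{lof_code}|{popmax}"
            fields = ["0/0:99"] * len(sample_ids)
            for si, (n_alt, gq) in genotype.get(v.key, {}).items():
                gt = "1/1" if n_alt >= 2 else "0/1"
                fields[si] = f"{gt}:{gq}"
            fh.write(
                f"{v.key.chrom}\t{v.key.pos}\t.\t{v.key.ref}\t{v.key.alt}\t"
                f".\tPASS\tCSQ={csq}\tGT:GQ\t" + "\t".join(fields) + "\n"
            )


def _write_phenotypes(config: SimulationConfig, outdir: Path,
                      sample_ids: Sequence[str],
                      truth: pd.DataFrame) -> tuple[Path, Path]:
    model = config.phenotype
    rng = np.random.default_rng([config.seed, _STREAM_PHENOTYPE])
    qualifying = truth[truth["qualifies"]]
    carrier_ids = set(
        qualifying[qualifying["gene"].isin(model.carrier_genes)]
        ["participant_id"]
    )
    ehr_rows, survey_rows = [], []
    decoy_code = ("SNOMED", "44054006")  # unrelated condition decoy
    for pid in sample_ids:
        p = model.baseline_prevalence * (
            model.relative_risk if pid in carrier_ids else 1.0
        )
        has_phenotype = rng.random() < min(p, 1.0)
        if has_phenotype:
            channel = int(rng.integers(0, 4))
            if channel in (0, 3):
                ehr_rows.append((pid, "SNOMED", model.snomed_codes[0]))
            if channel == 1:
                ehr_rows.append((pid, "SNOMED", model.snomed_codes[1]))
            if channel in (2, 3):
                survey_rows.append((pid, model.question_id, model.answer))
        else:
            if rng.random() < 0.02:
                ehr_rows.append((pid, *decoy_code))
            if rng.random() < 0.02:
                survey_rows.append((pid, model.question_id, "skin cancer"))
    ehr_path = outdir / "ehr.tsv"
    pd.DataFrame(ehr_rows, columns=["participant_id", "code_system", "code"]
                 ).to_csv(ehr_path, sep="\t", index=False)
    survey_path = outdir / "survey.tsv"
    pd.DataFrame(survey_rows,
                 columns=["participant_id", "question_id", "answer"]
                 ).to_csv(survey_path, sep="\t", index=False)
    return ehr_path, survey_path


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the complete input bundle (knowledge base + cohort) in outdir."""
    kb = build_synthetic_kb(config)
    paths = simulate_knowledgebase(config, outdir, kb=kb)
    paths.update(simulate_cohort(config, outdir, kb=kb))
    return paths


# ---------------------------------------------------------------------------
# End-to-end recovery
# ---------------------------------------------------------------------------


def end_to_end_recovery(config: SimulationConfig,
                        outdir: str | Path | None = None) -> dict:
    """Simulate, classify and test; report parameter recovery against truth.

    Returns a dict with per-ancestry observed vs planted positive rates (with
    binomial CIs), the chi-square result on the aggregated table, and the
    gene-outlier scan flags alongside the truly divergent planted genes.
    """
    import tempfile

    from .burden_stats import (
        aggregate_for_chisq, chisq_independence, gene_outlier_scan,
        rate_with_ci,
    )
    from .variant_selection import classify_cohort, count_cohort

    def run(workdir: Path) -> dict:
        paths = simulate_all(config, workdir)
        kb = build_synthetic_kb(config)
        panel = build_panel(config)
        findings = classify_cohort(paths["vcf"], panel, kb.plp_keys,
                                   gq_threshold=config.gq_threshold)
        labels = pd.read_csv(paths["ancestry"], sep="\t", dtype=str)
        table = count_cohort(
            findings, dict(zip(labels["participant_id"], labels["ancestry"])),
            panel,
        )
        recovery = {}
        for group in table.groups:
            n_g = int(table.denominators[group])
            if n_g == 0:
                continue
            ci = rate_with_ci(int(table.overall_positive[group]), n_g)
            planted = expected_positive_rate(config, group)
            recovery[group] = {
                "n": n_g, "observed_rate": ci.rate, "planted_rate": planted,
                "ci_low": ci.ci_low, "ci_high": ci.ci_high,
                "planted_within_ci": ci.ci_low <= planted <= ci.ci_high,
            }
        try:
            collapsed = aggregate_for_chisq(table)
            chisq = chisq_independence(collapsed)
            chisq_report = {"statistic": chisq.statistic, "df": chisq.df,
                            "p_value": chisq.p_value}
        except Exception as exc:  # tiny cohorts may not support the test
            chisq_report = {"error": str(exc)}
        scan = gene_outlier_scan(table)
        divergent = sorted(
            {
                gene for gene, per_group in config.gene_rate_overrides.items()
                for g, rate in per_group.items()
                if g != "eur" and plp_rate(config, specs_by_gene(config)[gene],
                                           "eur") > 0
                and not 0.5 <= rate / plp_rate(config,
                                               specs_by_gene(config)[gene],
                                               "eur") / config.ancestry_rate_scale[g] <= 2.0
            }
        )
        flagged = sorted({c.gene for c in scan.flagged})
        return {
            "rate_recovery": recovery,
            "chi_square": chisq_report,
            "outlier_scan": {
                "flagged_genes": flagged,
                "planted_divergent_genes": divergent,
                "m": scan.m,
                "alpha_adjusted": scan.alpha_adjusted,
            },
            "n_findings": len(findings),
        }

    if outdir is not None:
        return run(Path(outdir))
    with tempfile.TemporaryDirectory() as tmp:
        return run(Path(tmp))


def specs_by_gene(config: SimulationConfig) -> dict[str, GeneSimSpec]:
    return {s.gene: s for s in config.genes}
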