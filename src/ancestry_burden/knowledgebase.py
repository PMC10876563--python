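"""Variant knowledge sources: curated P/LP database, ClinVar TSV, population frequencies.

Three tabular knowledge sources feed the burden analysis:

* a curated pathogenic/likely-pathogenic ("VIP"-style) database, keyed by
  chrom-pos-ref-alt, whose ``Path``/``LPath`` rows define the known-P/LP set;
* a ClinVar ``variant_summary.txt``-dialect TSV, filtered by review-status
  star level, clinical-significance string and last-evaluated date into an
  alternative P/LP set;
* a gnomAD-style per-population allele-frequency table (AC/AN per population
  and subset) used for external rate comparisons.

All joins across sources use the raw chrom-pos-ref-alt key exactly as
published: no indel left-alignment or renormalization is attempted, so a
variant represented differently in two sources will fail to join and is
surfaced through the flagged-absent report of :func:`join_frequencies`.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, replace
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("ancestry_burden")

#: Continental ancestry groups used throughout the package.
ANCESTRY_GROUPS = ("afr", "amr", "eas", "eur", "mid", "sas", "oth")

#: gnomAD-style reference subsets supported by the frequency tables.
FREQUENCY_SUBSETS = ("full", "non_cancer", "non_topmed")


class Classification(enum.Enum):
    """Curated interpretation categories of the VIP-style database."""

    PATH = "Path"
    LPATH = "LPath"
    VUS = "VUS"
    BENIGN = "Benign"
    LBENIGN = "LBenign"
    RISK = "Risk"


#: Classifications that count as pathogenic/likely pathogenic.
PLP_CLASSES = frozenset({Classification.PATH, Classification.LPATH})

_ALLELE_RE = re.compile(r"^[ACGT]+$")


class KnowledgeBaseError(ValueError):
    """Raised for malformed or internally inconsistent knowledge-base input."""


# ---------------------------------------------------------------------------
# Variant identity
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class VariantKey:
    """chrom-pos-ref-alt identity; the primary key for every join.

    ``pos`` is the 1-based position of the first REF base (VCF convention);
    ``chrom`` is canonicalized to the ``chr``-prefixed spelling.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def canonicalize_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Build a canonical :class:`VariantKey` from raw record fields.

    ``"1"`` and ``"chr1"`` map to the same key; alleles are uppercased.
    Shared-prefix/suffix trimming is deliberately NOT applied: records are
    joined exactly as published.
    """
    chrom = str(chrom).strip()
    if not chrom.startswith("chr"):
        chrom = "chr" + chrom
    pos = int(pos)
    if pos < 1:
        raise KnowledgeBaseError(f"pos must be >= 1, got {pos}")
    ref = str(ref).strip().upper()
    alt = str(alt).strip().upper()
    for name, allele in (("ref", ref), ("alt", alt)):
        if not _ALLELE_RE.match(allele):
            raise KnowledgeBaseError(
                f"malformed {name} allele {allele!r} at {chrom}:{pos}"
            )
    if ref == alt:
        raise KnowledgeBaseError(f"ref and alt are identical at {chrom}:{pos}: {ref!r}")
    return VariantKey(chrom, pos, ref, alt)


def parse_key(text: str) -> VariantKey:
    """Parse a ``chrom:pos:ref:alt`` string into a canonical key."""
    parts = str(text).split(":")
    if len(parts) != 4:
        raise KnowledgeBaseError(f"cannot parse variant key {text!r}")
    return canonicalize_key(parts[0], int(parts[1]), parts[2], parts[3])


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KBVariant:
    """One curated variant: key, gene symbol and interpretation."""

    key: VariantKey
    gene: str
    classification: Classification
    hgvs_c: str | None = None
    source: str = ""

    @property
    def is_plp(self) -> bool:
        return self.classification in PLP_CLASSES


@dataclass(frozen=True)
class ClinVarRecord:
    """One ClinVar variant_summary row (the columns this analysis uses)."""

    key: VariantKey
    assembly: str  # "GRCh37" | "GRCh38"
    gene: str
    clinical_significance: str
    review_status: str
    stars: int
    last_evaluated: date | None

    def __post_init__(self) -> None:
        if not 0 <= self.stars <= 4:
            raise KnowledgeBaseError(f"stars out of range: {self.stars}")


@dataclass(frozen=True)
class PopFrequencyRecord:
    """Per-population, per-subset allele counts for one variant."""

    key: VariantKey
    gene: str
    population: str
    subset: str
    ac: int
    an: int
    popmax_af: float | None = None

    def __post_init__(self) -> None:
        if self.ac < 0 or self.an < 0:
            raise KnowledgeBaseError(f"negative allele counts for {self.key}")
        if self.ac > self.an:
            raise KnowledgeBaseError(
                f"AC {self.ac} exceeds AN {self.an} for {self.key}"
            )

    @property
    def af(self) -> float | None:
        """Allele frequency; defined only when AN > 0."""
        return self.ac / self.an if self.an > 0 else None


# ---------------------------------------------------------------------------
# VIP-style curated database
# ---------------------------------------------------------------------------

VIP_COLUMNS = ("Chrom", "Pos", "Ref", "Alt", "Gene", "Vip_variant_interpretation")


def load_vip(path: str | Path) -> dict[VariantKey, KBVariant]:
    """Load a VIP-style curated TSV into a key -> record mapping.

    Unknown interpretation strings are rejected, not coerced; duplicate keys
    with conflicting classifications raise an error listing the keys.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in VIP_COLUMNS if c not in df.columns]
    if missing:
        raise KnowledgeBaseError(f"VIP file {path} missing columns: {missing}")
    valid = {c.value: c for c in Classification}
    kb: dict[VariantKey, KBVariant] = {}
    conflicts: list[VariantKey] = []
    for row in df.itertuples(index=False):
        interp = str(row.Vip_variant_interpretation)
        if interp not in valid:
            raise KnowledgeBaseError(
                f"unknown Vip_variant_interpretation {interp!r} "
                f"at {row.Chrom}:{row.Pos}"
            )
        key = canonicalize_key(row.Chrom, int(row.Pos), row.Ref, row.Alt)
        rec = KBVariant(key=key, gene=str(row.Gene), classification=valid[interp],
                        source="vip")
        prev = kb.get(key)
        if prev is not None and prev.classification is not rec.classification:
            conflicts.append(key)
        kb[key] = rec
    if conflicts:
        raise KnowledgeBaseError(
            "conflicting classifications for duplicate keys: "
            + ", ".join(str(k) for k in sorted(set(conflicts)))
        )
    return kb


def plp_keys(kb: Mapping[VariantKey, KBVariant]) -> frozenset[VariantKey]:
    """The Path/LPath subset of a knowledge base, as a key set."""
    return frozenset(k for k, v in kb.items() if v.is_plp)


# ---------------------------------------------------------------------------
# ClinVar dialect
# ---------------------------------------------------------------------------

#: Standard ClinVar review-status -> star mapping.
STAR_TABLE: dict[str, int] = {
    "practice guideline": 4,
    "reviewed by expert panel": 3,
    "criteria provided, multiple submitters, no conflicts": 2,
    "criteria provided, conflicting interpretations": 1,
    "criteria provided, conflicting classifications": 1,
    "criteria provided, single submitter": 1,
    "no assertion criteria provided": 0,
    "no assertion provided": 0,
    "no interpretation for the single variant": 0,
    "no classification for the single variant": 0,
    "no classifications from unflagged records": 0,
}

#: Exact ClinicalSignificance strings accepted by the P/LP filter.
PLP_SIGNIFICANCE = frozenset(
    {
        "Likely pathogenic",
        "Likely pathogenic, risk factor",
        "Pathogenic",
        "Pathogenic/Likely pathogenic",
        "Pathogenic/Likely pathogenic, risk factor",
        "Pathogenic, risk factor",
    }
)

#: Review status required at the two-star level.
TWO_STAR_STATUS = "criteria provided, multiple submitters, no conflicts"

#: Default LastEvaluated cutoff for two-star records.
DEFAULT_CLINVAR_CUTOFF = date(2016, 1, 1)

CLINVAR_COLUMNS = {
    "assembly": "Assembly",
    "gene": "GeneSymbol",
    "significance": "ClinicalSignificance",
    "review_status": "ReviewStatus",
    "last_evaluated": "LastEvaluated",
    "chrom": "Chromosome",
    "pos": "PositionVCF",
    "ref": "ReferenceAlleleVCF",
    "alt": "AlternateAlleleVCF",
}


def stars_from_review_status(review_status: str) -> int:
    """Map a ClinVar ReviewStatus string to its 0-4 star level.

    Unrecognized statuses map to 0 stars with a logged warning.
    """
    status = str(review_status).strip().lower()
    try:
        return STAR_TABLE[status]
    except KeyError:
        logger.warning("unrecognized ClinVar review status %r -> 0 stars",
                       review_status)
        return 0


def _parse_clinvar_date(text) -> date | None:
    """Parse 'Jan 22, 2022'-style or ISO dates; '-' / blank -> None."""
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return None
    text = str(text).strip()
    if text in ("", "-", "nan", "NaN"):
        return None
    for fmt in ("%b %d, %Y", "%B %d, %Y"):
        try:
            return datetime.strptime(text, fmt).date()
        except ValueError:
            pass
    try:
        return date.fromisoformat(text)
    except ValueError:
        logger.warning("unparseable ClinVar LastEvaluated date %r", text)
        return None


def load_clinvar(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[ClinVarRecord]:
    """Load a variant_summary.txt-dialect TSV into :class:`ClinVarRecord` rows.

    ``columns`` remaps the logical column roles (see ``CLINVAR_COLUMNS``) to
    the header names actually present in the file.
    """
    cols = dict(CLINVAR_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise KnowledgeBaseError(f"ClinVar file {path} missing columns: {missing}")
    records: list[ClinVarRecord] = []
    for row in df.itertuples(index=False):
        get = lambda role: getattr(row, cols[role].replace(" ", "_"))
        status = str(get("review_status"))
        records.append(
            ClinVarRecord(
                key=canonicalize_key(get("chrom"), int(get("pos")),
                                     get("ref"), get("alt")),
                assembly=str(get("assembly")),
                gene=str(get("gene")),
                clinical_significance=str(get("significance")),
                review_status=status,
                stars=stars_from_review_status(status),
                last_evaluated=_parse_clinvar_date(get("last_evaluated")),
            )
        )
    return records


def filter_clinvar_plp(
    records: Iterable[ClinVarRecord],
    cutoff_date: date = DEFAULT_CLINVAR_CUTOFF,
) -> dict[VariantKey, KBVariant]:
    """Apply the ClinVar P/LP filtering scheme and map survivors to KBVariants.

    A record is kept iff all of:

    * assembly is GRCh38;
    * ClinicalSignificance is one of the six exact P/LP strings;
    * either it has >= 3 stars (kept regardless of evaluation date), or it has
      exactly 2 stars with ReviewStatus ``"criteria provided, multiple
      submitters, no conflicts"`` and LastEvaluated on/after ``cutoff_date``.

    Two-star records with a missing LastEvaluated date fail the date test and
    are excluded (logged). Survivors are classified ``LPath`` when the
    significance string starts with "Likely pathogenic", otherwise ``Path``.
    """
    out: dict[VariantKey, KBVariant] = {}
    for rec in records:
        if rec.assembly != "GRCh38":
            continue
        if rec.clinical_significance not in PLP_SIGNIFICANCE:
            continue
        if rec.stars >= 3:
            pass
        elif rec.stars == 2 and rec.review_status.strip().lower() == TWO_STAR_STATUS:
            if rec.last_evaluated is None:
                logger.info("excluding 2-star record %s: missing LastEvaluated",
                            rec.key)
                continue
            if rec.last_evaluated < cutoff_date:
                continue
        else:
            continue
        cls = (
            Classification.LPATH
            if rec.clinical_significance.startswith("Likely pathogenic")
            else Classification.PATH
        )
        prev = out.get(rec.key)
        if prev is not None and prev.classification is not cls:
            # keep the more severe interpretation on duplicate keys
            if prev.classification is Classification.PATH:
                continue
        out[rec.key] = KBVariant(key=rec.key, gene=rec.gene, classification=cls,
                                 source="clinvar")
    return out


# ---------------------------------------------------------------------------
# Population frequency tables
# ---------------------------------------------------------------------------

FREQ_COLUMNS = ("Chrom", "Pos", "Ref", "Alt", "Gene", "Population", "Subset",
                "AC", "AN", "Popmax_AF")


def load_frequencies(path: str | Path) -> list[PopFrequencyRecord]:
    """Load a gnomAD-style AC/AN TSV into :class:`PopFrequencyRecord` rows."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in FREQ_COLUMNS if c not in df.columns]
    if missing:
        raise KnowledgeBaseError(f"frequency file {path} missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        popmax = row.Popmax_AF
        popmax = None if popmax in (None, "", "-") or pd.isna(popmax) else float(popmax)
        records.append(
            PopFrequencyRecord(
                key=canonicalize_key(row.Chrom, int(row.Pos), row.Ref, row.Alt),
                gene=str(row.Gene),
                population=str(row.Population),
                subset=str(row.Subset),
                ac=int(row.AC),
                an=int(row.AN),
                popmax_af=popmax,
            )
        )
    return records


def merge_populations(
    records: Iterable[PopFrequencyRecord],
    recipe: Mapping[str, Sequence[str]],
) -> list[PopFrequencyRecord]:
    """Merge populations per a recipe, e.g. ``{"eur": ["fin", "nfe", "asj"]}``.

    AC and AN are summed over the member populations within each
    (key, subset); popmax is the max over members. Populations not mentioned
    in any recipe pass through unchanged.
    """
    members = {m: name for name, mm in recipe.items() for m in mm}
    merged: dict[tuple[VariantKey, str, str], dict] = {}
    out: list[PopFrequencyRecord] = []
    for rec in records:
        target = members.get(rec.population)
        if target is None:
            out.append(rec)
            continue
        slot = merged.setdefault(
            (rec.key, target, rec.subset),
            {"gene": rec.gene, "ac": 0, "an": 0, "popmax": None},
        )
        slot["ac"] += rec.ac
        slot["an"] += rec.an
        if rec.popmax_af is not None:
            slot["popmax"] = max(slot["popmax"] or 0.0, rec.popmax_af)
    for (key, pop, subset), slot in merged.items():
        out.append(
            PopFrequencyRecord(key=key, gene=slot["gene"], population=pop,
                               subset=subset, ac=slot["ac"], an=slot["an"],
                               popmax_af=slot["popmax"])
        )
    return out


def join_frequencies(
    plp_kb: Mapping[VariantKey, KBVariant],
    freq_records: Iterable[PopFrequencyRecord],
    population: str,
    subset: str = "full",
) -> pd.DataFrame:
    """Join a P/LP knowledge base to one population/subset of a frequency table.

    Returns one row per P/LP variant with columns ``key, gene, ac, an,
    popmax_af, absent``. P/LP variants absent from the frequency table get
    ``ac = 0, an = 0`` and ``absent = True`` so representation mismatches are
    visible rather than silently dropped.
    """
    selected: dict[VariantKey, PopFrequencyRecord] = {}
    for rec in freq_records:
        if rec.population != population or rec.subset != subset:
            continue
        if rec.key in selected:
            raise KnowledgeBaseError(
                f"duplicate frequency row for ({rec.key}, {population}, {subset})"
            )
        selected[rec.key] = rec
    rows = []
    for key, var in plp_kb.items():
        if not var.is_plp:
            continue
        rec = selected.get(key)
        rows.append(
            {
                "key": key,
                "gene": var.gene,
                "population": population,
                "subset": subset,
                "ac": rec.ac if rec else 0,
                "an": rec.an if rec else 0,
                "popmax_af": rec.popmax_af if rec else None,
                "absent": rec is None,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["key", "gene", "population", "subset", "ac", "an",
                 "popmax_af", "absent"],
    )
    n_absent = int(df["absent"].sum()) if len(df) else 0
    if n_absent:
        logger.info("%d/%d P/LP variants absent from %s/%s frequency table",
                    n_absent, len(df), population, subset)
    return df.sort_values("key", ignore_index=True, key=lambda s: s.map(str))
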