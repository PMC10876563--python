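"""Region padding, GQ/zygosity/pLoF rules and cohort counting."""

import random

import numpy as np
import pytest

from helpers import oracle_counts

from ancestry_burden.knowledgebase import VariantKey
from ancestry_burden.variant_selection import (
    AnnotationSpec,
    Category,
    ConsequenceAnnotation,
    Finding,
    GeneRegion,
    Inheritance,
    Panel,
    ParticipantCall,
    SelectionError,
    Zygosity,
    count_cohort,
    is_plof,
    pad_region,
    passes_gq,
    qualifying_findings,
    read_cohort_calls,
)

HFE_KEY = VariantKey("chr6", 26092913, "G", "A")


def region(gene="BRCA2", chrom="chr13", intervals=((10000, 12000),),
           strand="+", inheritance=Inheritance.DOMINANT, lof=True):
    return GeneRegion(gene=gene, chrom=chrom, coding_intervals=intervals,
                      strand=strand, inheritance=inheritance,
                      lof_mechanism=lof)


def call(pid="P1", chrom="chr13", pos=11000, ref="A", alt="G",
         zyg=Zygosity.HET, gq=99, csq=None, lof="missing", popmax=None):
    return ParticipantCall(
        participant_id=pid,
        key=VariantKey(chrom, pos, ref, alt),
        zygosity=zyg,
        gq=gq,
        annotation=ConsequenceAnnotation(csq, lof, popmax),
    )


class TestPadRegion:
    def test_plus_strand(self):
        assert pad_region(region(strand="+")) == (8000, 13000)

    def test_minus_strand_mirrors(self):
        assert pad_region(region(strand="-")) == (9000, 14000)

    def test_clipped_at_one(self):
        r = region(intervals=((1500, 3000),), strand="+")
        assert pad_region(r) == (1, 4000)

    def test_symmetric_mode_ignores_strand(self):
        r = region(strand="-")
        assert pad_region(r, strand_aware=False) == (8000, 13000)

    def test_envelope_spans_all_intervals(self):
        r = region(intervals=((10000, 11000), (20000, 21000)))
        assert pad_region(r) == (8000, 22000)


class TestPassesGq:
    @pytest.mark.parametrize("gq,expected", [(21, True), (20, False), (0, False)])
    def test_strict_boundary(self, gq, expected):
        assert passes_gq(call(gq=gq)) is expected


class TestIsPlof:
    @pytest.mark.parametrize("csq,lof,popmax,expected", [
        ("stop_gained", "high", 0.0005, True),
        ("stop_gained", "high", 0.001, False),   # strictly below 0.001
        ("missense_variant", "high", 0.0, False),
        ("stop_gained", "low", 0.0005, False),
        ("stop_gained", "missing", 0.0005, False),
        ("frameshift_variant", "high", None, True),  # missing AF implies rare
        ("splice_donor_variant", "high", 0.00099, True),
        ("transcript_ablation", "high", 0.0, False),  # outside the 6-term set
    ])
    def test_rules(self, csq, lof, popmax, expected):
        ann = ConsequenceAnnotation(csq, lof, popmax)
        assert is_plof(ann) is expected


class TestQualifyingFindings:
    def test_dominant_het_known_plp(self):
        plp = {call().key}
        (f,) = qualifying_findings([call()], plp, region())
        assert f.category is Category.KNOWN_PLP

    def test_recessive_requires_homozygous(self):
        r = region(gene="MUTYH", chrom="chr1",
                   inheritance=Inheritance.RECESSIVE, lof=False)
        het = call(chrom="chr1")
        hom = call(chrom="chr1", zyg=Zygosity.HOM_ALT)
        plp = {het.key}
        assert qualifying_findings([het], plp, r) == []
        (f,) = qualifying_findings([hom], plp, r)
        assert f.category is Category.KNOWN_PLP

    def test_hfe_only_target_homozygote(self):
        r = region(gene="HFE", chrom="chr6",
                   intervals=((26087000, 26098000),),
                   inheritance=Inheritance.HFE, lof=False)
        target_het = call(chrom="chr6", pos=26092913, ref="G", alt="A")
        target_hom = call(chrom="chr6", pos=26092913, ref="G", alt="A",
                          zyg=Zygosity.HOM_ALT)
        other_hom = call(chrom="chr6", pos=26090000, ref="C", alt="T",
                         zyg=Zygosity.HOM_ALT)
        plp = {target_het.key, other_hom.key}
        assert qualifying_findings([target_het], plp, r, hfe_target=HFE_KEY) == []
        assert qualifying_findings([other_hom], plp, r, hfe_target=HFE_KEY) == []
        (f,) = qualifying_findings([target_hom], plp, r, hfe_target=HFE_KEY)
        assert f.category is Category.KNOWN_PLP

    def test_plof_novel_vs_overlap_and_precedence(self):
        novel = call(pos=11100, csq="stop_gained", lof="high", popmax=1e-4)
        overlap = call(pos=11200, csq="frameshift_variant", lof="high",
                       popmax=1e-4)
        plp = {overlap.key}
        found = qualifying_findings([novel, overlap], plp, region())
        by_pos = {f.key.pos: f.category for f in found}
        assert by_pos[11100] is Category.PLOF_NOVEL
        # known P/LP takes precedence over the overlap category
        assert by_pos[11200] is Category.KNOWN_PLP

    def test_plof_overlap_when_zygosity_blocks_known(self):
        r = region(gene="MUTYH", chrom="chr1",
                   inheritance=Inheritance.RECESSIVE, lof=True)
        het = call(chrom="chr1", csq="stop_gained", lof="high", popmax=1e-4)
        (f,) = qualifying_findings([het], {het.key}, r)
        assert f.category is Category.PLOF_KNOWN_OVERLAP

    def test_plof_ignored_outside_lof_mechanism_genes(self):
        r = region(lof=False)
        c = call(csq="stop_gained", lof="high", popmax=1e-4)
        assert qualifying_findings([c], set(), r) == []

    def test_call_outside_region_is_an_error(self):
        c = call(pos=500_000)
        with pytest.raises(SelectionError, match="outside"):
            qualifying_findings([c], set(), region())


def _make_panel():
    return Panel(
        regions={
            "BRCA2": region(),
            "MUTYH": region(gene="MUTYH", chrom="chr1",
                            inheritance=Inheritance.RECESSIVE, lof=False),
        },
        hfe_target=HFE_KEY,
    )


class TestCountCohort:
    def test_distinct_participant_semantics(self):
        panel = _make_panel()
        findings = [
            Finding("P1", "BRCA2", VariantKey("chr13", 11000, "A", "G"),
                    Category.KNOWN_PLP),
            Finding("P1", "MUTYH", VariantKey("chr1", 11000, "A", "G"),
                    Category.KNOWN_PLP),
        ]
        table = count_cohort(findings, {"P1": "eur", "P2": "afr"}, panel)
        assert table.counts.loc["BRCA2", "eur"] == 1
        assert table.counts.loc["MUTYH", "eur"] == 1
        assert table.overall_positive["eur"] == 1  # one participant, not two
        assert table.denominators["afr"] == 1

    def test_same_gene_two_variants_counts_once_per_gene(self):
        panel = _make_panel()
        findings = [
            Finding("P1", "BRCA2", VariantKey("chr13", 11000, "A", "G"),
                    Category.KNOWN_PLP),
            Finding("P1", "BRCA2", VariantKey("chr13", 11500, "C", "T"),
                    Category.PLOF_NOVEL),
        ]
        table = count_cohort(findings, {"P1": "eur"}, panel)
        assert table.counts.loc["BRCA2", "eur"] == 1
        instance = count_cohort(findings, {"P1": "eur"}, panel, mode="instance")
        assert instance.counts.loc["BRCA2", "eur"] == 2

    def test_empty_findings_zero_table_with_denominators(self):
        table = count_cohort([], {"P1": "eur", "P2": "eur", "P3": "afr"},
                             _make_panel())
        assert (table.counts.to_numpy() == 0).all()
        assert table.denominators["eur"] == 2

    def test_missing_ancestry_excluded_and_reported(self):
        findings = [Finding("P9", "BRCA2",
                            VariantKey("chr13", 11000, "A", "G"),
                            Category.KNOWN_PLP)]
        table = count_cohort(findings, {"P1": "eur", "P9": "unknown"},
                             _make_panel())
        assert table.denominators.sum() == 1
        assert "P9" in table.diagnostics["participants_missing_ancestry"]
        assert "P9" in table.diagnostics["findings_participants_missing_ancestry"]


def _random_cohort(rng: random.Random, n_participants: int, n_variants: int):
    """Random small cohort spanning all inheritance modes for the oracle test."""
    regions = {
        "DOM": region(gene="DOM", chrom="chr13", lof=True),
        "REC": region(gene="REC", chrom="chr1",
                      inheritance=Inheritance.RECESSIVE, lof=False),
        "HFE": region(gene="HFE", chrom="chr6",
                      intervals=((26087000, 26098000),),
                      inheritance=Inheritance.HFE, lof=False),
    }
    spots = []
    for r in regions.values():
        start, end = pad_region(r)
        for _ in range(n_variants // 3 + 1):
            spots.append((r, rng.randrange(start, end + 1)))
    spots.append((regions["HFE"], 26092913))  # ensure the target key exists
    variants = []
    for r, pos in spots[:n_variants]:
        ref, alt = rng.sample("ACGT", 2)
        if pos == 26092913:
            ref, alt = "G", "A"
        variants.append((r, VariantKey(r.chrom, pos, ref, alt)))
    plp = {key for _, key in variants if rng.random() < 0.5}
    calls = []
    for pid in range(n_participants):
        for r, key in variants:
            if rng.random() > 0.15:
                continue
            if rng.random() < 0.3:
                ann = ConsequenceAnnotation(
                    rng.choice(["stop_gained", "frameshift_variant",
                                "missense_variant"]),
                    rng.choice(["high", "low", "missing"]),
                    rng.choice([None, 1e-4, 0.002]),
                )
            else:
                ann = ConsequenceAnnotation()
            calls.append(ParticipantCall(
                participant_id=f"P{pid}",
                key=key,
                zygosity=rng.choice([Zygosity.HET, Zygosity.HOM_ALT]),
                gq=rng.randrange(0, 100),
                annotation=ann,
            ))
    ancestry = {f"P{pid}": rng.choice(["eur", "afr", "amr"])
                for pid in range(n_participants)}
    return regions, plp, calls, ancestry


def _pipeline_counts(regions, plp, calls, ancestry, gq_threshold=20):
    panel = Panel(regions=dict(regions), hfe_target=HFE_KEY)
    grouped = {}
    for c in calls:
        if not passes_gq(c, gq_threshold):
            continue
        gene = panel.gene_at(c.key.chrom, c.key.pos)
        if gene is None:
            continue
        grouped.setdefault((c.participant_id, gene), []).append(c)
    findings = []
    for (pid, gene), group in grouped.items():
        findings.extend(qualifying_findings(group, plp, regions[gene],
                                            hfe_target=HFE_KEY))
    return count_cohort(findings, ancestry, panel), findings


@pytest.mark.parametrize("seed", range(12))
def test_pipeline_matches_brute_force_oracle(seed):
    """Counting pipeline equals a nested-loop per-call oracle on small cohorts."""
    rng = random.Random(seed)
    n = rng.randrange(20, 101)
    m = rng.randrange(10, 51)
    regions, plp, calls, ancestry = _random_cohort(rng, n, m)
    table, _ = _pipeline_counts(regions, plp, calls, ancestry)
    cells, overall = oracle_counts(calls, regions, plp, HFE_KEY, ancestry)
    for gene in table.genes:
        for group in table.groups:
            assert table.counts.loc[gene, group] == cells.get((gene, group), 0)
    for group in table.groups:
        assert table.overall_positive[group] == overall.get(group, 0)


def test_gq_filter_removal_is_monotone():
    """Dropping the GQ filter can only grow every cell of the table."""
    rng = random.Random(99)
    regions, plp, calls, ancestry = _random_cohort(rng, 60, 30)
    filtered, _ = _pipeline_counts(regions, plp, calls, ancestry, gq_threshold=20)
    unfiltered, _ = _pipeline_counts(regions, plp, calls, ancestry, gq_threshold=-1)
    assert (unfiltered.counts.to_numpy() >= filtered.counts.to_numpy()).all()


def test_call_order_invariance():
    """Permuting input calls never changes the counted table."""
    rng = random.Random(5)
    regions, plp, calls, ancestry = _random_cohort(rng, 40, 20)
    table1, _ = _pipeline_counts(regions, plp, calls, ancestry)
    shuffled = list(calls)
    rng.shuffle(shuffled)
    table2, _ = _pipeline_counts(regions, plp, shuffled, ancestry)
    assert table1.counts.equals(table2.counts)
    assert table1.overall_positive.equals(table2.overall_positive)


class TestVcfReading:
    def test_multiallelic_decomposition_and_gq(self, tmp_path):
        vcf = tmp_path / "mini.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr13,length=100000>\n"
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
            'annotations. Format: SYMBOL|Consequence|LoF|AF_popmax">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "chr13\t11000\t.\tA\tG,T\t.\tPASS\t"
            "CSQ=BRCA2|stop_gained|HC|0.0001,BRCA2|missense_variant||\t"
            "GT:GQ\t0/1:99\t2/2:50\t0/0:99\n"
            "chr13\t11500\t.\tC\tT\t.\tPASS\tCSQ=BRCA2|missense_variant||\t"
            "GT:GQ\t0/1:10\t0/1:99\t0/0:99\n"
            "chr13\t90000\t.\tG\tA\t.\tPASS\tCSQ=BRCA2|missense_variant||\t"
            "GT:GQ\t0/1:99\t0/0:99\t0/0:99\n"
        )
        panel = Panel(regions={"BRCA2": region()})
        calls = read_cohort_calls(vcf, panel, gq_threshold=20)
        got = {(c.participant_id, c.key.pos, c.key.alt, c.zygosity, c.gq)
               for c in calls}
        # S1 fails GQ at 11500; the 90000 record lies outside the padded region
        assert got == {
            ("S1", 11000, "G", Zygosity.HET, 99),
            ("S2", 11000, "T", Zygosity.HOM_ALT, 50),
            ("S2", 11500, "T", Zygosity.HET, 99),
        }
        annos = {(c.key.pos, c.key.alt): c.annotation for c in calls}
        assert annos[(11000, "G")].most_severe_consequence == "stop_gained"
        assert annos[(11000, "G")].lof_confidence == "high"
        assert annos[(11000, "T")].most_severe_consequence == "missense_variant"
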