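"""Knowledge-source parsing, star mapping, P/LP filtering and joins."""

from datetime import date

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ancestry_burden.knowledgebase import (
    Classification,
    ClinVarRecord,
    KnowledgeBaseError,
    PopFrequencyRecord,
    VariantKey,
    canonicalize_key,
    filter_clinvar_plp,
    join_frequencies,
    load_clinvar,
    load_vip,
    merge_populations,
    plp_keys,
    stars_from_review_status,
    PLP_SIGNIFICANCE,
    TWO_STAR_STATUS,
    _parse_clinvar_date,
)


class TestCanonicalizeKey:
    def test_chr_prefix_is_added(self):
        assert canonicalize_key("22", 36265860, "A", "G") == VariantKey(
            "chr22", 36265860, "A", "G"
        )

    def test_case_normalization_and_existing_prefix(self):
        assert canonicalize_key("chr1", 100, "a", "t") == VariantKey(
            "chr1", 100, "A", "T"
        )

    def test_identical_alleles_rejected(self):
        with pytest.raises(KnowledgeBaseError, match="identical"):
            canonicalize_key("1", 100, "A", "A")

    @pytest.mark.parametrize("ref,alt,field", [("N", "A", "ref"), ("A", "x", "alt")])
    def test_malformed_allele_names_offending_field(self, ref, alt, field):
        with pytest.raises(KnowledgeBaseError, match=field):
            canonicalize_key("1", 100, ref, alt)

    def test_position_below_one_rejected(self):
        with pytest.raises(KnowledgeBaseError):
            canonicalize_key("1", 0, "A", "T")


# Hand-built fixture of the standard ClinVar review-status ladder.
STAR_FIXTURE = [
    ("practice guideline", 4),
    ("reviewed by expert panel", 3),
    ("criteria provided, multiple submitters, no conflicts", 2),
    ("criteria provided, conflicting interpretations", 1),
    ("criteria provided, single submitter", 1),
    ("no assertion criteria provided", 0),
    ("no assertion provided", 0),
    ("no interpretation for the single variant", 0),
]


class TestStars:
    @pytest.mark.parametrize("status,stars", STAR_FIXTURE)
    def test_standard_ladder(self, status, stars):
        assert stars_from_review_status(status) == stars

    def test_case_insensitive(self):
        assert stars_from_review_status("Practice Guideline") == 4

    def test_unrecognized_maps_to_zero(self, caplog):
        with caplog.at_level("WARNING", logger="ancestry_burden"):
            assert stars_from_review_status("submitted by a friend") == 0
        assert "unrecognized" in caplog.text


def _cv(pos=1000, assembly="GRCh38", sig="Pathogenic",
        status=TWO_STAR_STATUS, when=date(2020, 1, 1), gene="BRCA2"):
    return ClinVarRecord(
        key=VariantKey("chr13", pos, "A", "G"),
        assembly=assembly,
        gene=gene,
        clinical_significance=sig,
        review_status=status,
        stars=stars_from_review_status(status),
        last_evaluated=when,
    )


class TestClinVarFilter:
    def test_golden_branches(self):
        """Every star/date/significance/assembly branch of the filter."""
        records = {
            "two_star_recent": _cv(pos=1),
            "two_star_on_cutoff": _cv(pos=2, when=date(2016, 1, 1)),
            "two_star_stale": _cv(pos=3, when=date(2015, 12, 31)),
            "two_star_missing_date": _cv(pos=4, when=None),
            "three_star_stale": _cv(pos=5, status="reviewed by expert panel",
                                    when=date(2010, 6, 1)),
            "four_star_stale": _cv(pos=6, status="practice guideline",
                                   when=date(2010, 6, 1)),
            "one_star_recent": _cv(pos=7,
                                   status="criteria provided, single submitter"),
            "conflicting_sig": _cv(
                pos=8, sig="Conflicting interpretations of pathogenicity"),
            "benign": _cv(pos=9, sig="Benign"),
            "grch37": _cv(pos=10, assembly="GRCh37"),
        }
        kept = filter_clinvar_plp(records.values())
        kept_pos = {k.pos for k in kept}
        assert kept_pos == {1, 2, 5, 6}

    @pytest.mark.parametrize("sig", sorted(PLP_SIGNIFICANCE))
    def test_all_six_significance_strings_pass(self, sig):
        kept = filter_clinvar_plp([_cv(sig=sig)])
        assert len(kept) == 1
        rec = next(iter(kept.values()))
        expected = (Classification.LPATH if sig.startswith("Likely pathogenic")
                    else Classification.PATH)
        assert rec.classification is expected

    @given(
        st.lists(
            st.builds(
                _cv,
                pos=st.integers(1, 500),
                assembly=st.sampled_from(["GRCh37", "GRCh38"]),
                sig=st.sampled_from(sorted(PLP_SIGNIFICANCE) + ["Benign"]),
                status=st.sampled_from([s for s, _ in STAR_FIXTURE]),
                when=st.one_of(st.none(), st.dates(date(2005, 1, 1),
                                                   date(2023, 1, 1))),
            ),
            max_size=30,
        ),
        st.dates(date(2010, 1, 1), date(2022, 1, 1)),
        st.integers(1, 2000),
    )
    def test_monotone_in_cutoff_date(self, records, cutoff, delta):
        """A later cutoff never admits a variant a stricter run excluded."""
        from datetime import timedelta

        early = set(filter_clinvar_plp(records, cutoff_date=cutoff))
        late = set(filter_clinvar_plp(
            records, cutoff_date=cutoff + timedelta(days=delta)))
        assert late <= early

    @given(
        st.lists(
            st.builds(
                _cv,
                pos=st.integers(1, 500),
                assembly=st.sampled_from(["GRCh37", "GRCh38"]),
                sig=st.sampled_from(sorted(PLP_SIGNIFICANCE)
                                    + ["Benign", "Uncertain significance"]),
                status=st.sampled_from([s for s, _ in STAR_FIXTURE]),
            ),
            max_size=30,
        )
    )
    def test_outputs_confined_to_contract(self, records):
        by_key = {r.key: r for r in records if r.assembly == "GRCh38"}
        for key, var in filter_clinvar_plp(records).items():
            assert var.is_plp
            src = by_key[key]
            assert src.clinical_significance in PLP_SIGNIFICANCE


class TestClinVarDates:
    @pytest.mark.parametrize("text,expected", [
        ("Jan 22, 2022", date(2022, 1, 22)),
        ("December 3, 2015", date(2015, 12, 3)),
        ("2016-01-01", date(2016, 1, 1)),
        ("-", None),
        ("", None),
    ])
    def test_parse(self, text, expected):
        assert _parse_clinvar_date(text) == expected


class TestLoadVip:
    def _write(self, tmp_path, rows):
        path = tmp_path / "vip.tsv"
        header = "Chrom\tPos\tRef\tAlt\tGene\tVip_variant_interpretation\n"
        path.write_text(header + "".join(rows))
        return path

    def test_classifications_loaded_and_plp_subset(self, tmp_path):
        path = self._write(tmp_path, [
            "13\t100\tA\tG\tBRCA2\tPath\n",
            "chr13\t200\tC\tT\tBRCA2\tLPath\n",
            "13\t300\tG\tA\tBRCA2\tVUS\n",
        ])
        kb = load_vip(path)
        assert len(kb) == 3
        assert kb[VariantKey("chr13", 100, "A", "G")].classification is Classification.PATH
        assert plp_keys(kb) == {
            VariantKey("chr13", 100, "A", "G"),
            VariantKey("chr13", 200, "C", "T"),
        }

    def test_unknown_interpretation_rejected(self, tmp_path):
        path = self._write(tmp_path, ["13\t100\tA\tG\tBRCA2\tprobably bad\n"])
        with pytest.raises(KnowledgeBaseError, match="probably bad"):
            load_vip(path)

    def test_empty_file_with_header(self, tmp_path):
        assert load_vip(self._write(tmp_path, [])) == {}

    def test_conflicting_duplicates_listed(self, tmp_path):
        path = self._write(tmp_path, [
            "13\t100\tA\tG\tBRCA2\tPath\n",
            "13\t100\tA\tG\tBRCA2\tBenign\n",
        ])
        with pytest.raises(KnowledgeBaseError, match="chr13:100:A:G"):
            load_vip(path)


class TestLoadClinVar:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "clinvar.tsv"
        path.write_text(
            "Assembly\tGeneSymbol\tClinicalSignificance\tReviewStatus\t"
            "LastEvaluated\tChromosome\tPositionVCF\tReferenceAlleleVCF\t"
            "AlternateAlleleVCF\n"
            "GRCh38\tBRCA2\tPathogenic\t"
            "criteria provided, multiple submitters, no conflicts\t"
            "Jan 22, 2022\t13\t32340000\tA\tG\n"
        )
        (rec,) = load_clinvar(path)
        assert rec.stars == 2
        assert rec.last_evaluated == date(2022, 1, 22)
        assert rec.key == VariantKey("chr13", 32340000, "A", "G")


def _freq(pos, pop="eur", subset="full", ac=5, an=1000, gene="BRCA2"):
    return PopFrequencyRecord(
        key=VariantKey("chr13", pos, "A", "G"), gene=gene, population=pop,
        subset=subset, ac=ac, an=an,
    )


class TestJoinFrequencies:
    def _kb(self, positions):
        from ancestry_burden.knowledgebase import KBVariant

        return {
            VariantKey("chr13", p, "A", "G"): KBVariant(
                key=VariantKey("chr13", p, "A", "G"), gene="BRCA2",
                classification=Classification.PATH)
            for p in positions
        }

    def test_present_and_absent_variants(self):
        joined = join_frequencies(self._kb([100, 200]), [_freq(100)], "eur")
        present = joined[joined["key"].map(lambda k: k.pos) == 100].iloc[0]
        absent = joined[joined["key"].map(lambda k: k.pos) == 200].iloc[0]
        assert present["ac"] == 5 and not present["absent"]
        assert absent["ac"] == 0 and absent["absent"]

    def test_key_stability(self):
        """|joined| = |P/LP set|; matched + flagged-absent partition it."""
        kb = self._kb([100, 200, 300])
        joined = join_frequencies(kb, [_freq(100), _freq(300)], "eur")
        assert len(joined) == 3
        assert int(joined["absent"].sum()) == 1

    def test_subsets_are_distinct_joins(self):
        records = [_freq(100, subset="full"), _freq(100, subset="non_cancer", ac=2)]
        full = join_frequencies(self._kb([100]), records, "eur", "full")
        nc = join_frequencies(self._kb([100]), records, "eur", "non_cancer")
        assert full.iloc[0]["ac"] == 5 and nc.iloc[0]["ac"] == 2

    def test_duplicate_rows_rejected(self):
        with pytest.raises(KnowledgeBaseError, match="duplicate"):
            join_frequencies(self._kb([100]), [_freq(100), _freq(100)], "eur")

    def test_pop_frequency_invariants(self):
        with pytest.raises(KnowledgeBaseError):
            _freq(100, ac=10, an=5)


class TestMergePopulations:
    def test_eur_recipe_sums_counts(self):
        records = [
            _freq(100, pop="fin", ac=1, an=100),
            _freq(100, pop="nfe", ac=2, an=200),
            _freq(100, pop="asj", ac=3, an=300),
            _freq(100, pop="afr", ac=9, an=900),
        ]
        merged = merge_populations(records, {"eur": ["fin", "nfe", "asj"]})
        eur = [r for r in merged if r.population == "eur"]
        assert len(eur) == 1 and eur[0].ac == 6 and eur[0].an == 600
        assert any(r.population == "afr" and r.ac == 9 for r in merged)
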