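# Methods

## Problem and model

The package estimates, per genetic-ancestry group, the fraction of cohort
participants carrying at least one qualifying variant in an actionable gene
panel, and tests whether those fractions differ between groups and from
external reference databases. A "qualifying" variant is either

* a **known P/LP** variant — present in a curated pathogenic/likely-pathogenic
  knowledge base (or in ClinVar after star/date filtering) — subject to
  inheritance-aware zygosity rules, or
* a **rare high-confidence pLoF** variant in a gene where loss of function is
  an established disease mechanism.

Participants, not alleles, are the default counting unit: a participant with
findings in two genes contributes once to the overall positive rate and once
to each gene's cell. An allele-instance counting mode (`mode="instance"`) is
provided for table-style reporting of every variant occurrence.

## Filtering rules and their parameters

| parameter | default | meaning |
|---|---|---|
| upstream / downstream padding | 2000 / 1000 bp | extension of the coding envelope per gene; "upstream" is the 5' side of the transcription strand |
| GQ threshold | 20 | genotype kept iff GQ > 20, strictly |
| pLoF popmax AF | 0.001 | kept iff popmax AF < 0.001, strictly; missing popmax passes (absence from the reference implies rarity) |
| pLoF consequence set | 6 SO terms | frameshift_variant, stop_gained, stop_lost, splice_acceptor_variant, splice_donor_variant, start_lost; LOFTEE-style confidence must be "high" |
| ClinVar cutoff date | 2016-01-01 | two-star records need LastEvaluated on/after this date; 3–4-star records pass regardless |
| recessive genes | MUTYH, ATP7B, KCNQ1 | homozygous genotypes only |
| HFE rule | rs1800562 (chr6:26092913 G>A, GRCh38) | only this key, homozygous; configurable through the panel file |
| chi-square aggregation | expected ≥ 5; collapse {eas, mid, sas, oth} | sparse groups merged into one column, then smallest-total gene rows merged into one row |
| significance | α = 0.05, Bonferroni α/m | m = number of (gene, group) tests actually performed, unless overridden |
| CI level / method | 0.95 / Wilson | normal approximation selectable |

The two-proportion test is the pooled z-test: with group counts Y₁/n₁ and
Y₂/n₂ and pooled proportion p̂ = (Y₁+Y₂)/(n₁+n₂),
Z = (p̂₁ − p̂₂) / √(p̂(1−p̂)(1/n₁ + 1/n₂)) and p = 2(1 − Φ(|Z|)). When p̂ is
0 or 1 the variance vanishes; the result is flagged degenerate with p = 1
rather than raising. On any 2×2 table Z² equals the Pearson chi-square
statistic without continuity correction — a property the test suite asserts
to 1e-9.

Reference-side per-gene rates follow the published recipe exactly: numerator
= Σ alternate-allele counts over the gene's P/LP variants, denominator =
maximum total allele number observed among them. Cohort rates for these
comparisons are allele-frequency style (alt alleles over 2N chromosomes) so
both sides share a scale; participant-level rates are available but labeled
distinctly.

## Design choices where the design was open

* **Confidence intervals**: Wilson score intervals by default — they behave
  correctly at the small counts typical of per-gene carrier tallies; the
  interval method is recorded in every output row.
* **Relative difference**: defined as (cohort − reference)/reference; an
  absolute-difference mode exists. A zero reference with nonzero cohort rate
  is reported as "defined missing" rather than infinite.
* **Gene-row collapsing order** for the chi-square aggregation: smallest row
  total first, ties broken alphabetically — deterministic and conservative.
* **Bonferroni family size**: the number of comparisons actually performed
  (zero-zero pairs are skipped and listed); overridable.
* **Reported p-values** are always unadjusted, with a separate
  adjusted-significance flag, because adjusted-p conventions are ambiguous
  across publications.
* **Padding strandedness**: strand-aware by default, with a
  coordinate-symmetric toggle, since published descriptions of region
  padding rarely state strandedness.
* **Compound heterozygotes** in recessive genes do not qualify: no phasing
  is attempted, matching homozygous-only counting.
* **Hemizygous/male X genotypes** are treated as homozygous-alt; the panel
  is autosomal-dominated so this choice is rarely exercised.
* **Multi-allelic records** are decomposed into one call per ALT on read;
  no indel left-alignment or renormalization is performed anywhere, so
  records join across sources exactly as published. Representation
  mismatches therefore surface as flagged-absent rows in the frequency
  join, not as silent drops.
* **ClinVar "risk factor" significances** are filtered on the significance
  string alone; zygosity semantics remain a property of the gene rule, not
  of the ClinVar record.
* **Enrichment background**: the full genotyped cohort *including* the
  phenotype cohort (the convention used with large-biobank denominators);
  a complement-background mode is available.

## The synthetic-data generator

The generator emulates the study conditions end to end from one seed:

* **Cohort composition** — eur 50.4%, afr 23.2%, amr 16.1%, eas 2.1%,
  sas 1.0%, mid 0.2%, oth 7.0%.
* **Carrier rates** — a nine-gene panel spanning all inheritance modes
  (five dominant-acting genes, the recessive trio, *HFE*) with European
  known-P/LP carrier rates summing to 1.96% and pLoF rates to 0.30%, giving
  an overall European qualifying rate of ~2.26%; other groups are scaled
  (oth 0.85×, afr 0.72×, amr 0.62×, eas/sas/mid 0.75×), reproducing the
  observed European-highest gradient. Per-gene, per-group absolute
  overrides allow planting divergent genes for power studies.
* **Zygosity** — recessive and *HFE* carriers are planted homozygous so
  planted carriers qualify; a per-gene `plant_zygosity` override plants
  non-qualifying heterozygotes to exercise the rules.
* **Decoys** — VUS/benign records, low-confidence and common (popmax 0.01)
  pLoF-shaped variants, a P/LP-classified variant outside every panel
  region, one P/LP variant inside the upstream padding, ClinVar records
  spanning all star levels, pre-cutoff dates, missing dates, conflicting
  significances and GRCh37 duplicates.
* **Frequency tables** — AC/AN per population in three subsets; per-variant
  allele frequencies track the planted carrier rates (halved for
  heterozygous planting, full for homozygous) so reference and cohort rates
  are commensurable; the `full` subset of designated disease genes is
  inflated 3× to emulate disease-ascertained reference samples.
* **GQ noise** — off by default: the planted rates describe the
  post-GQ-filter data, and failures at true variant sites are rare in WGS.
  When enabled, a configured fraction of carrier calls receives GQ ≤ 20 and
  the classifier's shortfall matches that fraction (asserted within a
  binomial CI).
* **Phenotype** — a breast-cancer-style label with baseline prevalence
  1.68% and relative risk 4 for carriers in BRCA2/PALB2, delivered through
  SNOMED condition codes and/or a literal survey answer plus decoy codes
  and answers.

Randomness uses one root seed with fixed per-purpose
`default_rng([seed, stream_id])` streams, so adding or reordering generation
steps never perturbs other streams; the same seed yields byte-identical
files.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, admixture within participants, sequencing-read-level
error processes, variant-representation ambiguity (all sources share one
representation, so the join false-negative mode is exercised only via the
flagged-absent report), and transcript-level annotation complexity (one
annotation per alt). Passing tests therefore validate the counting and
statistical machinery under the planted model, not robustness to annotation
or representation noise in real call sets.

## Problem sizes used in the test suite

Simulated cohorts range from 500 to 40,000 participants: truth-table
equivalence and knowledge-base checks at n = 4,000; planted-rate recovery at
n = 10,000–12,000 (99% Wilson intervals); outlier-scan power end to end at
n = 40,000 with a 3× divergence planted in the African group; chi-square
calibration on 6,000 null contingency replicates; the brute-force counting
oracle on cohorts up to 100 participants × 50 variants across all
inheritance modes. These sizes give the Monte-Carlo estimates standard
errors comfortably inside the asserted bands.

## Numerical notes and degenerate inputs

* Wilson bounds are clipped to exactly 0 (count = 0) and 1 (count = n).
* `aggregate_for_chisq` raises when even full aggregation cannot reach the
  minimum expected count — small cohorts should use the
  positive/negative × group construction instead (`positive_negative_table`).
* Correlations require ≥ 3 shared genes and are flagged undefined under
  zero variance; subset reports break ties alphabetically and note them.
* Unparseable ClinVar dates and review statuses degrade softly (missing
  date → excluded at 2 stars; unknown status → 0 stars) with logged
  warnings; malformed alleles and conflicting duplicate classifications are
  hard errors naming the offending records.

## Known limitations

* Ancestry labels are consumed as given; the package neither predicts
  ancestry nor models within-participant admixture.
* ClinVar filtering is the simple star/date scheme; variants with
  conflicting interpretations are excluded even when clinically reportable
  (the *HFE* C282Y situation), which is why the curated database, not
  ClinVar, is the default P/LP source.
* No liftover: all sources must share GRCh38 coordinates.
* The chi-square on gene × group counts treats a participant with findings
  in several genes as independent contributions to several cells; the
  participant-level positive/negative construction avoids this and is
  provided alongside.
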