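"""End-to-end orchestration: classify -> stats -> compare -> enrich.

A :class:`RunConfig` names every input and threshold; :func:`run_all`
executes the stages, writes versioned TSV/JSON outputs plus a run manifest
(config echo, input checksums, tool version), and raises a
:class:`StageError` naming the failing stage. Outputs are a pure function of
(inputs, config).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .burden_stats import (
    BurdenTable,
    aggregate_for_chisq,
    chisq_independence,
    gene_outlier_scan,
    group_rate_table,
    positive_negative_table,
)
from .cohort_enrichment import (
    PhenotypeCriteria,
    phenotype_enrichment,
    select_cohort,
)
from .external_comparison import (
    cohort_allele_rates,
    compare_gene_rates,
    gene_level_rate,
    rate_correlation,
)
from .knowledgebase import (
    filter_clinvar_plp,
    join_frequencies,
    load_clinvar,
    load_frequencies,
    load_vip,
    plp_keys,
)
from .variant_selection import classify_cohort, count_cohort, load_panel

logger = logging.getLogger("ancestry_burden")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths, thresholds and toggles for one reproducible run."""

    vcf: Path
    panel: Path
    kb: Path  # VIP-style TSV
    ancestry: Path
    outdir: Path
    clinvar: Path | None = None
    freq: Path | None = None
    ehr: Path | None = None
    survey: Path | None = None
    criteria: Path | None = None  # YAML phenotype criteria
    kb_source: str = "vip"  # "vip" | "clinvar"
    gq_threshold: int = 20
    plof_af_threshold: float = 1e-3
    alpha: float = 0.05
    ci_level: float = 0.95
    reference_group: str = "eur"
    compare_population: str = "all"
    compare_subset: str = "full"
    strand_aware_padding: bool = True
    counting_mode: str = "participant"
    background_mode: str = "full"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vcf", "panel", "kb", "ancestry", "outdir", "clinvar",
                     "freq", "ehr", "survey", "criteria"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        if not 0 < self.alpha < 1 or not 0 < self.ci_level < 1:
            raise ValueError("alpha and ci_level must lie in (0, 1)")
        if self.gq_threshold < 0 or not 0 <= self.plof_af_threshold <= 1:
            raise ValueError("invalid thresholds")
        for name in ("vcf", "panel", "kb", "ancestry", "clinvar", "freq",
                     "ehr", "survey", "criteria"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} input not found: {value}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: str(v) if isinstance(v, Path) else v for k, v in out.items()}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, comment_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in comment_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_criteria(path: str | Path) -> PhenotypeCriteria:
    """Phenotype criteria from YAML: condition_codes [[system, code]...],
    survey_matches [[question_id, answer]...]."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PhenotypeCriteria(
        condition_codes=frozenset(
            (str(s), str(c)) for s, c in raw.get("condition_codes", [])
        ),
        survey_matches=frozenset(
            (str(q), str(a)) for q, a in raw.get("survey_matches", [])
        ),
    )


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise StageError(name, exc) from exc
        return deco

    @stage("load")
    def loaded():
        panel = load_panel(config.panel,
                           strand_aware=config.strand_aware_padding)
        vip = load_vip(config.kb)
        if config.kb_source == "clinvar":
            if config.clinvar is None:
                raise ValueError("kb_source=clinvar requires a clinvar path")
            kb = filter_clinvar_plp(load_clinvar(config.clinvar))
        elif config.kb_source == "vip":
            kb = {k: v for k, v in vip.items() if v.is_plp}
        else:
            raise ValueError(f"unknown kb_source {config.kb_source!r}")
        labels_df = pd.read_csv(config.ancestry, sep="\t", dtype=str)
        labels = dict(zip(labels_df["participant_id"], labels_df["ancestry"]))
        return panel, kb, labels

    panel, kb, labels = loaded

    @stage("classify")
    def classified():
        findings, calls = classify_cohort(
            config.vcf, panel, plp_keys(kb) if hasattr(kb, "items") else kb,
            gq_threshold=config.gq_threshold,
            af_threshold=config.plof_af_threshold,
            return_calls=True,
        )
        df = pd.DataFrame(
            [{"participant_id": f.participant_id, "gene": f.gene,
              "key": str(f.key), "category": f.category.value}
             for f in findings]
        )
        path = outdir / "findings.tsv"
        _write_tsv(df, path, [
            "qualifying findings per participant and gene",
            "category: known_plp | plof_novel | plof_known_overlap",
        ])
        outputs["findings"] = str(path)
        return findings, calls

    findings, calls = classified

    @stage("burden")
    def burden():
        table = count_cohort(findings, labels, panel,
                             mode=config.counting_mode)
        wide = table.counts.copy()
        wide.loc["__denominator__"] = table.denominators
        wide.insert(0, "gene", wide.index)
        path = outdir / "burden.tsv"
        _write_tsv(wide, path, [
            f"gene x ancestry counts; counting mode = {table.mode}",
            "row __denominator__ holds per-group participant totals",
        ])
        outputs["burden"] = str(path)
        rates = group_rate_table(table, level=config.ci_level)
        rpath = outdir / "rates.tsv"
        _write_tsv(rates, rpath, [
            "overall positive rate per ancestry group with confidence interval",
        ])
        outputs["rates"] = str(rpath)
        return table

    table = burden

    @stage("stats")
    def stats_stage():
        report: dict = {"alpha": config.alpha}
        try:
            collapsed = aggregate_for_chisq(table)
            chisq = chisq_independence(collapsed)
            report["chi_square"] = {
                "statistic": chisq.statistic, "df": chisq.df,
                "p_value": chisq.p_value,
                "table_rows": list(map(str, collapsed.index)),
                "table_cols": list(map(str, collapsed.columns)),
            }
        except Exception as exc:
            report["chi_square"] = {"error": str(exc)}
        scan = gene_outlier_scan(table,
                                 reference_group=config.reference_group,
                                 alpha=config.alpha)
        report["outlier_scan"] = {
            "reference_group": scan.reference_group,
            "m": scan.m,
            "alpha_adjusted": scan.alpha_adjusted,
            "comparisons": [
                {"gene": c.gene, "group": c.group, "z": c.result.z,
                 "p_value": c.result.p_value, "significant": c.significant}
                for c in scan.comparisons
            ],
            "skipped": [list(s) for s in scan.skipped],
        }
        path = outdir / "stats.json"
        path.write_text(json.dumps(report, indent=2))
        outputs["stats"] = str(path)
        return report

    stats_stage

    if config.freq is not None:
        @stage("compare")
        def compare():
            freq = load_frequencies(config.freq)
            joined = join_frequencies({k: v for k, v in kb.items()},
                                      freq, config.compare_population,
                                      config.compare_subset)
            ref_rates = {}
            for gene in panel.genes:
                rec = gene_level_rate(joined, gene, config.compare_population,
                                      config.compare_subset)
                if not rec.empty_gene and not rec.undefined:
                    ref_rates[gene] = rec.rate
            cohort = cohort_allele_rates(calls, plp_keys(kb), panel,
                                         n_participants=len(labels))
            df = compare_gene_rates(cohort, ref_rates)
            path = outdir / "compare.tsv"
            _write_tsv(df, path, [
                "per-gene P/LP allele rates: cohort vs reference "
                f"({config.compare_population}/{config.compare_subset})",
                "cohort rate denominator = 2N chromosomes (allele mode)",
            ])
            outputs["compare"] = str(path)
            summary: dict = {"population": config.compare_population,
                             "subset": config.compare_subset,
                             "n_genes": int(len(df))}
            try:
                corr = rate_correlation(cohort, ref_rates)
                summary["pearson_r"] = corr.r
                summary["n_shared_genes"] = corr.n
            except Exception as exc:
                summary["pearson_r_error"] = str(exc)
            spath = outdir / "compare.json"
            spath.write_text(json.dumps(summary, indent=2))
            outputs["compare_summary"] = str(spath)

        compare

    if config.criteria is not None and config.ehr is not None:
        @stage("enrich")
        def enrich():
            criteria = load_criteria(config.criteria)
            ehr = pd.read_csv(config.ehr, sep="\t", dtype=str)
            survey = (pd.read_csv(config.survey, sep="\t", dtype=str)
                      if config.survey is not None
                      else pd.DataFrame(columns=["participant_id",
                                                 "question_id", "answer"]))
            selection = select_cohort(labels.keys(), ehr, survey, criteria)
            positives = {f.participant_id for f in findings}
            result = phenotype_enrichment(selection, positives, labels.keys(),
                                          background=config.background_mode)
            path = outdir / "enrich.json"
            path.write_text(json.dumps({
                "n_selected": selection.n_selected,
                "n_genotyped": selection.n_genotyped,
                "cohort_positive": result.cohort_positive,
                "cohort_n": result.cohort_n,
                "background_positive": result.background_positive,
                "background_n": result.background_n,
                "cohort_rate": result.cohort_rate,
                "background_rate": result.background_rate,
                "z": result.test.z,
                "p_value": result.test.p_value,
                "background_mode": config.background_mode,
            }, indent=2))
            outputs["enrich"] = str(path)

        enrich

    inputs = {
        name: {"path": str(getattr(config, name)),
               "sha256": _sha256(getattr(config, name))}
        for name in ("vcf", "panel", "kb", "ancestry", "clinvar", "freq",
                     "ehr", "survey", "criteria")
        if getattr(config, name) is not None
    }
    manifest = {
        "tool": "ancestry-burden",
        "version": __version__,
        "config": config.echo(),
        "inputs": inputs,
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
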