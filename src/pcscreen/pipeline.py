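"""Staged carrier-screening workflow over files in an output directory.

Each stage reads the previous stage's TSV outputs from ``out_dir`` and
writes its own, so partial runs reuse upstream results. A run manifest
(JSON) records the configuration digest, seed, stage timings, input/output
digests and package version; identical inputs reproduce identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

import pcscreen
from pcscreen import io as pio
from pcscreen.cohort import CohortComposition, compute_carrier_rate, carrier_burden_summary
from pcscreen.couples import Couple, assess_couple, couple_cohort_summary, exome_wide_couple_scan
from pcscreen.curation import GeneConditionPair, curate_panel
from pcscreen.risk import (
    FdrEstimate,
    aggregate_fdr,
    contribution_breakdown,
    default_expansion_table,
    fdr_autosomal_recessive,
    fdr_x_linked,
    fdr_fmr1_expansion,
)
from pcscreen.secondary import load_acmg_sf_list, screen_secondary_findings
from pcscreen.simulate import (
    SimulationConfig,
    default_config,
    simulate_couples,
    simulate_population,
)
from pcscreen.variants import apply_filters

log = logging.getLogger("pcscreen")

__all__ = ["PipelineSettings", "load_settings", "run_stage", "STAGES"]

ONSET_LABELS = {"childhood", "adult/late"}


@dataclass
class PipelineSettings:
    """All tunables of the workflow, with the study defaults."""

    seed: int = 1
    n_individuals: int = 14125
    n_couples: int = 776
    min_depth: float = 10.0
    min_quality: float = 20.0
    min_het_ratio: float = 0.35
    max_maf: float = 0.01
    fdr_threshold: float = 1e-6
    sf_ad_maf_max: float = 0.005
    fmr1_premutation_min: int = 55
    min_severity: int = 2

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_settings(path: str | Path | None) -> PipelineSettings:
    settings = PipelineSettings()
    if path is None:
        return settings
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    thresholds = raw.pop("thresholds", {})
    for key, value in {**raw, **thresholds}.items():
        if not hasattr(settings, key):
            raise ValueError(f"unknown config key {key!r}")
        setattr(settings, key, type(getattr(settings, key))(value))
    return settings


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


# ---------------------------------------------------------------- stages


def stage_simulate(settings: PipelineSettings, out: Path) -> list[Path]:
    cfg = default_config(seed=settings.seed, n_individuals=settings.n_individuals)
    pop = simulate_population(cfg)
    couples = simulate_couples(pop, settings.n_couples, seed=settings.seed + 1)
    pop.individuals.to_csv(out / "individuals.tsv", sep="\t", index=False)
    pio.write_calls_tsv(pop.calls, out / "calls.tsv")
    pd.DataFrame(
        {
            "individual_id": list(pop.fmr1_alleles),
            "allele1": [a for a, _ in pop.fmr1_alleles.values()],
            "allele2": [b for _, b in pop.fmr1_alleles.values()],
        }
    ).to_csv(out / "fmr1_alleles.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, i) for g, ids in sorted(pop.truth.items()) for i in sorted(ids)],
        columns=["gene", "individual_id"],
    ).to_csv(out / "truth_carriers.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "couple_id": [f"CPL{i:04d}" for i in range(len(couples))],
            "female_id": [c.female_id for c in couples],
            "male_id": [c.male_id for c in couples],
        }
    ).to_csv(out / "couples.tsv", sep="\t", index=False)
    log.info("simulated %d individuals, %d calls, %d couples",
             settings.n_individuals, len(pop.calls), len(couples))
    return [out / n for n in (
        "individuals.tsv", "calls.tsv", "fmr1_alleles.tsv",
        "truth_carriers.tsv", "couples.tsv")]


def stage_filter(settings: PipelineSettings, out: Path) -> list[Path]:
    calls = pio.read_calls_tsv(out / "calls.tsv")
    retained, decisions = apply_filters(
        calls,
        min_depth=settings.min_depth,
        min_quality=settings.min_quality,
        min_het_ratio=settings.min_het_ratio,
        max_maf=settings.max_maf,
    )
    pio.write_calls_tsv(retained, out / "retained_calls.tsv")
    pio.write_filter_audit(decisions, out / "filter_audit.tsv")
    tally = pd.Series([d.reason for d in decisions]).value_counts()
    for reason, n in tally.items():
        log.info("filter step %-22s %d calls", reason, n)
    log.info("retained %d of %d calls", len(retained), len(calls))
    return [out / "retained_calls.tsv", out / "filter_audit.tsv"]


def _load_cohort(out: Path):
    individuals = pd.read_csv(out / "individuals.tsv", sep="\t")
    comp = CohortComposition(
        n_female_patient=int(((individuals.sex == "female") & (individuals.group == "patient")).sum()),
        n_female_donor=int(((individuals.sex == "female") & (individuals.group == "donor")).sum()),
        n_male_patient=int(((individuals.sex == "male") & (individuals.group == "patient")).sum()),
        n_male_donor=int(((individuals.sex == "male") & (individuals.group == "donor")).sum()),
    )
    sex_lookup = dict(zip(individuals.individual_id, individuals.sex))
    group_lookup = dict(zip(individuals.individual_id, individuals.group))
    return individuals, comp, sex_lookup, group_lookup


def _gene_table(settings: PipelineSettings) -> pd.DataFrame:
    from pcscreen.simulate import load_default_panel

    return load_default_panel()


def _carrier_sets(out: Path) -> dict[str, set[str]]:
    retained = pd.read_csv(out / "retained_calls.tsv", sep="\t")
    return {
        gene: set(sub.individual_id.astype(str))
        for gene, sub in retained.groupby("gene")
    }


def stage_carrier_rates(settings: PipelineSettings, out: Path) -> list[Path]:
    genes = _gene_table(settings)
    _, comp, sex_lookup, _ = _load_cohort(out)
    carrier_sets = _carrier_sets(out)
    fmr1 = pd.read_csv(out / "fmr1_alleles.tsv", sep="\t")
    fmr1_carriers = set(
        fmr1.loc[
            (fmr1[["allele1", "allele2"]].max(axis=1) >= settings.fmr1_premutation_min)
            & (fmr1[["allele1", "allele2"]].max(axis=1) < 200),
            "individual_id",
        ].astype(str)
    )
    stats = []
    for r in genes.itertuples():
        carriers = fmr1_carriers if r.gene == "FMR1" else carrier_sets.get(r.gene, set())
        inheritance = "XL" if r.inheritance == "XLR" else "AR"
        stats.append(
            compute_carrier_rate(carriers, comp, inheritance, sex_lookup, gene=r.gene)
        )
    pio.write_carrier_rates(stats, out / "carrier_rates.tsv")

    # carrier burden over panel conditions
    retained = pd.read_csv(out / "retained_calls.tsv", sep="\t")
    panel_genes = set(genes.loc[genes.in_panel, "gene"])
    per_ind = retained[retained.gene.isin(panel_genes)].groupby("individual_id").size()
    counts = {i: 0 for i in sex_lookup}
    counts.update(per_ind.to_dict())
    burden = carrier_burden_summary(counts)
    pd.DataFrame(
        {"n_variants": list(burden.histogram), "n_individuals": list(burden.histogram.values())}
    ).to_csv(out / "burden_histogram.tsv", sep="\t", index=False)
    log.info(
        "carrier burden: mean %.3f per individual, %.1f%% positive",
        burden.mean_per_individual, 100 * burden.positive_fraction,
    )
    return [out / "carrier_rates.tsv", out / "burden_histogram.tsv"]


def _fdr_estimates(settings: PipelineSettings, out: Path) -> list[FdrEstimate]:
    genes = _gene_table(settings)
    rates = pd.read_csv(out / "carrier_rates.tsv", sep="\t").set_index("gene")
    _, comp, _, _ = _load_cohort(out)
    table = default_expansion_table()
    fmr1 = pd.read_csv(out / "fmr1_alleles.tsv", sep="\t")
    estimates = []
    for r in genes.itertuples():
        cr = float(rates.loc[r.gene, "rate"])
        if r.gene == "FMR1":
            sizes = fmr1[["allele1", "allele2"]].max(axis=1)
            freqs = {}
            for lo, hi, _p in table.bins:
                n = int(((sizes >= lo) & (sizes <= hi)).sum())
                if n:
                    freqs[(lo, hi)] = n / comp.n_female
            fdr = fdr_fmr1_expansion(freqs, table)
            model = "FMR1"
        elif r.inheritance == "XLR":
            fdr = fdr_x_linked(cr)
            model = "XL"
        else:
            fdr = fdr_autosomal_recessive(cr, cr)
            model = "AR"
        estimates.append(
            FdrEstimate(
                gene=r.gene,
                condition=r.condition,
                model=model,
                fdr=fdr,
                severity=int(r.severity),
                carrier_rate=cr,
            )
        )
    return estimates


def stage_fdr(settings: PipelineSettings, out: Path) -> list[Path]:
    estimates = _fdr_estimates(settings, out)
    genes = _gene_table(settings)
    panel_genes = set(genes.loc[genes.in_panel, "gene"])
    panel_estimates = [e for e in estimates if e.gene in panel_genes]
    agg = aggregate_fdr(panel_estimates, min_severity=settings.min_severity)
    if agg.fdr > 0:
        report = contribution_breakdown(
            [e for e in panel_estimates if e.severity >= settings.min_severity]
        )
        with_pct = [
            FdrEstimate(
                gene=e.gene, condition=e.condition, model=e.model, fdr=e.fdr,
                severity=e.severity, carrier_rate=e.carrier_rate,
                contribution_pct=report.per_gene_pct.get(e.gene),
            )
            for e in estimates
        ]
        log.info("aggregate FDR (severity >= %d): %.3e (%s); X-linked share %.1f%%",
                 settings.min_severity, agg.fdr, agg.display, report.x_linked_pct)
    else:
        with_pct = estimates
    rates = pd.read_csv(out / "carrier_rates.tsv", sep="\t")
    displays = dict(zip(rates.gene, rates.display))
    pio.write_fdr_report(with_pct, out / "fdr_report.tsv", carrier_displays=displays)
    return [out / "fdr_report.tsv"]


def _panel_pairs(settings: PipelineSettings, out: Path):
    genes = _gene_table(settings)
    fdr_report = pd.read_csv(out / "fdr_report.tsv", sep="\t").set_index("gene")
    pairs = []
    for r in genes.itertuples():
        pair = GeneConditionPair(
            gene=r.gene,
            condition=r.condition,
            inheritance=r.inheritance,
            severity=int(r.severity),
            onset=r.onset,
            penetrance=r.penetrance,
            evidence=r.evidence,
            mim_phenotype=r.mim_phenotype if isinstance(r.mim_phenotype, str) else None,
            mim_gene=r.mim_gene if isinstance(r.mim_gene, str) else None,
        )
        pairs.append((pair, float(fdr_report.loc[r.gene, "fdr"])))
    return pairs


def stage_curate_panel(settings: PipelineSettings, out: Path) -> list[Path]:
    pairs = _panel_pairs(settings, out)
    panel, ledger = curate_panel(pairs, fdr_threshold=settings.fdr_threshold)
    pio.write_curation_ledger(ledger, out / "panel_ledger.tsv")
    log.info("curated panel: %d of %d pairs retained", len(panel), len(pairs))
    return [out / "panel_ledger.tsv"]


def _genotype_map(out: Path) -> dict[str, list]:
    retained = pio.read_calls_tsv(out / "retained_calls.tsv")
    genotypes: dict[str, list] = {}
    for c in retained:
        genotypes.setdefault(c.individual_id, []).append(c)
    individuals = pd.read_csv(out / "individuals.tsv", sep="\t")
    for i in individuals.individual_id.astype(str):
        genotypes.setdefault(i, [])
    return genotypes


def stage_couples(settings: PipelineSettings, out: Path) -> list[Path]:
    ledger = pd.read_csv(out / "panel_ledger.tsv", sep="\t")
    genes = _gene_table(settings)
    meta = genes.set_index("gene")
    panel = []
    for r in ledger[ledger.retained].itertuples():
        g = meta.loc[r.gene]
        panel.append(
            GeneConditionPair(
                gene=r.gene, condition=r.condition, inheritance=r.inheritance,
                severity=int(r.severity), onset=str(g.onset),
                penetrance=str(g.penetrance), evidence=str(g.evidence),
            )
        )
    genotypes = _genotype_map(out)
    fmr1 = pd.read_csv(out / "fmr1_alleles.tsv", sep="\t")
    fmr1_alleles = {
        str(r.individual_id): (int(r.allele1), int(r.allele2)) for r in fmr1.itertuples()
    }
    couples_df = pio.read_couples_tsv(out / "couples.tsv")
    gene_inh = dict(zip(genes.gene, genes.inheritance))
    rows = []
    findings_by_couple = {}
    for r in couples_df.itertuples():
        couple = Couple(female_id=r.female_id, male_id=r.male_id)
        findings = assess_couple(
            couple, panel, genotypes, fmr1_alleles,
            fmr1_premutation_min=settings.fmr1_premutation_min,
        )
        findings += exome_wide_couple_scan(couple, genotypes, panel, gene_inh)
        findings_by_couple[couple] = findings
        for f in findings:
            rows.append(
                {
                    "couple_id": r.couple_id,
                    "gene": f.gene,
                    "category": f.category,
                    "female_variants": ";".join(f.female_variants),
                    "male_variants": ";".join(f.male_variants),
                }
            )
    pd.DataFrame(
        rows, columns=["couple_id", "gene", "category", "female_variants", "male_variants"]
    ).to_csv(out / "couple_report.tsv", sep="\t", index=False)
    summary = couple_cohort_summary(
        {c: [f for f in fl if f.category != "exome_wide_rare"]
         for c, fl in findings_by_couple.items()},
        n_couples=len(couples_df),
    )
    pd.DataFrame(
        [
            {
                "n_couples": summary.n_couples,
                "n_at_risk": summary.n_at_risk,
                "pct": summary.proportion.point_pct,
                "ci_lower_pct": summary.proportion.lower_pct,
                "ci_upper_pct": summary.proportion.upper_pct,
                **{f"n_{k}": v for k, v in summary.category_counts.items()},
            }
        ]
    ).to_csv(out / "couple_summary.tsv", sep="\t", index=False)
    log.info("couples at increased risk: %d/%d (%.1f%%; 95%% CI %.1f-%.1f)",
             summary.n_at_risk, summary.n_couples, summary.proportion.point_pct,
             summary.proportion.lower_pct, summary.proportion.upper_pct)
    return [out / "couple_report.tsv", out / "couple_summary.tsv"]


def stage_secondary_findings(settings: PipelineSettings, out: Path) -> list[Path]:
    _, comp, sex_lookup, group_lookup = _load_cohort(out)
    retained = pio.read_calls_tsv(out / "retained_calls.tsv")
    sf_list = load_acmg_sf_list()
    result = screen_secondary_findings(
        retained, sf_list, comp, sex_lookup, group_lookup,
        ad_maf_max=settings.sf_ad_maf_max,
    )
    pd.DataFrame(
        [
            {
                "gene": row.gene,
                "inheritance": row.inheritance,
                "CR": row.display_cr,
                "patient_female": row.counts["patient_female"],
                "donor_female": row.counts["donor_female"],
                "patient_male": row.counts["patient_male"],
                "donor_male": row.counts["donor_male"],
            }
            for row in result.rows
        ]
    ).to_csv(out / "sf_report.tsv", sep="\t", index=False)
    sf_genes = {e.gene for e in sf_list}
    pd.DataFrame(
        [
            {
                "variant_key": c.variant_key,
                "gene": c.gene,
                "classification": c.sf_classification or c.classification,
            }
            for c in retained
            if c.gene in sf_genes
        ]
    ).to_csv(out / "sf_variants.tsv", sep="\t", index=False)
    log.info("secondary findings: %d positives (%.2f%%), %d with >1 variant",
             len(result.positives), 100 * len(result.positives) / comp.n_total,
             len(result.multi_positive))
    return [out / "sf_report.tsv", out / "sf_variants.tsv"]


STAGES = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "carrier-rates": stage_carrier_rates,
    "fdr": stage_fdr,
    "curate-panel": stage_curate_panel,
    "couples": stage_couples,
    "secondary-findings": stage_secondary_findings,
}

STAGE_ORDER = list(STAGES)


def run_stage(
    subcommand: str, settings: PipelineSettings, out_dir: str | Path
) -> dict:
    """Run one stage (or ``report-all``) and append to the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = STAGE_ORDER if subcommand == "report-all" else [subcommand]
    if any(n not in STAGES for n in names):
        raise ValueError(f"unknown subcommand {subcommand!r}")
    manifest = {
        "package_version": pcscreen.__version__,
        "config_digest": settings.digest(),
        "seed": settings.seed,
        "stages": [],
        "outputs": {},
    }
    for name in names:
        t0 = time.perf_counter()
        outputs = STAGES[name](settings, out)
        elapsed = time.perf_counter() - t0
        manifest["stages"].append({"stage": name, "seconds": round(elapsed, 3)})
        for p in outputs:
            manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
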