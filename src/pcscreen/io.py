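"""Readers and writers for the pipeline's tabular and VCF interfaces.

Variant calls enter either as VCF 4.2 (clinical classification and
population frequency read from configurable INFO keys) or as a flat TSV
with one call per row. All reports leave as TSV.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from pcscreen.cohort import CarrierStat
from pcscreen.curation import CurationLedgerEntry, GeneConditionPair
from pcscreen.risk import ExpansionTable, FdrEstimate
from pcscreen.variants import FilterDecision, VariantCall, decisions_to_frame

__all__ = [
    "read_calls_vcf",
    "read_calls_tsv",
    "write_calls_tsv",
    "read_expansion_table",
    "read_panel_tsv",
    "read_couples_tsv",
    "write_filter_audit",
    "write_carrier_rates",
    "write_curation_ledger",
    "write_fdr_report",
]

CALL_COLUMNS = [
    "individual_id",
    "gene",
    "variant_key",
    "zygosity",
    "depth",
    "base_quality",
    "het_allele_ratio",
    "classification",
    "population_maf",
]


def read_calls_tsv(path: str | Path) -> list[VariantCall]:
    """Read per-individual variant calls from the flat TSV dialect.

    Missing depth/base_quality/het_allele_ratio mark separate-test records
    that bypass quality filtering. An optional ``sf_classification`` column
    carries the independent secondary-findings classification.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"call table missing columns: {missing}")
    calls = []
    has_sf = "sf_classification" in df.columns
    for row in df.itertuples():
        calls.append(
            VariantCall(
                individual_id=str(row.individual_id),
                gene=str(row.gene),
                variant_key=str(row.variant_key),
                zygosity=str(row.zygosity),
                depth=_opt_float(row.depth),
                base_quality=_opt_float(row.base_quality),
                het_allele_ratio=_opt_float(row.het_allele_ratio),
                classification=str(row.classification),
                population_maf=float(row.population_maf),
                sf_classification=(
                    str(row.sf_classification)
                    if has_sf and not _is_na(row.sf_classification)
                    else None
                ),
            )
        )
    return calls


def _is_na(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def _opt_float(v) -> float | None:
    return None if _is_na(v) else float(v)


def write_calls_tsv(calls: Sequence[VariantCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "individual_id": c.individual_id,
                "gene": c.gene,
                "variant_key": c.variant_key,
                "zygosity": c.zygosity,
                "depth": c.depth,
                "base_quality": c.base_quality,
                "het_allele_ratio": c.het_allele_ratio,
                "classification": c.classification,
                "population_maf": c.population_maf,
                "sf_classification": c.sf_classification,
            }
        )
    pd.DataFrame(rows, columns=CALL_COLUMNS + ["sf_classification"]).to_csv(
        path, sep="\t", index=False
    )


# ClinVar-style CLNSIG strings mapped onto the five-level scale
_CLNSIG_MAP = {
    "pathogenic": "P",
    "likely_pathogenic": "LP",
    "pathogenic/likely_pathogenic": "LP",
    "uncertain_significance": "VUS",
    "likely_benign": "LB",
    "benign": "B",
    "benign/likely_benign": "LB",
}


def read_calls_vcf(
    path: str | Path,
    sex_lookup: Mapping[str, str] | None = None,
    classification_key: str = "CLNSIG",
    maf_key: str = "AF_popmax",
    gene_key: str = "GENE",
) -> list[VariantCall]:
    """Read a multi-sample VCF 4.2 into per-individual calls.

    Classification and population MAF come from the configured INFO keys;
    multiallelic records are split into one call per alternate allele.
    Zygosity follows the genotype; a single-allele (haploid) genotype, or a
    homozygous-alt genotype on X in a male when ``sex_lookup`` is supplied,
    is recorded hemizygous. Heterozygous allele ratio is taken from the AD
    FORMAT field when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    calls: list[VariantCall] = []
    for rec in vcf:
        clnsig = rec.INFO.get(classification_key)
        classification = _map_clnsig(clnsig)
        maf = rec.INFO.get(maf_key)
        gene = rec.INFO.get(gene_key) or ""
        on_x = rec.CHROM.removeprefix("chr") == "X"
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            key = f"{rec.CHROM}:{rec.POS}:{rec.REF}>{alt}"
            genotypes = rec.genotypes  # [allele1, allele2, phased] (or haploid)
            depths = rec.format("DP")
            ads = rec.format("AD")
            for si, gt in enumerate(genotypes):
                alleles = [a for a in gt[:-1] if a >= 0]
                n_alt = sum(1 for a in alleles if a == alt_idx)
                if n_alt == 0:
                    continue
                sample = samples[si]
                male = sex_lookup is not None and sex_lookup.get(sample) == "male"
                if len(alleles) == 1 or (on_x and male and n_alt == len(alleles)):
                    zygosity = "hemizygous"
                elif n_alt == len(alleles):
                    zygosity = "homozygous"
                else:
                    zygosity = "heterozygous"
                depth = float(depths[si][0]) if depths is not None else None
                ratio = None
                if ads is not None and len(ads[si]) > alt_idx:
                    total = float(sum(x for x in ads[si] if x >= 0))
                    if total > 0:
                        ratio = float(ads[si][alt_idx]) / total
                calls.append(
                    VariantCall(
                        individual_id=sample,
                        gene=str(gene),
                        variant_key=key,
                        zygosity=zygosity,
                        depth=depth,
                        base_quality=float(rec.QUAL) if rec.QUAL is not None else None,
                        het_allele_ratio=ratio,
                        classification=classification,
                        population_maf=float(maf) if maf is not None else 0.0,
                    )
                )
    return calls


def _map_clnsig(value) -> str:
    if value is None:
        return "VUS"
    text = str(value).strip().lower().replace(" ", "_")
    return _CLNSIG_MAP.get(text, "VUS")


def read_expansion_table(path: str | Path) -> ExpansionTable:
    """Read a (cgg_lower, cgg_upper, expansion_prob) TSV."""
    df = pd.read_csv(path, sep="\t")
    bins = tuple(
        (int(r.cgg_lower), int(r.cgg_upper), float(r.expansion_prob))
        for r in df.itertuples()
    )
    return ExpansionTable(bins=bins)


def read_panel_tsv(path: str | Path) -> list[GeneConditionPair]:
    """Read gene-condition metadata (the curation input / S2-style layout)."""
    df = pd.read_csv(path, sep="\t", dtype={"mim_phenotype": str, "mim_gene": str})
    pairs = []
    for r in df.itertuples():
        pairs.append(
            GeneConditionPair(
                gene=str(r.gene),
                condition=str(r.condition),
                inheritance=str(r.inheritance),
                severity=int(r.severity),
                onset=str(r.onset),
                penetrance=str(r.penetrance),
                evidence=str(r.evidence),
                mim_phenotype=getattr(r, "mim_phenotype", None),
                mim_gene=getattr(r, "mim_gene", None),
            )
        )
    return pairs


def read_couples_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("couple_id", "female_id", "male_id"):
        if col not in df.columns:
            raise ValueError(f"couples table missing column {col!r}")
    return df


def write_filter_audit(decisions: Sequence[FilterDecision], path: str | Path) -> None:
    decisions_to_frame(decisions).to_csv(path, sep="\t", index=False)


def write_carrier_rates(stats: Sequence[CarrierStat], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene": [s.gene for s in stats],
            "inheritance": [s.inheritance for s in stats],
            "carriers": [s.n_carriers for s in stats],
            "denominator": [s.denominator for s in stats],
            "rate": [s.rate for s in stats],
            "display": [s.display for s in stats],
        }
    ).to_csv(path, sep="\t", index=False)


def write_curation_ledger(
    ledger: Sequence[CurationLedgerEntry], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "gene": [e.pair.gene for e in ledger],
            "condition": [e.pair.condition for e in ledger],
            "inheritance": [e.pair.inheritance for e in ledger],
            "severity": [e.pair.severity for e in ledger],
            "fdr": [e.fdr for e in ledger],
            "step": [e.step for e in ledger],
            "retained": [e.retained for e in ledger],
            "all_failed_steps": [";".join(e.failed_steps) for e in ledger],
        }
    ).to_csv(path, sep="\t", index=False)


def write_fdr_report(
    estimates: Sequence[FdrEstimate],
    path: str | Path,
    carrier_displays: Mapping[str, str] | None = None,
) -> None:
    carrier_displays = carrier_displays or {}
    pd.DataFrame(
        {
            "gene": [e.gene for e in estimates],
            "condition": [e.condition for e in estimates],
            "model": [e.model for e in estimates],
            "severity": [e.severity for e in estimates],
            "carrier_rate_display": [
                carrier_displays.get(e.gene, "") for e in estimates
            ],
            "fdr": [e.fdr for e in estimates],
            "contribution_pct": [e.contribution_pct for e in estimates],
        }
    ).to_csv(path, sep="\t", index=False)
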