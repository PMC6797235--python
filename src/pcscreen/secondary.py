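"""Medically actionable secondary findings (ACMG SF v2.0).

Retained variants are screened against the 59-gene ACMG SF v2.0 list.
Classification may come from an independent source than the carrier screen
(``VariantCall.sf_classification`` takes precedence when set). A
frequency-demotion rule treats P/LP variants in autosomal-dominant SF genes
as benign when population MAF > 0.005 — too common to be highly penetrant
for a rare dominant disorder. X-linked SF genes count female carriers over
the female denominator; the biallelic-recessive entries (ATP7B, MUTYH) are
additionally screened for homozygotes and potential compound heterozygotes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

from pcscreen.cohort import CohortComposition, display_denominator
from pcscreen.variants import VariantCall

__all__ = [
    "SfGeneEntry",
    "SfReportRow",
    "SfScreenResult",
    "BiallelicFinding",
    "load_acmg_sf_list",
    "screen_secondary_findings",
    "biallelic_recessive_sf_check",
]

SUBGROUPS = ("patient_female", "donor_female", "patient_male", "donor_male")


@dataclass(frozen=True)
class SfGeneEntry:
    """One gene on the medically-actionable secondary-findings list."""

    gene: str
    phenotype: str
    mim_disorder: str
    mim_gene: str
    inheritance: str  # AD | XL | AR
    typical_onset: str = ""

    def __post_init__(self) -> None:
        if self.inheritance not in ("AD", "XL", "AR"):
            raise ValueError(f"unknown SF inheritance {self.inheritance!r}")


@dataclass(frozen=True)
class SfReportRow:
    """Per-gene secondary-findings carrier counts by cohort subgroup."""

    gene: str
    inheritance: str
    counts: dict[str, int]  # keyed by SUBGROUPS
    n_carriers: int
    display_cr: str


@dataclass(frozen=True)
class SfScreenResult:
    rows: list[SfReportRow]
    positives: set[str]
    multi_positive: set[str]
    n_unique_variants: int
    n_occurrences: int
    warnings: list[str]


@dataclass(frozen=True)
class BiallelicFinding:
    individual_id: str
    gene: str
    variant_keys: tuple[str, ...]
    kind: str  # "homozygous" | "potential_compound_het"


def load_acmg_sf_list() -> list[SfGeneEntry]:
    """The shipped ACMG SF v2.0 59-gene list."""
    import pandas as pd

    with resources.as_file(
        resources.files("pcscreen.data") / "acmg_sf_v2.tsv"
    ) as path:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = [
        SfGeneEntry(
            gene=r.gene,
            phenotype=r.phenotype,
            mim_disorder=r.mim_disorder,
            mim_gene=r.mim_gene,
            inheritance=r.inheritance,
            typical_onset=r.typical_onset,
        )
        for r in df.itertuples()
    ]
    if len({e.gene for e in entries}) != len(entries):
        raise ValueError("duplicate genes in SF list")
    return entries


def _sf_class(call: VariantCall) -> str:
    return call.sf_classification if call.sf_classification is not None else call.classification


def screen_secondary_findings(
    calls: Sequence[VariantCall],
    sf_list: Sequence[SfGeneEntry],
    composition: CohortComposition,
    sex_lookup: Mapping[str, str],
    group_lookup: Mapping[str, str],
    ad_maf_max: float = 0.005,
    annotated_genes: Iterable[str] | None = None,
) -> SfScreenResult:
    """Tabulate secondary-findings carriers per SF gene and cohort subgroup.

    ``group_lookup`` maps individual id -> {"patient", "donor"}. An
    individual with several surviving variants in one gene contributes once
    to that gene's count; ``positives`` / ``multi_positive`` hold ids with
    >=1 / >=2 surviving SF variants anywhere on the list.
    """
    sf_by_gene = {e.gene: e for e in sf_list}
    warnings = []
    if annotated_genes is not None:
        universe = set(annotated_genes)
        for e in sf_list:
            if e.gene not in universe:
                warnings.append(f"SF gene {e.gene} absent from annotation universe")

    surviving: list[VariantCall] = []
    for call in calls:
        entry = sf_by_gene.get(call.gene)
        if entry is None:
            continue
        if _sf_class(call) not in ("P", "LP"):
            continue
        if entry.inheritance == "AD" and call.population_maf > ad_maf_max:
            continue  # demoted: too common to be a penetrant dominant allele
        if entry.inheritance == "XL" and sex_lookup.get(call.individual_id) != "female":
            continue  # XL SF carriers are counted among females
        surviving.append(call)

    per_individual: dict[str, set[str]] = {}
    per_gene_carriers: dict[str, set[str]] = {e.gene: set() for e in sf_list}
    for call in surviving:
        per_individual.setdefault(call.individual_id, set()).add(call.variant_key)
        per_gene_carriers[call.gene].add(call.individual_id)

    rows = []
    for entry in sf_list:
        carriers = per_gene_carriers[entry.gene]
        if not carriers:
            continue
        counts = {k: 0 for k in SUBGROUPS}
        for ind in carriers:
            key = f"{group_lookup[ind]}_{sex_lookup[ind]}"
            counts[key] += 1
        denominator = (
            composition.n_female if entry.inheritance == "XL" else composition.n_total
        )
        rows.append(
            SfReportRow(
                gene=entry.gene,
                inheritance=entry.inheritance,
                counts=counts,
                n_carriers=len(carriers),
                display_cr=f"1/{display_denominator(denominator, len(carriers))}",
            )
        )
    rows.sort(key=lambda r: r.gene)
    positives = set(per_individual)
    multi = {i for i, keys in per_individual.items() if len(keys) >= 2}
    return SfScreenResult(
        rows=rows,
        positives=positives,
        multi_positive=multi,
        n_unique_variants=len({v.variant_key for v in surviving}),
        n_occurrences=len(surviving),
        warnings=warnings,
    )


def biallelic_recessive_sf_check(
    calls: Sequence[VariantCall],
    genes: Iterable[str] = ("ATP7B", "MUTYH"),
) -> list[BiallelicFinding]:
    """Homozygotes or potential compound heterozygotes in biallelic SF genes.

    Phase is unavailable, so two distinct heterozygous P/LP variants in the
    same gene are reported as POTENTIAL compound heterozygotes.
    """
    wanted = set(genes)
    per: dict[tuple[str, str], list[VariantCall]] = {}
    for call in calls:
        if call.gene in wanted and _sf_class(call) in ("P", "LP"):
            per.setdefault((call.individual_id, call.gene), []).append(call)
    findings = []
    for (ind, gene), clist in sorted(per.items()):
        hom = [c for c in clist if c.zygosity == "homozygous"]
        distinct = {c.variant_key for c in clist}
        if hom:
            findings.append(
                BiallelicFinding(
                    individual_id=ind,
                    gene=gene,
                    variant_keys=tuple(sorted({c.variant_key for c in hom})),
                    kind="homozygous",
                )
            )
        elif len(distinct) >= 2:
            findings.append(
                BiallelicFinding(
                    individual_id=ind,
                    gene=gene,
                    variant_keys=tuple(sorted(distinct)),
                    kind="potential_compound_het",
                )
            )
    return findings
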