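"""Couple-level reproductive risk assessment.

A couple is flagged at increased risk when

* both partners carry a qualifying P/LP variant in the same autosomal
  recessive panel gene (same variant or potential compound heterozygote —
  both flagged identically),
* the female partner carries a P/LP variant or structural event in an
  X-linked panel gene, or
* any female FMR1 allele lies in the premutation range (55-200 CGG by the
  standard clinical definition; expansion probability is deliberately not
  weighted at the couple level).

The exome-wide couple scan extends the shared-gene rule to recessive genes
outside the curated panel. Its confidentiality contract: carrier status in
an off-panel gene seen in only one partner is never reported — disclosure
requires the couple, as a unit, to be at risk.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from pcscreen.cohort import CohortProportion, proportion_ci
from pcscreen.curation import GeneConditionPair
from pcscreen.variants import VariantCall

__all__ = [
    "Couple",
    "CoupleRiskFinding",
    "parse_fmr1_alleles",
    "assess_couple",
    "exome_wide_couple_scan",
    "couple_cohort_summary",
    "CoupleCohortSummary",
]

CATEGORIES = (
    "AR_shared_gene",
    "XL_female_carrier",
    "FMR1_premutation",
    "exome_wide_rare",
)


@dataclass(frozen=True)
class Couple:
    female_id: str
    male_id: str

    def __post_init__(self) -> None:
        if self.female_id == self.male_id:
            raise ValueError("couple members must be distinct individuals")


@dataclass(frozen=True)
class CoupleRiskFinding:
    """An at-risk call for one couple in one gene."""

    couple: Couple
    gene: str
    category: str
    female_variants: tuple[str, ...] = ()
    male_variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category in ("AR_shared_gene", "exome_wide_rare"):
            if not (self.female_variants and self.male_variants):
                raise ValueError(f"{self.category} requires variants in both partners")


_FMR1_PAIR = re.compile(r"^\s*(\d+)\.(\d+)\*?\s*$")


def parse_fmr1_alleles(text: str) -> tuple[int, int]:
    """Parse a clinical 'NN.MM*' FMR1 genotype string into two allele sizes.

    The two CGG repeat counts are separated by a period (e.g. "32.56*" is a
    32-repeat and a 56-repeat allele). This reading of the report format is
    an interpretation; the parser is isolated here so it can be replaced.
    """
    m = _FMR1_PAIR.match(text)
    if not m:
        raise ValueError(f"cannot parse FMR1 allele string {text!r}")
    return int(m.group(1)), int(m.group(2))


def _calls_by_gene(calls: Iterable[VariantCall]) -> dict[str, list[VariantCall]]:
    out: dict[str, list[VariantCall]] = {}
    for c in calls:
        out.setdefault(c.gene, []).append(c)
    return out


def assess_couple(
    couple: Couple,
    panel: Sequence[GeneConditionPair],
    genotypes: Mapping[str, Sequence[VariantCall]],
    fmr1_alleles: Mapping[str, Sequence[int]] | None = None,
    fmr1_premutation_min: int = 55,
    fmr1_full_mutation_min: int = 200,
) -> list[CoupleRiskFinding]:
    """Panel-based at-risk findings for one couple.

    ``genotypes`` maps individual id -> already-filtered retained calls
    (including separate-test structural events). ``fmr1_alleles`` maps
    female ids to their measured CGG allele sizes.
    """
    for member in (couple.female_id, couple.male_id):
        if member not in genotypes:
            raise KeyError(f"couple member {member!r} missing from genotype set")
    female = _calls_by_gene(genotypes[couple.female_id])
    male = _calls_by_gene(genotypes[couple.male_id])
    findings: list[CoupleRiskFinding] = []
    for pair in panel:
        gene = pair.gene
        if pair.inheritance == "AR":
            if gene in female and gene in male:
                findings.append(
                    CoupleRiskFinding(
                        couple=couple,
                        gene=gene,
                        category="AR_shared_gene",
                        female_variants=tuple(v.variant_key for v in female[gene]),
                        male_variants=tuple(v.variant_key for v in male[gene]),
                    )
                )
        elif pair.inheritance == "XLR":
            if gene == "FMR1":
                continue  # handled via measured allele sizes below
            if gene in female:
                findings.append(
                    CoupleRiskFinding(
                        couple=couple,
                        gene=gene,
                        category="XL_female_carrier",
                        female_variants=tuple(v.variant_key for v in female[gene]),
                    )
                )
    if fmr1_alleles is not None:
        alleles = fmr1_alleles.get(couple.female_id, ())
        premut = tuple(
            a for a in alleles if fmr1_premutation_min <= a < fmr1_full_mutation_min
        )
        if premut:
            findings.append(
                CoupleRiskFinding(
                    couple=couple,
                    gene="FMR1",
                    category="FMR1_premutation",
                    female_variants=tuple(f"CGG{a}" for a in premut),
                )
            )
    findings.sort(key=lambda f: f.gene)
    return findings


def exome_wide_couple_scan(
    couple: Couple,
    genotypes: Mapping[str, Sequence[VariantCall]],
    panel: Sequence[GeneConditionPair],
    gene_inheritance: Mapping[str, str] | None = None,
) -> list[CoupleRiskFinding]:
    """Shared-gene scan over recessive genes outside the curated panel.

    Emits a finding only when BOTH partners carry a retained P/LP variant in
    the same off-panel gene; a variant seen in one partner alone never
    surfaces. ``gene_inheritance`` optionally restricts the scan to genes
    annotated AR/XLR; unannotated genes are treated as candidate recessive.
    """
    for member in (couple.female_id, couple.male_id):
        if member not in genotypes:
            raise KeyError(f"couple member {member!r} missing from genotype set")
    panel_genes = {p.gene for p in panel}
    female = _calls_by_gene(genotypes[couple.female_id])
    male = _calls_by_gene(genotypes[couple.male_id])
    findings = []
    for gene in sorted(set(female) & set(male) - panel_genes):
        if gene_inheritance is not None:
            if gene_inheritance.get(gene) not in ("AR", "XLR"):
                continue
        findings.append(
            CoupleRiskFinding(
                couple=couple,
                gene=gene,
                category="exome_wide_rare",
                female_variants=tuple(v.variant_key for v in female[gene]),
                male_variants=tuple(v.variant_key for v in male[gene]),
            )
        )
    return findings


@dataclass(frozen=True)
class CoupleCohortSummary:
    """Cohort-level couple-risk summary with exact binomial CI."""

    proportion: CohortProportion
    n_at_risk: int
    n_couples: int
    category_counts: dict[str, int]


def couple_cohort_summary(
    findings: Mapping[Couple, Sequence[CoupleRiskFinding]],
    n_couples: int,
    include_fmr1: bool = True,
    level: float = 0.95,
) -> CoupleCohortSummary:
    """Fraction of couples with at least one panel finding, with exact CI.

    A couple counts once however many findings it has. With
    ``include_fmr1`` false, FMR1 premutation findings are dropped before
    counting (couples at risk only through a premutation are excluded).
    """
    if n_couples < 1:
        raise ValueError("n_couples must be >= 1")
    category_counts = {c: 0 for c in CATEGORIES}
    n_at_risk = 0
    for couple, flist in findings.items():
        kept = [
            f
            for f in flist
            if include_fmr1 or f.category != "FMR1_premutation"
        ]
        for f in kept:
            category_counts[f.category] += 1
        if kept:
            n_at_risk += 1
    return CoupleCohortSummary(
        proportion=proportion_ci(n_at_risk, n_couples, level=level),
        n_at_risk=n_at_risk,
        n_couples=n_couples,
        category_counts=category_counts,
    )
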