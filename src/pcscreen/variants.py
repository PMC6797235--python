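"""Per-call quality and pathogenicity filtering of exome variant calls.

The carrier-screening call set is built from annotated single-nucleotide
variant calls in two passes. A quality pass drops calls with inadequate
coverage (<10X), low base quality (<=Q20) or an implausible heterozygous
allele ratio (<=35% alternate-read fraction, heterozygous calls only).
A classification pass then keeps only pathogenic (P) and likely pathogenic
(LP) variants that are rare (population MAF <= 1%) and never observed
homozygous in any unaffected cohort member — a homozygote in a healthy adult
argues against the variant causing a severe childhood-onset recessive
disease. Every input call receives exactly one auditable decision.

Structural and repeat-expansion events from orthogonal assays (SMN1 exon
deletions, F8 Inv22, DMD del/dup, HBA deletion classes, FMR1 CGG sizing)
bypass these filters: they arrive pre-validated and carry no read-level
quality fields.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CLASSIFICATIONS",
    "VariantCall",
    "FilterDecision",
    "GeneCoverageRecord",
    "filter_by_quality",
    "filter_by_classification",
    "flag_low_coverage_genes",
    "build_healthy_homozygote_index",
    "apply_filters",
    "decisions_to_frame",
]

CLASSIFICATIONS = frozenset({"P", "LP", "VUS", "LB", "B"})
ZYGOSITIES = frozenset({"heterozygous", "homozygous", "hemizygous"})

#: Fixed order in which classification-pass failure reasons are assigned.
CLASSIFICATION_REASON_ORDER = ("not_plp", "common_maf", "homozygous_in_healthy")


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one individual.

    ``depth``, ``base_quality`` and ``het_allele_ratio`` may be ``None`` for
    structural / separate-test records, which are exempt from quality
    filtering. ``sf_classification`` carries an optional second, independent
    clinical classification used for secondary-findings screening (the two
    screens may rely on different classification sources).
    """

    individual_id: str
    gene: str
    variant_key: str
    zygosity: str
    classification: str
    population_maf: float = 0.0
    depth: float | None = None
    base_quality: float | None = None
    het_allele_ratio: float | None = None
    sf_classification: str | None = None

    def __post_init__(self) -> None:
        if not self.variant_key:
            raise ValueError("variant_key must be non-empty")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.het_allele_ratio is not None and not 0.0 <= self.het_allele_ratio <= 1.0:
            raise ValueError("het_allele_ratio must be in [0, 1]")
        if not 0.0 <= self.population_maf <= 1.0:
            raise ValueError("population_maf must be in [0, 1]")

    @property
    def is_separate_test(self) -> bool:
        """True for orthogonal-assay records lacking read-level QC fields."""
        return self.depth is None and self.base_quality is None


@dataclass(frozen=True)
class FilterDecision:
    """Audit record: one retained/excluded verdict per input call."""

    call: VariantCall
    retained: bool
    reason: str

    def __post_init__(self) -> None:
        if self.retained != (self.reason == "ok"):
            raise ValueError("retained must hold exactly when reason is 'ok'")


@dataclass(frozen=True)
class GeneCoverageRecord:
    """Fraction of a gene's coding sequence adequately covered by the assay."""

    gene: str
    cds_covered_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cds_covered_fraction <= 1.0:
            raise ValueError("cds_covered_fraction must be in [0, 1]")


def filter_by_quality(
    calls: Sequence[VariantCall],
    min_depth: float = 10,
    min_quality: float = 20,
    min_het_ratio: float = 0.35,
    *,
    het_ratio_strict: bool = True,
) -> list[FilterDecision]:
    """Apply read-level quality filters.

    A call is retained iff depth >= ``min_depth``, base quality strictly
    above ``min_quality`` (Q20 itself fails), and — for heterozygous SNV
    calls only — alternate-allele read fraction above ``min_het_ratio``
    (``het_ratio_strict`` selects retain-iff-> vs retain-iff->=).
    Separate-test records without QC fields pass unconditionally.
    Order is preserved and every call receives exactly one decision.
    """
    if min_depth < 0 or min_quality < 0 or min_het_ratio < 0:
        raise ValueError("quality thresholds must be non-negative")
    decisions: list[FilterDecision] = []
    for call in calls:
        if call.is_separate_test:
            decisions.append(FilterDecision(call, True, "ok"))
            continue
        if call.depth is None or call.depth < min_depth:
            decisions.append(FilterDecision(call, False, "low_depth"))
        elif call.base_quality is None or call.base_quality <= min_quality:
            decisions.append(FilterDecision(call, False, "low_quality"))
        elif call.zygosity == "heterozygous" and not _ratio_ok(
            call.het_allele_ratio, min_het_ratio, het_ratio_strict
        ):
            decisions.append(FilterDecision(call, False, "low_het_ratio"))
        else:
            decisions.append(FilterDecision(call, True, "ok"))
    return decisions


def _ratio_ok(ratio: float | None, threshold: float, strict: bool) -> bool:
    if ratio is None:
        return False
    return ratio > threshold if strict else ratio >= threshold


def build_healthy_homozygote_index(calls: Iterable[VariantCall]) -> set[str]:
    """Variant keys observed homozygous in any (unaffected) cohort member.

    All participants are phenotypically unaffected for the screened
    conditions, so the index is built in one pass over the whole cohort.
    """
    return {c.variant_key for c in calls if c.zygosity == "homozygous"}


def filter_by_classification(
    calls: Sequence[VariantCall],
    max_maf: float = 0.01,
    healthy_homozygote_index: frozenset[str] | set[str] = frozenset(),
) -> list[FilterDecision]:
    """Keep pathogenic/likely-pathogenic, rare, never-homozygous-in-healthy calls.

    Retained iff classification in {P, LP} AND population MAF <= ``max_maf``
    AND the variant key is not in ``healthy_homozygote_index``. Excluded
    calls carry the first failing reason in the fixed order
    not_plp -> common_maf -> homozygous_in_healthy.
    """
    decisions: list[FilterDecision] = []
    for call in calls:
        if call.classification not in ("P", "LP"):
            decisions.append(FilterDecision(call, False, "not_plp"))
        elif call.population_maf > max_maf:
            decisions.append(FilterDecision(call, False, "common_maf"))
        elif call.variant_key in healthy_homozygote_index:
            decisions.append(FilterDecision(call, False, "homozygous_in_healthy"))
        else:
            decisions.append(FilterDecision(call, True, "ok"))
    return decisions


def apply_filters(
    calls: Sequence[VariantCall],
    min_depth: float = 10,
    min_quality: float = 20,
    min_het_ratio: float = 0.35,
    max_maf: float = 0.01,
    *,
    het_ratio_strict: bool = True,
    healthy_homozygote_index: set[str] | None = None,
) -> tuple[list[VariantCall], list[FilterDecision]]:
    """Run the full filtering cascade; return retained calls and all decisions.

    The healthy-homozygote index defaults to one built from the quality-passing
    calls of this same cohort.
    """
    quality = filter_by_quality(
        calls, min_depth, min_quality, min_het_ratio, het_ratio_strict=het_ratio_strict
    )
    passed_quality = [d.call for d in quality if d.retained]
    if healthy_homozygote_index is None:
        healthy_homozygote_index = build_healthy_homozygote_index(passed_quality)
    classification = filter_by_classification(
        passed_quality, max_maf, healthy_homozygote_index
    )
    decisions = [d for d in quality if not d.retained] + classification
    retained = [d.call for d in classification if d.retained]
    return retained, decisions


def flag_low_coverage_genes(
    records: Sequence[GeneCoverageRecord], min_fraction: float = 0.90
) -> set[str]:
    """Genes whose coding sequence is covered below ``min_fraction``.

    Flagged genes are annotated in downstream reports but stay in the
    carrier-rate and fetal-risk computation: frequent pathogenic variants in
    the well-covered portion of a gene remain clinically informative.
    """
    counts = Counter(r.gene for r in records)
    dupes = [g for g, n in counts.items() if n > 1]
    if dupes:
        raise ValueError(f"duplicate coverage records for genes: {sorted(dupes)}")
    return {r.gene for r in records if r.cds_covered_fraction < min_fraction}


def decisions_to_frame(decisions: Sequence[FilterDecision]):
    """FilterDecision rows as a pandas DataFrame (the audit TSV layout)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "individual_id": [d.call.individual_id for d in decisions],
            "gene": [d.call.gene for d in decisions],
            "variant_key": [d.call.variant_key for d in decisions],
            "zygosity": [d.call.zygosity for d in decisions],
            "classification": [d.call.classification for d in decisions],
            "population_maf": [d.call.population_maf for d in decisions],
            "retained": [d.retained for d in decisions],
            "reason": [d.reason for d in decisions],
        }
    )
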