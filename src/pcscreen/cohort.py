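"""Cohort-level carrier statistics.

Carrier rates are inheritance-aware: for autosomal genes every tested
individual enters the denominator; for X-linked genes only females are
counted as carriers and only females form the denominator (hemizygous males
are affected, not carriers). Rates are also reported in the clinical "1/N"
display form with the denominator rounded half-up. Proportions carry exact
(Clopper-Pearson) binomial confidence intervals and subgroup contrasts use
Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CohortComposition",
    "CarrierStat",
    "CohortProportion",
    "BurdenSummary",
    "FisherResult",
    "compute_carrier_rate",
    "carrier_burden_summary",
    "proportion_ci",
    "fisher_exact_test",
    "display_denominator",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (clinical convention)."""
    return int(math.floor(x + 0.5))


def display_denominator(denominator: int, n_carriers: int) -> int:
    """N of the '1/N' clinical display for a carrier count over a denominator."""
    if n_carriers <= 0:
        raise ValueError("display form undefined for zero carriers")
    return round_half_up(denominator / n_carriers)


@dataclass(frozen=True)
class CohortComposition:
    """Cohort size broken down by sex and screening indication."""

    n_female_patient: int
    n_female_donor: int
    n_male_patient: int
    n_male_donor: int

    def __post_init__(self) -> None:
        for v in (
            self.n_female_patient,
            self.n_female_donor,
            self.n_male_patient,
            self.n_male_donor,
        ):
            if v < 0:
                raise ValueError("subgroup counts must be >= 0")

    @property
    def n_total(self) -> int:
        return (
            self.n_female_patient
            + self.n_female_donor
            + self.n_male_patient
            + self.n_male_donor
        )

    @property
    def n_female(self) -> int:
        return self.n_female_patient + self.n_female_donor

    @property
    def n_male(self) -> int:
        return self.n_male_patient + self.n_male_donor


@dataclass(frozen=True)
class CarrierStat:
    """Per-gene carrier rate with its clinical display form."""

    gene: str
    inheritance: str
    n_carriers: int
    denominator: int
    rate: float
    display: str

    @property
    def display_denominator(self) -> int | None:
        if self.n_carriers == 0:
            return None
        return int(self.display.split("/")[1])


@dataclass(frozen=True)
class CohortProportion:
    """A proportion with its exact binomial confidence bounds, in percent."""

    numerator: int
    denominator: int
    level: float
    point_pct: float
    lower_pct: float
    upper_pct: float

    def __post_init__(self) -> None:
        if self.numerator > self.denominator:
            raise ValueError("numerator must not exceed denominator")
        if not (0.0 <= self.lower_pct <= self.point_pct + 1e-9):
            raise ValueError("lower bound above point estimate")
        if not (self.point_pct - 1e-9 <= self.upper_pct <= 100.0 + 1e-9):
            raise ValueError("upper bound below point estimate")


@dataclass(frozen=True)
class BurdenSummary:
    """Distribution of retained P/LP panel variants per individual."""

    n_individuals: int
    mean_per_individual: float
    positive_fraction: float
    mean_per_positive: float | None
    histogram: dict[int, int]


def compute_carrier_rate(
    carriers: set[str],
    composition: CohortComposition,
    inheritance: str,
    sex_lookup: Mapping[str, str] | None = None,
    gene: str = "",
) -> CarrierStat:
    """Carrier rate for one gene under its inheritance pattern.

    For autosomal (AR) genes the denominator is the whole tested cohort;
    for X-linked (XL) genes only female carriers are counted over the female
    denominator. ``sex_lookup`` maps individual id -> {"female", "male"} and
    doubles as the cohort membership roster; every carrier must be present.
    An individual carrying several qualifying variants in the gene counts
    once (callers pass a set of ids).
    """
    if inheritance not in ("AR", "XL"):
        raise ValueError(f"inheritance must be 'AR' or 'XL', got {inheritance!r}")
    if sex_lookup is not None:
        missing = [c for c in carriers if c not in sex_lookup]
        if missing:
            raise ValueError(f"carriers not in cohort roster: {sorted(missing)[:5]}")
    if inheritance == "XL":
        if sex_lookup is None:
            raise ValueError("X-linked carrier rates require a sex lookup")
        counted = {c for c in carriers if sex_lookup[c] == "female"}
        denominator = composition.n_female
    else:
        counted = set(carriers)
        denominator = composition.n_total
    if denominator <= 0:
        raise ValueError("empty denominator for carrier rate")
    n = len(counted)
    rate = n / denominator
    display = f"0/{denominator}" if n == 0 else f"1/{display_denominator(denominator, n)}"
    return CarrierStat(
        gene=gene,
        inheritance=inheritance,
        n_carriers=n,
        denominator=denominator,
        rate=rate,
        display=display,
    )


def carrier_burden_summary(per_individual_counts: Mapping[str, int]) -> BurdenSummary:
    """Summarise per-individual counts of retained P/LP panel variants."""
    if not per_individual_counts:
        raise ValueError("empty cohort")
    counts = np.asarray(list(per_individual_counts.values()), dtype=int)
    if (counts < 0).any():
        raise ValueError("negative variant counts")
    mean = float(counts.mean())
    positive_fraction = float((counts > 0).mean())
    mean_per_positive = mean / positive_fraction if positive_fraction > 0 else None
    histogram = {
        int(k): int(v)
        for k, v in zip(*np.unique(counts, return_counts=True))
    }
    for k in range(counts.max() + 1):
        histogram.setdefault(k, 0)
    return BurdenSummary(
        n_individuals=len(counts),
        mean_per_individual=mean,
        positive_fraction=positive_fraction,
        mean_per_positive=mean_per_positive,
        histogram=dict(sorted(histogram.items())),
    )


def proportion_ci(
    numerator: int, denominator: int, level: float = 0.95, method: str = "beta"
) -> CohortProportion:
    """Proportion with exact (Clopper-Pearson) confidence bounds, in percent.

    ``method`` is passed to statsmodels ``proportion_confint``; the default
    "beta" is the exact interval from beta-distribution quantiles.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator out of range")
    lower, upper = proportion_confint(
        numerator, denominator, alpha=1.0 - level, method=method
    )
    return CohortProportion(
        numerator=numerator,
        denominator=denominator,
        level=level,
        point_pct=100.0 * numerator / denominator,
        lower_pct=100.0 * float(lower),
        upper_pct=100.0 * float(upper),
    )


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    degenerate: bool


def fisher_exact_test(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    Tables with any zero margin carry no information about association and
    return p = 1 flagged degenerate.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, t.astype(int)):
        raise ValueError("table must be 2x2 non-negative integers")
    t = t.astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return FisherResult(p_value=1.0, odds_ratio=float("nan"), degenerate=True)
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return FisherResult(p_value=float(p), odds_ratio=float(odds), degenerate=False)
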