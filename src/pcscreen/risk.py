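"""Fetal disease risk (FDR) models.

FDR is the modelled probability that a random conception is affected by a
given recessive condition, derived from observed carrier frequencies under
random mating:

* autosomal recessive:   FDR = CR_female x CR_male / 4
  (both partners carriers, one quarter of their conceptions affected);
* X-linked recessive:    FDR = CR_female / 4
  (half of a carrier mother's conceptions inherit the variant, half of
  those are male and therefore affected);
* FMR1 CGG expansion:    FDR = (1/4) x sum_bins freq(bin) x P(expansion|bin)
  — the X-linked formula weighted, per maternal premutation size bin, by
  the probability that the premutation expands to a full mutation on
  transmission;
* alpha-thalassemia:     FDR = CR(-a3.7) x CR(-MED/-SEA) / 4
  — an HbH-type conception requires a single-gene-deletion carrier matched
  with a double-gene-deletion carrier.

A seeded Monte Carlo mating simulator provides an independent oracle for
every closed form. Aggregate FDR over a curated panel is the sum of
per-pair risks at or above a severity floor; contribution shares decompose
the aggregate by gene, inheritance and rarity.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FdrEstimate",
    "ExpansionTable",
    "AlphaThalInput",
    "ContributionReport",
    "fdr_autosomal_recessive",
    "fdr_x_linked",
    "fdr_fmr1_expansion",
    "fdr_alpha_thalassemia",
    "simulate_conception_risk",
    "aggregate_fdr",
    "contribution_breakdown",
    "default_expansion_table",
]


def _check_rate(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class FdrEstimate:
    """Modelled fetal disease risk for one gene-condition pair."""

    gene: str
    condition: str
    model: str  # AR | XL | FMR1 | HBA
    fdr: float
    severity: int = 3
    carrier_rate: float | None = None
    contribution_pct: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError("fdr must be in [0, 1]")
        if self.model not in ("AR", "XL", "FMR1", "HBA"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass(frozen=True)
class ExpansionTable:
    """Maternal CGG-size-dependent full-mutation expansion probabilities.

    ``bins`` is a sorted, non-overlapping list of
    (cgg_lower, cgg_upper, expansion_prob) with inclusive bounds.
    """

    bins: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        prev_hi = -1
        for lo, hi, p in self.bins:
            if lo > hi:
                raise ValueError(f"bin lower {lo} above upper {hi}")
            if lo <= prev_hi:
                raise ValueError("expansion-table bins overlap or are unsorted")
            if not 0.0 <= p <= 1.0:
                raise ValueError("expansion probabilities must be in [0, 1]")
            prev_hi = hi

    def probability(self, cgg: int) -> float:
        """Expansion probability for a maternal allele of ``cgg`` repeats."""
        for lo, hi, p in self.bins:
            if lo <= cgg <= hi:
                return p
        raise KeyError(f"CGG size {cgg} not covered by expansion table")

    def probability_for_bin(self, key: tuple[int, int]) -> float:
        for lo, hi, p in self.bins:
            if (lo, hi) == tuple(key):
                return p
        raise KeyError(f"bin {key} missing from expansion table")


@dataclass(frozen=True)
class AlphaThalInput:
    """Carrier rates for the two alpha-globin deletion classes."""

    cr_a37: float  # single-gene -a3.7 deletion carriers
    cr_sev: float  # combined --MED and --SEA double-gene deletion carriers

    def __post_init__(self) -> None:
        _check_rate("cr_a37", self.cr_a37)
        _check_rate("cr_sev", self.cr_sev)


def default_expansion_table() -> ExpansionTable:
    """Shipped maternal CGG expansion-risk table (replaceable TSV data file)."""
    from pcscreen.io import read_expansion_table

    with resources.as_file(
        resources.files("pcscreen.data") / "fmr1_expansion_maternal.tsv"
    ) as path:
        return read_expansion_table(path)


def fdr_autosomal_recessive(cr_female: float, cr_male: float) -> float:
    """AR fetal disease risk: CR_f x CR_m / 4 under random mating.

    Pass the pooled cohort carrier rate for both arguments when sex-specific
    rates are not available.
    """
    _check_rate("cr_female", cr_female)
    _check_rate("cr_male", cr_male)
    return cr_female * cr_male / 4.0


def fdr_x_linked(cr_female: float) -> float:
    """X-linked recessive fetal disease risk: female carrier rate / 4."""
    _check_rate("cr_female", cr_female)
    return cr_female / 4.0


def fdr_fmr1_expansion(
    premutation_allele_freqs: Mapping[tuple[int, int], float],
    table: ExpansionTable,
) -> float:
    """Fragile-X fetal disease risk from binned maternal premutation frequencies.

    Each bin's female premutation-carrier frequency is weighted by the
    probability that an allele of that size expands to a full mutation on
    maternal transmission, then the X-linked 1/4 factor applies.
    """
    total = 0.0
    for bin_key, freq in premutation_allele_freqs.items():
        _check_rate(f"freq{bin_key}", freq)
        total += freq * table.probability_for_bin(bin_key)
    return total / 4.0


def fdr_alpha_thalassemia(input: AlphaThalInput) -> float:
    """HbH-type alpha-thalassemia risk: CR(-a3.7) x CR(--MED/--SEA) / 4."""
    return input.cr_a37 * input.cr_sev / 4.0


def simulate_conception_risk(
    carrier_freqs,
    model: str,
    n_conceptions: int,
    seed: int,
) -> float:
    """Monte Carlo mating oracle: fraction of simulated conceptions affected.

    Random parental pairs are drawn from the given carrier frequencies and
    alleles transmitted by Mendelian rules. ``carrier_freqs`` is
    model-specific:

    * ``AR``:   (cr_female, cr_male) or a single pooled rate;
    * ``XL``:   cr_female;
    * ``FMR1``: (freqs: {(lo, hi): female freq}, ExpansionTable);
    * ``HBA``:  AlphaThalInput (one parent drawn from the -a3.7 carrier
      pool, the other from the --MED/--SEA pool, matching the closed form's
      directional convention).
    """
    if n_conceptions < 1:
        raise ValueError("n_conceptions must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_conceptions

    if model == "AR":
        if np.isscalar(carrier_freqs):
            cr_f = cr_m = float(carrier_freqs)
        else:
            cr_f, cr_m = map(float, carrier_freqs)
        mother = rng.random(n) < cr_f
        father = rng.random(n) < cr_m
        from_mother = mother & (rng.random(n) < 0.5)
        from_father = father & (rng.random(n) < 0.5)
        affected = from_mother & from_father
    elif model == "XL":
        cr_f = float(carrier_freqs)
        mother = rng.random(n) < cr_f
        transmitted = mother & (rng.random(n) < 0.5)
        male_child = rng.random(n) < 0.5
        affected = transmitted & male_child
    elif model == "FMR1":
        freqs, table = carrier_freqs
        bins = list(freqs.keys())
        probs = np.array([table.probability_for_bin(b) for b in bins])
        fr = np.array([freqs[b] for b in bins], dtype=float)
        if fr.sum() > 1.0:
            raise ValueError("premutation bin frequencies sum above 1")
        # maternal genotype: one of the premutation bins, or non-carrier
        choice = rng.choice(
            len(bins) + 1, size=n, p=np.append(fr, 1.0 - fr.sum())
        )
        carrier = choice < len(bins)
        expand_p = np.where(carrier, probs[np.minimum(choice, len(bins) - 1)], 0.0)
        transmitted = carrier & (rng.random(n) < 0.5)
        expanded = transmitted & (rng.random(n) < expand_p)
        male_child = rng.random(n) < 0.5
        affected = expanded & male_child
    elif model == "HBA":
        inp = carrier_freqs
        a37_parent = rng.random(n) < inp.cr_a37
        sev_parent = rng.random(n) < inp.cr_sev
        got_a37 = a37_parent & (rng.random(n) < 0.5)
        got_sev = sev_parent & (rng.random(n) < 0.5)
        affected = got_a37 & got_sev
    else:
        raise ValueError(f"unknown model tag {model!r}")

    return float(np.count_nonzero(affected)) / n


@dataclass(frozen=True)
class AggregateFdr:
    """Summed fetal disease risk over a panel, with '1/x' display."""

    fdr: float
    n_pairs: int
    display: str


def aggregate_fdr(
    estimates: Sequence[FdrEstimate], min_severity: int = 1
) -> AggregateFdr:
    """Sum per-pair FDR over estimates at or above a severity floor."""
    selected = [e for e in estimates if e.severity >= min_severity]
    total = float(sum(e.fdr for e in selected))
    if total > 0:
        display = f"1/{round(1.0 / total)}"
    else:
        display = "0"
    return AggregateFdr(fdr=total, n_pairs=len(selected), display=display)


@dataclass(frozen=True)
class ContributionReport:
    """Decomposition of aggregate fetal risk."""

    aggregate_fdr: float
    per_gene_pct: dict[str, float]
    x_linked_pct: float
    rare_condition_pct: float  # share from genes with CR < rare_threshold


def contribution_breakdown(
    estimates: Sequence[FdrEstimate],
    carrier_rates: Mapping[str, float] | None = None,
    rare_threshold: float = 0.01,
) -> ContributionReport:
    """Per-gene contribution shares plus X-linked and rare-condition shares.

    Rarity (CR below ``rare_threshold``, i.e. 1/100) is judged on
    ``carrier_rates`` when supplied, else on each estimate's own
    ``carrier_rate`` attribute where present.
    """
    total = float(sum(e.fdr for e in estimates))
    if total <= 0:
        raise ValueError("aggregate FDR is zero; no contributions to report")
    per_gene: dict[str, float] = {}
    for e in estimates:
        per_gene[e.gene] = per_gene.get(e.gene, 0.0) + 100.0 * e.fdr / total
    xl = sum(e.fdr for e in estimates if e.model in ("XL", "FMR1")) / total * 100.0

    def _cr(e: FdrEstimate) -> float | None:
        if carrier_rates is not None and e.gene in carrier_rates:
            return carrier_rates[e.gene]
        return e.carrier_rate

    rare = (
        sum(e.fdr for e in estimates if (_cr(e) is not None and _cr(e) < rare_threshold))
        / total
        * 100.0
    )
    return ContributionReport(
        aggregate_fdr=total,
        per_gene_pct=per_gene,
        x_linked_pct=float(xl),
        rare_condition_pct=float(rare),
    )
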