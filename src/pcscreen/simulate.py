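"""Synthetic preconception-screening cohorts with known ground truth.

Generates a cohort of configurable size and composition (female/male x
donor/patient), plants per-gene carrier genotypes at configured carrier
frequencies (autosomal genes over everyone, X-linked genes over females),
adds QC-noise and classification contamination calls that each violate
exactly one downstream filter, draws female FMR1 CGG allele sizes from a
configurable premutation distribution, plants secondary-findings carriers,
and randomly pairs couples. Every planted status is recorded in truth
tables so pipeline output can be audited exactly. All draws flow from a
single mandatory seed; identical configs produce identical cohorts.

The generator works directly in carrier-frequency space (one heterozygous
call per planted carrier) because the screening analysis consumes carrier
rates, not allele frequencies. An optional Hardy-Weinberg mode plants
homozygotes at (q/2)^2 for exercising the healthy-homozygote exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from pcscreen.cohort import CohortComposition
from pcscreen.couples import Couple
from pcscreen.variants import VariantCall

__all__ = [
    "GeneModel",
    "SimulationConfig",
    "Population",
    "simulate_population",
    "simulate_couples",
    "default_config",
]

# contamination class -> the single filter reason it is built to trip
CONTAMINATION_REASONS = {
    "vus": "not_plp",
    "benign": "not_plp",
    "common_maf": "common_maf",
    "low_depth": "low_depth",
    "low_quality": "low_quality",
    "low_het_ratio": "low_het_ratio",
}


class GeneModel(BaseModel):
    """Ground-truth parameters for one simulated gene-condition pair."""

    gene: str
    condition: str = ""
    inheritance: str = "AR"  # AR | XLR
    carrier_freq: float = Field(ge=0.0, le=1.0)
    severity: int = Field(default=3, ge=1, le=4)
    onset: str = "childhood"
    penetrance: str = "high"
    evidence: str = "definitive/strong"
    in_panel: bool = True
    structural: bool = False  # separate-test event (no read-level QC fields)
    mim_phenotype: str | None = None
    mim_gene: str | None = None

    @field_validator("inheritance")
    @classmethod
    def _inh(cls, v: str) -> str:
        if v not in ("AR", "XLR"):
            raise ValueError("simulated genes must be AR or XLR")
        return v


class SimulationConfig(BaseModel):
    """Complete description of a synthetic cohort to generate."""

    n_individuals: int = Field(ge=1)
    subgroup_fractions: dict[str, float] = Field(
        default={
            "patient_female": 0.1378,
            "donor_female": 0.3907,
            "patient_male": 0.4484,
            "donor_male": 0.0231,
        }
    )
    genes: list[GeneModel] = Field(default_factory=list)
    contamination: dict[str, float] = Field(default_factory=dict)
    fmr1_premutation_freqs: dict[str, float] = Field(default_factory=dict)
    sf_gene_freqs: dict[str, float] = Field(default_factory=dict)
    hardy_weinberg_homozygotes: bool = False
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        total = sum(self.subgroup_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("subgroup fractions must sum to 1")
        if set(self.subgroup_fractions) != {
            "patient_female",
            "donor_female",
            "patient_male",
            "donor_male",
        }:
            raise ValueError("subgroup_fractions must use the four canonical keys")
        for cls in self.contamination:
            if cls not in CONTAMINATION_REASONS:
                raise ValueError(f"unknown contamination class {cls!r}")
        for rng_ in self.fmr1_premutation_freqs:
            lo, hi = _parse_bin(rng_)
            if lo > hi:
                raise ValueError(f"bad FMR1 bin {rng_!r}")
        return self


def _parse_bin(text: str) -> tuple[int, int]:
    lo, hi = text.split("-")
    return int(lo), int(hi)


@dataclass
class Population:
    """A simulated cohort with its ground truth."""

    individuals: pd.DataFrame  # individual_id, sex, group
    calls: list[VariantCall]
    fmr1_alleles: dict[str, tuple[int, int]]
    truth: dict[str, set[str]]  # gene -> planted carrier ids (screen panel + SF)
    planted_contamination: dict[str, int]  # filter reason -> planted call count
    composition: CohortComposition
    config: SimulationConfig

    @property
    def sex_lookup(self) -> dict[str, str]:
        return dict(zip(self.individuals.individual_id, self.individuals.sex))

    @property
    def group_lookup(self) -> dict[str, str]:
        return dict(zip(self.individuals.individual_id, self.individuals.group))


def _subgroup_counts(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment so subgroup counts sum to n exactly."""
    keys = ["patient_female", "donor_female", "patient_male", "donor_male"]
    raw = {k: n * fractions[k] for k in keys}
    counts = {k: int(raw[k]) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _passing_qc(rng: np.random.Generator) -> dict:
    return {
        "depth": float(rng.integers(30, 201)),
        "base_quality": float(rng.uniform(30, 40)),
        "het_allele_ratio": float(rng.uniform(0.40, 0.60)),
    }


def simulate_population(config: SimulationConfig) -> Population:
    """Draw a full synthetic cohort from ``config`` (reproducible per seed)."""
    rng = np.random.default_rng(config.seed)
    counts = _subgroup_counts(config.n_individuals, config.subgroup_fractions)
    ids, sexes, groups = [], [], []
    i = 0
    for key in ("patient_female", "donor_female", "patient_male", "donor_male"):
        group, sex = key.split("_")
        for _ in range(counts[key]):
            ids.append(f"IND{i:06d}")
            sexes.append(sex)
            groups.append(group)
            i += 1
    individuals = pd.DataFrame({"individual_id": ids, "sex": sexes, "group": groups})
    composition = CohortComposition(
        n_female_patient=counts["patient_female"],
        n_female_donor=counts["donor_female"],
        n_male_patient=counts["patient_male"],
        n_male_donor=counts["donor_male"],
    )
    id_arr = np.array(ids)
    female_mask = np.array([s == "female" for s in sexes])

    calls: list[VariantCall] = []
    truth: dict[str, set[str]] = {}

    for gm in config.genes:
        eligible = id_arr[female_mask] if gm.inheritance == "XLR" else id_arr
        draw = rng.random(len(eligible)) < gm.carrier_freq
        carriers = set(eligible[draw])
        truth[gm.gene] = carriers
        for ind in sorted(carriers):
            if gm.structural:
                # orthogonal-assay event: pre-validated, no read-level QC
                calls.append(
                    VariantCall(
                        individual_id=ind,
                        gene=gm.gene,
                        variant_key=f"{gm.gene}:structural_event",
                        zygosity="heterozygous",
                        classification="P",
                        population_maf=float(rng.uniform(0.0, 0.005)),
                    )
                )
                continue
            variant_no = int(rng.integers(1, 4))
            calls.append(
                VariantCall(
                    individual_id=ind,
                    gene=gm.gene,
                    variant_key=f"{gm.gene}:c.{variant_no * 100}G>A",
                    zygosity="heterozygous",
                    classification="P" if rng.random() < 0.7 else "LP",
                    population_maf=float(rng.uniform(0.0, 0.005)),
                    **_passing_qc(rng),
                )
            )
        if config.hardy_weinberg_homozygotes and gm.inheritance == "AR":
            p_hom = (gm.carrier_freq / 2.0) ** 2
            hom_draw = rng.random(len(id_arr)) < p_hom
            for ind in sorted(id_arr[hom_draw]):
                calls.append(
                    VariantCall(
                        individual_id=ind,
                        gene=gm.gene,
                        variant_key=f"{gm.gene}:c.100G>A",
                        zygosity="homozygous",
                        classification="P",
                        population_maf=float(rng.uniform(0.0, 0.005)),
                        **_passing_qc(rng),
                    )
                )

    # contamination: each class is built to trip exactly one filter
    planted: dict[str, int] = {}
    gene_pool = [gm.gene for gm in config.genes] or ["GENE0"]
    for cls, rate in config.contamination.items():
        n_calls = rng.poisson(rate, size=len(id_arr))
        reason = CONTAMINATION_REASONS[cls]
        n_total = int(n_calls.sum())
        planted[reason] = planted.get(reason, 0) + n_total
        for ind, k in zip(id_arr, n_calls):
            for j in range(k):
                qc = _passing_qc(rng)
                classification = "P"
                maf = float(rng.uniform(0.0, 0.005))
                if cls == "vus":
                    classification = "VUS"
                elif cls == "benign":
                    classification = "B" if rng.random() < 0.5 else "LB"
                elif cls == "common_maf":
                    maf = float(rng.uniform(0.02, 0.2))
                elif cls == "low_depth":
                    qc["depth"] = float(rng.integers(0, 10))
                elif cls == "low_quality":
                    qc["base_quality"] = float(rng.uniform(5, 20))
                elif cls == "low_het_ratio":
                    qc["het_allele_ratio"] = float(rng.uniform(0.05, 0.35))
                calls.append(
                    VariantCall(
                        individual_id=ind,
                        gene=str(rng.choice(gene_pool)),
                        variant_key=f"CONTAM:{cls}:{ind}:{j}",
                        zygosity="heterozygous",
                        classification=classification,
                        population_maf=maf,
                        **qc,
                    )
                )

    # FMR1 CGG sizing for females: allele 1 always normal, allele 2
    # premutation with the configured per-bin frequency
    fmr1_alleles: dict[str, tuple[int, int]] = {}
    if config.fmr1_premutation_freqs:
        bins = sorted(config.fmr1_premutation_freqs.items(), key=lambda kv: kv[0])
        freqs = np.array([f for _, f in bins])
        if freqs.sum() > 1.0:
            raise ValueError("FMR1 premutation bin frequencies sum above 1")
        fmr1_carriers: set[str] = set()
        females = id_arr[female_mask]
        choice = rng.choice(
            len(bins) + 1, size=len(females), p=np.append(freqs, 1.0 - freqs.sum())
        )
        for ind, c in zip(females, choice):
            a1 = int(rng.integers(20, 41))
            if c < len(bins):
                lo, hi = _parse_bin(bins[c][0])
                a2 = int(rng.integers(lo, hi + 1))
                fmr1_carriers.add(ind)
            else:
                a2 = int(rng.integers(20, 41))
            fmr1_alleles[ind] = (min(a1, a2), max(a1, a2))
        truth["FMR1"] = fmr1_carriers

    # secondary-findings carriers (independent classification channel)
    for gene, freq in config.sf_gene_freqs.items():
        draw = rng.random(len(id_arr)) < freq
        carriers = set(id_arr[draw])
        truth.setdefault(f"SF:{gene}", set()).update(carriers)
        for ind in sorted(carriers):
            variant_no = int(rng.integers(1, 6))
            calls.append(
                VariantCall(
                    individual_id=ind,
                    gene=gene,
                    variant_key=f"{gene}:c.{variant_no * 111}C>T",
                    zygosity="heterozygous",
                    classification="P",
                    sf_classification="P",
                    population_maf=float(rng.uniform(0.0, 0.004)),
                    **_passing_qc(rng),
                )
            )

    return Population(
        individuals=individuals,
        calls=calls,
        fmr1_alleles=fmr1_alleles,
        truth=truth,
        planted_contamination=planted,
        composition=composition,
        config=config,
    )


def simulate_couples(
    population: Population, n_couples: int, seed: int
) -> list[Couple]:
    """Randomly pair females with males, without replacement."""
    if n_couples < 0:
        raise ValueError("n_couples must be >= 0")
    df = population.individuals
    females = df.loc[df.sex == "female", "individual_id"].to_numpy()
    males = df.loc[df.sex == "male", "individual_id"].to_numpy()
    if n_couples > min(len(females), len(males)):
        raise ValueError(
            f"cannot form {n_couples} couples from "
            f"{len(females)} females and {len(males)} males"
        )
    rng = np.random.default_rng(seed)
    chosen_f = rng.choice(females, size=n_couples, replace=False)
    chosen_m = rng.choice(males, size=n_couples, replace=False)
    return [Couple(female_id=f, male_id=m) for f, m in zip(chosen_f, chosen_m)]


def default_config(seed: int, n_individuals: int = 14125) -> SimulationConfig:
    """Shipped default: a cohort mirroring the headline study structure.

    14,125 individuals split 1,946/5,518/6,334/327 across female patients,
    female donors, male patients and male donors; a 114-gene panel with
    carrier rates spanning 1/28 to 1/500 whose top contributors match the
    printed couple-report genes; light contamination in every QC class; an
    FMR1 premutation frequency near 1/146 concentrated in the 55-69 CGG
    range; and a handful of secondary-findings genes.
    """
    panel = load_default_panel()
    genes = [
        GeneModel(
            gene=r.gene,
            condition=r.condition,
            inheritance=r.inheritance,
            carrier_freq=float(r.carrier_freq),
            severity=int(r.severity),
            onset=r.onset,
            penetrance=r.penetrance,
            evidence=r.evidence,
            in_panel=bool(r.in_panel),
            structural=bool(r.structural),
            mim_phenotype=r.mim_phenotype if isinstance(r.mim_phenotype, str) else None,
            mim_gene=r.mim_gene if isinstance(r.mim_gene, str) else None,
        )
        for r in panel.itertuples()
    ]
    return SimulationConfig(
        n_individuals=n_individuals,
        subgroup_fractions={
            "patient_female": 1946 / 14125,
            "donor_female": 5518 / 14125,
            "patient_male": 6334 / 14125,
            "donor_male": 327 / 14125,
        },
        genes=genes,
        contamination={
            "vus": 0.04,
            "benign": 0.02,
            "common_maf": 0.01,
            "low_depth": 0.01,
            "low_quality": 0.01,
            "low_het_ratio": 0.01,
        },
        fmr1_premutation_freqs={"55-59": 0.004, "60-69": 0.002, "70-89": 0.0008},
        sf_gene_freqs={
            "BRCA2": 57 / 14125,
            "KCNH2": 25 / 14125,
            "LDLR": 22 / 14125,
            "RYR1": 22 / 14125,
            "MYBPC3": 21 / 14125,
            "BRCA1": 20 / 14125,
        },
        seed=seed,
    )


def load_default_panel() -> pd.DataFrame:
    """The shipped default gene-condition table used by ``default_config``."""
    with resources.as_file(
        resources.files("pcscreen.data") / "default_panel.tsv"
    ) as path:
        return pd.read_csv(
            path, sep="\t", dtype={"mim_phenotype": str, "mim_gene": str}
        )
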