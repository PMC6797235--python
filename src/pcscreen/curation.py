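"""Stepwise gene-disease pair curation.

Candidate gene-condition pairs are reduced to a screening panel by a fixed
exclusion cascade, each pair recorded at the first failing step:

1. prevalence  — modelled fetal disease risk below 1 in a million
                 (for autosomal recessive pairs this is equivalent to a
                 pooled carrier frequency below 1 in 500);
2. inheritance — not autosomal or X-linked recessive;
3. evidence    — gene-disease association not definitive/strong (ClinGen
                 clinical-validity classes are an input column);
4. penetrance  — established low/moderate penetrance (unknown retained);
5. onset       — adult/late onset;
6. severity    — mild (ordinal 1 on the mild=1 .. profound=4 scale).

Survivors form the curated panel. Because published step tallies can
overlap (a pair may fail several criteria), the ledger also records every
failing step so either accounting can be reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "SEVERITY_SCALE",
    "GeneConditionPair",
    "CurationLedgerEntry",
    "severity_rank",
    "curate_panel",
]

SEVERITY_SCALE = {"mild": 1, "moderate": 2, "severe": 3, "profound": 4}

_RECESSIVE = ("AR", "XLR")
_STEPS = ("prevalence", "inheritance", "evidence", "penetrance", "onset", "severity")


def severity_rank(label: str) -> int:
    """Ordinal severity: mild=1, moderate=2, severe=3, profound=4."""
    try:
        return SEVERITY_SCALE[label.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown severity label {label!r}") from None


@dataclass(frozen=True)
class GeneConditionPair:
    """A gene-disease association with its curation-relevant attributes."""

    gene: str
    condition: str
    inheritance: str  # AR | XLR | AD | XLD | other
    severity: int  # 1..4
    onset: str  # childhood | adult/late
    penetrance: str  # high | low/moderate | unknown
    evidence: str  # definitive/strong | low/moderate | none
    mim_phenotype: str | None = None
    mim_gene: str | None = None

    def __post_init__(self) -> None:
        if self.severity not in (1, 2, 3, 4):
            raise ValueError("severity must be the ordinal 1..4")
        for mim in (self.mim_phenotype, self.mim_gene):
            if mim is not None and not (len(mim) == 6 and mim.isdigit()):
                raise ValueError(f"MIM identifier must be 6 digits, got {mim!r}")


@dataclass(frozen=True)
class CurationLedgerEntry:
    """Fate of one candidate pair: first failing step plus all failing steps."""

    pair: GeneConditionPair
    fdr: float
    step: str  # first failing step, or "retained"
    retained: bool
    failed_steps: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.retained != (self.step == "retained"):
            raise ValueError("retained must hold exactly when step is 'retained'")


def _failing_steps(
    pair: GeneConditionPair, fdr: float, fdr_threshold: float
) -> list[str]:
    failed = []
    if fdr < fdr_threshold:
        failed.append("prevalence")
    if pair.inheritance not in _RECESSIVE:
        failed.append("inheritance")
    if pair.evidence != "definitive/strong":
        failed.append("evidence")
    if pair.penetrance == "low/moderate":
        failed.append("penetrance")
    if pair.onset == "adult/late":
        failed.append("onset")
    if pair.severity == 1:
        failed.append("severity")
    return failed


def curate_panel(
    pairs: Sequence[tuple[GeneConditionPair, float]],
    fdr_threshold: float = 1e-6,
) -> tuple[list[GeneConditionPair], list[CurationLedgerEntry]]:
    """Apply the exclusion cascade; return the curated panel and full ledger.

    ``pairs`` is a sequence of (pair, modelled fdr). Every input pair
    appears exactly once in the ledger, excluded pairs under their first
    failing step in the fixed cascade order. Unknown penetrance is retained.
    """
    if fdr_threshold < 0:
        raise ValueError("fdr_threshold must be >= 0")
    panel: list[GeneConditionPair] = []
    ledger: list[CurationLedgerEntry] = []
    for pair, fdr in pairs:
        if fdr is None:
            raise ValueError(f"missing FDR for pair {pair.gene}/{pair.condition}")
        failed = _failing_steps(pair, fdr, fdr_threshold)
        if failed:
            ledger.append(
                CurationLedgerEntry(
                    pair=pair,
                    fdr=fdr,
                    step=failed[0],
                    retained=False,
                    failed_steps=tuple(failed),
                )
            )
        else:
            panel.append(pair)
            ledger.append(
                CurationLedgerEntry(pair=pair, fdr=fdr, step="retained", retained=True)
            )
    return panel, ledger
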