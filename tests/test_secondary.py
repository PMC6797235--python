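"""ACMG SF v2.0 secondary-findings screening."""

import pytest

from pcscreen.cohort import CohortComposition, display_denominator, round_half_up
from pcscreen.secondary import (
    biallelic_recessive_sf_check,
    load_acmg_sf_list,
    screen_secondary_findings,
)

from conftest import make_call

STUDY = CohortComposition(1946, 5518, 6334, 327)

# published per-gene secondary-findings subgroup counts and the printed
# carrier-rate denominator: (patient F, donor F, patient M, donor M, CR
# denominator, inheritance). X-linked rows use the 7,464-female denominator.
PUBLISHED_SF_COUNTS = {
    "BRCA1": (2, 5, 11, 2, 706, "AD"),
    "BRCA2": (7, 19, 28, 3, 248, "AD"),
    "TP53": (2, 1, 1, 1, 2825, "AD"),
    "APC": (0, 1, 0, 0, 14125, "AD"),
    "MLH1": (0, 1, 3, 0, 3531, "AD"),
    "MSH2": (0, 3, 3, 0, 2354, "AD"),
    "MSH6": (1, 6, 4, 0, 1284, "AD"),
    "PMS2": (4, 5, 5, 0, 1009, "AD"),
    "VHL": (1, 1, 0, 0, 7063, "AD"),
    "TSC1": (3, 1, 3, 0, 2018, "AD"),
    "RB1": (0, 0, 1, 0, 14125, "AD"),
    "SDHD": (1, 0, 0, 0, 14125, "AD"),
    "SDHC": (0, 2, 2, 0, 3531, "AD"),
    "SDHB": (1, 0, 2, 0, 4708, "AD"),
    "FBN1": (2, 7, 5, 1, 942, "AD"),
    "TGFBR1": (1, 1, 0, 0, 7063, "AD"),
    "ACTA2": (1, 0, 0, 0, 14125, "AD"),
    "MYBPC3": (1, 10, 10, 0, 673, "AD"),
    "MYH7": (4, 3, 7, 0, 1009, "AD"),
    "TNNT2": (1, 1, 0, 0, 7063, "AD"),
    "TNNI3": (2, 1, 2, 0, 2825, "AD"),
    "PRKAG2": (1, 0, 0, 0, 14125, "AD"),
    "MYL2": (0, 2, 0, 0, 7063, "AD"),
    "LMNA": (0, 0, 1, 0, 14125, "AD"),
    "RYR2": (0, 2, 1, 0, 4708, "AD"),
    "PKP2": (2, 2, 6, 0, 1413, "AD"),
    "DSP": (0, 0, 2, 0, 7063, "AD"),
    "DSC2": (0, 1, 1, 0, 7063, "AD"),
    "DSG2": (1, 0, 2, 1, 3531, "AD"),
    "KCNQ1": (4, 3, 7, 0, 1009, "AD"),
    "KCNH2": (7, 7, 10, 1, 565, "AD"),
    "SCN5A": (2, 2, 3, 0, 2018, "AD"),
    "LDLR": (2, 8, 12, 0, 642, "AD"),
    "APOB": (1, 1, 2, 1, 2825, "AD"),
    "PCSK9": (0, 4, 3, 0, 2018, "AD"),
    "OTC": (1, 1, 0, 0, 3732, "XL"),
    "RYR1": (6, 4, 11, 1, 642, "AD"),
    "PTEN": (0, 1, 0, 0, 14125, "AD"),
}


def test_shipped_list_has_59_unique_genes():
    entries = load_acmg_sf_list()
    assert len(entries) == 59
    assert len({e.gene for e in entries}) == 59
    assert {e.gene for e in entries} >= set(PUBLISHED_SF_COUNTS)


@pytest.mark.parametrize("gene", sorted(PUBLISHED_SF_COUNTS))
def test_published_carrier_rate_display_arithmetic(gene):
    """Round-half-up(denominator / carriers) reproduces every printed CR cell."""
    pf, df, pm, dm, printed, inheritance = PUBLISHED_SF_COUNTS[gene]
    carriers = pf + df + pm + dm
    denominator = STUDY.n_female if inheritance == "XL" else STUDY.n_total
    assert display_denominator(denominator, carriers) == printed


def _cohort(n_per_subgroup=5):
    comp = CohortComposition(n_per_subgroup, n_per_subgroup,
                            n_per_subgroup, n_per_subgroup)
    sex, group = {}, {}
    i = 0
    for g in ("patient", "donor"):
        for s in ("female", "male"):
            for _ in range(n_per_subgroup):
                ind = f"I{i}"
                sex[ind], group[ind] = s, g
                i += 1
    return comp, sex, group


class TestScreen:
    def test_demotion_of_common_dominant_variant(self):
        comp, sex, group = _cohort()
        call = make_call(individual_id="I0", gene="BRCA2",
                         variant_key="BRCA2:c.1G>A", population_maf=0.006)
        result = screen_secondary_findings([call], load_acmg_sf_list(), comp,
                                           sex, group)
        assert result.rows == [] and result.positives == set()

    def test_rare_dominant_variant_counted(self):
        comp, sex, group = _cohort()
        call = make_call(individual_id="I0", gene="BRCA2",
                         variant_key="BRCA2:c.1G>A", population_maf=0.004)
        result = screen_secondary_findings([call], load_acmg_sf_list(), comp,
                                           sex, group)
        [row] = result.rows
        assert row.gene == "BRCA2"
        assert row.counts["patient_female"] == 1
        assert result.positives == {"I0"}

    def test_demotion_monotonic_in_threshold(self):
        comp, sex, group = _cohort()
        calls = [
            make_call(individual_id=f"I{i}", gene="BRCA2",
                      variant_key=f"BRCA2:c.{i}G>A", population_maf=m)
            for i, m in enumerate([0.0001, 0.003, 0.004, 0.0049])
        ]
        sf = load_acmg_sf_list()
        prev = None
        for cutoff in (0.005, 0.004, 0.003, 0.0001, 0.0):
            pos = screen_secondary_findings(calls, sf, comp, sex, group,
                                            ad_maf_max=cutoff).positives
            if prev is not None:
                assert pos <= prev
            prev = pos

    def test_xl_gene_counts_females_over_female_denominator(self):
        comp, sex, group = _cohort()
        female = make_call(individual_id="I0", gene="OTC",
                           variant_key="OTC:c.1G>A")
        male = make_call(individual_id="I5", gene="OTC",
                         variant_key="OTC:c.1G>A")
        result = screen_secondary_findings([female, male], load_acmg_sf_list(),
                                           comp, sex, group)
        [row] = result.rows
        assert row.n_carriers == 1
        assert row.display_cr == f"1/{round_half_up(comp.n_female / 1)}"

    def test_individual_with_two_variants_counts_once_per_gene(self):
        comp, sex, group = _cohort()
        calls = [
            make_call(individual_id="I0", gene="BRCA2", variant_key="BRCA2:c.1G>A"),
            make_call(individual_id="I0", gene="BRCA2", variant_key="BRCA2:c.2G>A"),
        ]
        result = screen_secondary_findings(calls, load_acmg_sf_list(), comp,
                                           sex, group)
        assert result.rows[0].n_carriers == 1
        assert result.multi_positive == {"I0"}
        assert result.n_unique_variants == 2 and result.n_occurrences == 2

    def test_sf_classification_channel_preferred(self):
        comp, sex, group = _cohort()
        # carrier-screen VUS, but the independent SF classifier calls it P
        call = make_call(individual_id="I0", gene="BRCA2",
                         variant_key="BRCA2:c.1G>A", classification="VUS",
                         sf_classification="P")
        result = screen_secondary_findings([call], load_acmg_sf_list(), comp,
                                           sex, group)
        assert result.positives == {"I0"}

    def test_positives_independent_of_subgroup_labels(self):
        comp, sex, group = _cohort()
        calls = [make_call(individual_id=f"I{i}", gene="BRCA2",
                           variant_key="BRCA2:c.1G>A") for i in range(4)]
        sf = load_acmg_sf_list()
        base = screen_secondary_findings(calls, sf, comp, sex, group).positives
        flipped = {i: ("donor" if g == "patient" else "patient")
                   for i, g in group.items()}
        assert screen_secondary_findings(calls, sf, comp, sex, flipped).positives == base

    def test_missing_sf_gene_warns_not_errors(self):
        comp, sex, group = _cohort()
        result = screen_secondary_findings([], load_acmg_sf_list(), comp, sex,
                                           group, annotated_genes={"CFTR"})
        assert result.warnings


class TestBiallelicCheck:
    def test_homozygote_flagged(self):
        call = make_call(individual_id="I1", gene="MUTYH",
                         variant_key="MUTYH:c.1G>A", zygosity="homozygous")
        [f] = biallelic_recessive_sf_check([call])
        assert f.kind == "homozygous"

    def test_single_het_not_flagged(self):
        call = make_call(individual_id="I1", gene="ATP7B",
                         variant_key="ATP7B:c.1G>A")
        assert biallelic_recessive_sf_check([call]) == []

    def test_two_distinct_hets_flagged_as_potential_compound(self):
        calls = [
            make_call(individual_id="I1", gene="ATP7B", variant_key="ATP7B:c.1G>A"),
            make_call(individual_id="I1", gene="ATP7B", variant_key="ATP7B:c.2G>A"),
        ]
        [f] = biallelic_recessive_sf_check(calls)
        assert f.kind == "potential_compound_het"
        assert f.variant_keys == ("ATP7B:c.1G>A", "ATP7B:c.2G>A")

    def test_clean_cohort_yields_no_findings(self):
        calls = [make_call(individual_id=f"I{i}", gene="MUTYH",
                           variant_key="MUTYH:c.1G>A") for i in range(20)]
        assert biallelic_recessive_sf_check(calls) == []
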