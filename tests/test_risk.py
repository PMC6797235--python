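"""Fetal-disease-risk models and the Monte Carlo mating oracle."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from pcscreen.risk import (
    AlphaThalInput,
    ExpansionTable,
    FdrEstimate,
    aggregate_fdr,
    contribution_breakdown,
    default_expansion_table,
    fdr_alpha_thalassemia,
    fdr_autosomal_recessive,
    fdr_fmr1_expansion,
    fdr_x_linked,
    simulate_conception_risk,
)


def mc_tolerance(p: float, n: int) -> float:
    """Three binomial standard errors on an affected fraction."""
    return 3 * math.sqrt(p * (1 - p) / n)


class TestClosedForms:
    def test_ar_published_value(self):
        assert fdr_autosomal_recessive(1 / 125, 1 / 125) == pytest.approx(0.000016)

    def test_ar_zero(self):
        assert fdr_autosomal_recessive(0.0, 0.0) == 0.0

    def test_xl_published_values(self):
        assert fdr_x_linked(1 / 3732) == pytest.approx(6.69882e-5, rel=1e-5)
        assert fdr_x_linked(1 / 1244) == pytest.approx(0.000200965, rel=1e-5)

    def test_xl_zero(self):
        assert fdr_x_linked(0.0) == 0.0

    def test_inclusion_threshold_identity(self):
        # carrier frequency 1/500 sits exactly on the 1-in-a-million
        # prevalence threshold used for panel inclusion
        assert fdr_autosomal_recessive(1 / 500, 1 / 500) == 1e-6

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(ValueError):
            fdr_x_linked(1.2)


class TestFmr1:
    def test_degenerates_to_x_linked_when_expansion_certain(self):
        table = ExpansionTable(bins=((55, 200, 1.0),))
        fdr = fdr_fmr1_expansion({(55, 200): 1 / 146}, table)
        assert fdr == pytest.approx(1 / 584)

    def test_zero_expansion_probability(self):
        table = ExpansionTable(bins=((55, 200, 0.0),))
        assert fdr_fmr1_expansion({(55, 200): 1 / 146}, table) == 0.0

    def test_pooled_round_trip_of_published_value(self):
        # the published fragile-X risk implies a mean expansion probability
        # of fdr * 4 * 146 over a pooled 1/146 premutation carrier rate;
        # feeding that probability back must reproduce the printed risk
        published = 0.000176459
        mean_p = published * 4 * 146
        table = ExpansionTable(bins=((55, 200, mean_p),))
        assert fdr_fmr1_expansion({(55, 200): 1 / 146}, table) == pytest.approx(
            published, rel=1e-9
        )

    def test_missing_bin_rejected(self):
        table = ExpansionTable(bins=((55, 59, 0.04),))
        with pytest.raises(KeyError):
            fdr_fmr1_expansion({(60, 64): 0.001}, table)

    def test_shipped_table_covers_premutation_range(self):
        table = default_expansion_table()
        assert table.probability(55) < table.probability(90)
        for cgg in (55, 70, 100, 200):
            assert 0.0 <= table.probability(cgg) <= 1.0


class TestAlphaThalassemia:
    def test_zero_single_deletion_rate(self):
        assert fdr_alpha_thalassemia(AlphaThalInput(0.0, 0.01)) == 0.0

    def test_hand_arithmetic(self):
        assert fdr_alpha_thalassemia(AlphaThalInput(0.02, 0.005)) == pytest.approx(2.5e-5)

    def test_monte_carlo_agreement(self):
        inp = AlphaThalInput(0.02, 0.005)
        expected = fdr_alpha_thalassemia(inp)
        n = 10_000_000
        observed = simulate_conception_risk(inp, "HBA", n, seed=5)
        assert abs(observed - expected) < mc_tolerance(expected, n)


class TestMatingOracle:
    def test_all_carriers_limit(self):
        assert simulate_conception_risk(1.0, "AR", 100_000, seed=1) == pytest.approx(
            0.25, abs=0.01
        )

    def test_xl_closed_form(self):
        n = 1_000_000
        observed = simulate_conception_risk(0.01, "XL", n, seed=2)
        assert abs(observed - 0.0025) < mc_tolerance(0.0025, n)

    def test_ar_closed_form(self):
        n = 1_000_000
        observed = simulate_conception_risk(0.02, "AR", n, seed=3)
        assert abs(observed - 1e-4) < mc_tolerance(1e-4, n)

    def test_fmr1_closed_form(self):
        table = ExpansionTable(bins=((55, 69, 0.05), (70, 200, 0.5)))
        freqs = {(55, 69): 0.005, (70, 200): 0.001}
        expected = fdr_fmr1_expansion(freqs, table)
        n = 4_000_000
        observed = simulate_conception_risk((freqs, table), "FMR1", n, seed=4)
        assert abs(observed - expected) < mc_tolerance(expected, n)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            simulate_conception_risk(0.01, "AD", 10, seed=1)


class TestAggregation:
    def test_sum_and_display(self):
        ests = [
            FdrEstimate("G1", "c1", "AR", 1e-6, severity=3),
            FdrEstimate("G2", "c2", "AR", 2e-6, severity=3),
        ]
        agg = aggregate_fdr(ests, min_severity=3)
        assert agg.fdr == pytest.approx(3e-6)
        assert agg.display == "1/333333"

    def test_empty_selection(self):
        assert aggregate_fdr([], min_severity=1).fdr == 0.0

    def test_severity_floor(self):
        ests = [
            FdrEstimate("G1", "c", "AR", 1e-4, severity=1),
            FdrEstimate("G2", "c", "AR", 1e-4, severity=3),
        ]
        assert aggregate_fdr(ests, min_severity=2).fdr == pytest.approx(1e-4)

    def test_partition_linearity(self):
        ests = [
            FdrEstimate(f"G{i}", "c", "AR", (i + 1) * 1e-6, severity=3)
            for i in range(10)
        ]
        whole = aggregate_fdr(ests).fdr
        parts = aggregate_fdr(ests[:4]).fdr + aggregate_fdr(ests[4:]).fdr
        assert whole == pytest.approx(parts)


class TestContributionBreakdown:
    def test_single_gene_is_everything(self):
        report = contribution_breakdown([FdrEstimate("G1", "c", "AR", 1e-4)])
        assert report.per_gene_pct == {"G1": pytest.approx(100.0)}

    def test_top_six_combined_risk(self):
        # the six largest published contributions, as shares of the
        # severe-plus aggregate of 1/522, jointly represent ~1 in 823
        shares = [16.35, 13.26, 9.51, 9.21, 7.70, 7.38]
        aggregate = 1 / 522
        combined = sum(s / 100 * aggregate for s in shares)
        assert round(1 / combined) == 823

    def test_planted_x_linked_share_recovered(self):
        ests = [
            FdrEstimate("GX", "c", "XL", 4e-5),
            FdrEstimate("GA", "c", "AR", 6e-5),
        ]
        report = contribution_breakdown(ests)
        assert report.x_linked_pct == pytest.approx(40.0)

    def test_rare_condition_share(self):
        ests = [
            FdrEstimate("RARE", "c", "AR", 1e-5, carrier_rate=1 / 200),
            FdrEstimate("COMMON", "c", "AR", 3e-5, carrier_rate=1 / 50),
        ]
        report = contribution_breakdown(ests)
        assert report.rare_condition_pct == pytest.approx(25.0)

    def test_shares_partition_to_100(self):
        ests = [
            FdrEstimate(f"G{i}", "c", "AR", (i + 1) * 1e-6) for i in range(7)
        ]
        report = contribution_breakdown(ests)
        assert sum(report.per_gene_pct.values()) == pytest.approx(100.0, abs=0.1)

    def test_zero_aggregate_rejected(self):
        with pytest.raises(ValueError):
            contribution_breakdown([FdrEstimate("G", "c", "AR", 0.0)])


class TestMonotonicity:
    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
    )
    def test_ar_fdr_non_decreasing_in_each_rate(self, a, b, delta):
        hi = min(1.0, a + delta)
        assert fdr_autosomal_recessive(hi, b) >= fdr_autosomal_recessive(a, b)
        assert fdr_autosomal_recessive(b, hi) >= fdr_autosomal_recessive(b, a)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0, 0.5), st.floats(0, 0.5))
    def test_xl_fdr_non_decreasing(self, a, delta):
        assert fdr_x_linked(min(1.0, a + delta)) >= fdr_x_linked(a)
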