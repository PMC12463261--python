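"""Disproportionality statistics: 2x2 construction, IC, ROR, aggregation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mednorm.fixtures import NoiseModel, SignalSpec, gen_reports
from mednorm.signals import (
    ContingencyTable,
    ReportRecord,
    compare_aggregation,
    contingency,
    information_component,
    reporting_odds_ratio,
    signal_stats,
)


def _rep(rid, drugs=(), events=()):
    return ReportRecord(rid, frozenset(drugs), frozenset(events))


class TestContingency:
    def test_enumerable_four_reports(self):
        reports = [
            _rep("1", {"D"}, {"E"}),
            _rep("2", {"D"}),
            _rep("3", events={"E"}),
            _rep("4"),
        ]
        t = contingency(reports, "D", "E")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
        assert t.n_total == 4

    def test_absent_drug_gives_zero_margin(self):
        t = contingency([_rep("1", events={"E"})], "D", "E")
        assert (t.a, t.b) == (0, 0)

    def test_report_based_unit_deduplicates(self):
        # a report is one unit regardless of repeated mentions: sets
        once = contingency([_rep("1", {"D"}, {"E"})], "D", "E")
        twice = contingency(
            [ReportRecord("1", frozenset({"D", "D"}), frozenset({"E", "E"}))],
            "D", "E",
        )
        assert once == twice

    def test_empty_reports_rejected(self):
        with pytest.raises(ValueError):
            contingency([], "D", "E")


class TestInformationComponent:
    def test_closed_form_a20_e2(self):
        ic, ic025, ic975 = information_component(
            ContingencyTable(20, 80, 180, 9720)
        )
        assert ic == pytest.approx(math.log2(20.5 / 2.5))
        assert round(ic, 4) == 3.0356
        assert round(ic025, 4) == 2.2852

    def test_closed_form_a3_e1(self):
        ic, ic025, _ = information_component(
            ContingencyTable(3, 47, 1997, 97953)
        )
        assert round(ic, 4) == 1.2224
        assert ic025 == pytest.approx(-0.84697, abs=1e-4)

    def test_zero_when_observed_equals_expected(self):
        # margins 100 and 1000 over 10000 give E = 10 = a
        t = ContingencyTable(10, 90, 990, 8910)
        assert t.expected == 10
        assert information_component(t)[0] == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            information_component(ContingencyTable(0, 0, 0, 0))

    def test_monotone_in_a_with_margins_fixed(self):
        # same margins and total, increasing observed count
        ics = []
        for a in range(0, 21, 5):
            t = ContingencyTable(a, 100 - a, 200 - a, 9700 + a)
            ics.append(information_component(t)[0])
        assert ics == sorted(ics)

    @settings(max_examples=200, deadline=None)
    @given(
        a=st.integers(0, 50), b=st.integers(0, 200),
        c=st.integers(0, 200), d=st.integers(1, 5000),
    )
    def test_credibility_bounds_bracket_point(self, a, b, c, d):
        ic, ic025, ic975 = information_component(ContingencyTable(a, b, c, d))
        assert ic025 < ic < ic975


class TestROR:
    def test_closed_form(self):
        ror, low, high, corrected = reporting_odds_ratio(
            ContingencyTable(10, 90, 20, 880)
        )
        assert round(ror, 3) == 4.889
        assert low == pytest.approx(2.220, abs=5e-4)
        assert high == pytest.approx(10.767, abs=5e-4)
        assert not corrected

    def test_balanced_table_is_null(self):
        ror, low, high, _ = reporting_odds_ratio(ContingencyTable(10, 10, 10, 10))
        assert ror == 1.0
        assert low < 1.0 < high

    def test_zero_cell_haldane_correction(self):
        ror, low, high, corrected = reporting_odds_ratio(
            ContingencyTable(0, 50, 50, 900)
        )
        assert corrected
        assert ror == pytest.approx((0.5 * 900.5) / (50.5 * 50.5))
        assert ror < 1.0

    def test_two_empty_margins_rejected(self):
        with pytest.raises(ValueError):
            reporting_odds_ratio(ContingencyTable(0, 0, 0, 10))

    @settings(max_examples=200, deadline=None)
    @given(
        a=st.integers(0, 50), b=st.integers(0, 100),
        c=st.integers(0, 100), d=st.integers(1, 1000),
    )
    def test_swap_invariance(self, a, b, c, d):
        """ROR is unchanged by swapping a<->d and b<->c."""
        t1 = ContingencyTable(a, b, c, d)
        t2 = ContingencyTable(d, c, b, a)
        margins = [a + b, c + d, a + c, b + d]
        if sum(m == 0 for m in margins) >= 2:
            return
        r1 = reporting_odds_ratio(t1)
        r2 = reporting_odds_ratio(t2)
        assert r1[0] == pytest.approx(r2[0])
        assert r1[1] == pytest.approx(r2[1])


class TestSdrFlags:
    def test_flags_follow_lower_bounds(self):
        strong = signal_stats(ContingencyTable(30, 470, 1970, 97530))
        assert strong.ic025 > 0 and strong.sdr_ic
        weak = signal_stats(ContingencyTable(3, 47, 1997, 97953))
        assert weak.ic025 < 0 and not weak.sdr_ic
        assert weak.sdr_ror == (weak.ror_low > 1)


class TestAggregation:
    def test_fragmented_signal_appears_only_after_aggregation(self):
        """Ten variants each observed 3 times show no SDR, while the
        aggregated count of 30 does: the dilution mechanism that name
        standardization reverses."""
        spec = SignalSpec(
            drug_key="mesalamine", event_key="asthenia",
            n_reports=100_000, target_a=30,
            drug_margin=500, event_margin=2000, n_variants=10,
        )
        reports, variant_map, expected, variants = gen_reports(
            spec, NoiseModel(p_typo=1.0, rng_seed=42)
        )
        comparison = compare_aggregation(reports, variant_map, "asthenia")
        assert len(comparison.per_variant) == 10
        for stats in comparison.per_variant.values():
            assert stats.n == 3
            assert round(stats.ic025, 4) == pytest.approx(-0.8470, abs=1e-4)
            assert not stats.sdr_ic
        agg = comparison.aggregated["mesalamine"]
        assert agg.n == 30
        assert round(agg.ic025, 4) == pytest.approx(0.9290, abs=1e-4)
        assert agg.sdr_ic
        assert comparison.aggregated_tables["mesalamine"] == expected

    def test_identity_map_equals_single_variant(self):
        reports = [
            _rep("1", {"D"}, {"E"}), _rep("2", {"D"}),
            _rep("3", events={"E"}), _rep("4"), _rep("5"),
        ]
        comparison = compare_aggregation(reports, {"D": "D"}, "E")
        assert comparison.per_variant["D"] == comparison.aggregated["D"]

    def test_aggregated_a_sums_disjoint_variants(self):
        reports = [
            _rep("1", {"v1"}, {"E"}), _rep("2", {"v2"}, {"E"}),
            _rep("3", {"v1"}), _rep("4"), _rep("5"),
        ]
        comparison = compare_aggregation(
            reports, {"v1": "D", "v2": "D"}, "E"
        )
        assert comparison.aggregated_tables["D"].a == 2  # 1 + 1
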