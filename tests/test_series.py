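"""Imputation, reconciliation, and assembly of the global annual series."""

import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

import heatcount as hc
from heatcount.errors import CoverageError, RuleConflictError, RuleError

HEADER = "company,brand,year,users_millions,sticks_billions,report_vintage,notes\n"


def small_panel(rows, companies, years):
    return hc.load_panel(io.StringIO(HEADER + rows), companies=companies, years=years)


class TestImputation:
    def test_launch_zero_cells(self, prepared_panel):
        assert prepared_panel.users("PMI", 2014) == 0.0
        assert prepared_panel.users("PMI", 2015) == 0.0
        assert prepared_panel.users("BAT", 2016) == 0.0
        assert prepared_panel.sticks("BAT", 2016) == 0.0

    def test_share_carry_fills_missing_sticks(self, prepared_panel):
        # 2.5% global share against the other firms' 71.2 billion sticks
        expected = 0.025 / 0.975 * 71.2e9
        assert prepared_panel.sticks("JT", 2019) == pytest.approx(expected, rel=1e-9)
        assert prepared_panel.sticks("JT", 2019) == pytest.approx(1.826e9, rel=1e-3)

    def test_imputed_cells_are_flagged(self, prepared_panel):
        assert prepared_panel.frame.loc[("JT", 2019), "sticks_origin"] == "imputed:share_carry"
        assert prepared_panel.frame.loc[("PMI", 2014), "users_origin"] == "imputed:launch_zero"
        assert any("share_carry: JT 2019" in line for line in prepared_panel.log)

    def test_rule_on_non_missing_cell_conflicts(self, panel):
        rules = hc.ImputationRuleSet(launch_zero=[("PMI", 2016)])
        with pytest.raises(RuleConflictError):
            hc.impute_panel(panel, rules)
        # explicit override is allowed
        out = hc.impute_panel(panel, rules, override=True)
        assert out.users("PMI", 2016) == 0.0

    def test_rule_on_unknown_cell_is_error(self, panel):
        with pytest.raises(RuleError):
            hc.impute_panel(panel, hc.ImputationRuleSet(launch_zero=[("PMI", 1999)]))

    def test_split_carry_scales_total_to_domestic(self):
        p = small_panel("A,a,2020,N/A,10.0,,\n", ["A"], [2020])
        rule = hc.SplitCarryRule(
            company="A", source_year=2021, target_years=(2020,),
            source_domestic=3.7e9, source_total=7.4e9,
        )
        out = hc.impute_panel(p, hc.ImputationRuleSet(split_carry=[rule]))
        assert out.sticks("A", 2020) == pytest.approx(5.0e9)

    def test_inventory_unchanged_by_imputation(self, panel, prepared_panel):
        # classification keys on provenance, so imputing does not inflate it
        before = hc.inventory_stats(panel)
        after = hc.inventory_stats(prepared_panel)
        assert before.to_dict() == after.to_dict()


class TestReconciliation:
    rule = hc.ReconciliationRule("PMI", "KT&G", 2021)

    def test_flags_absorbed_company_domestic_only(self, panel, config):
        out = hc.reconcile_overlap(panel, self.rule)
        for year in range(2021, 2025):
            assert bool(out.frame.loc[("KT&G", year), "domestic_only"])
        assert not bool(out.frame.loc[("KT&G", 2020), "domestic_only"])
        # absorbing company's reported totals untouched
        assert out.users("PMI", 2024) == panel.users("PMI", 2024)

    def test_idempotent(self, panel):
        once = hc.reconcile_overlap(panel, self.rule)
        twice = hc.reconcile_overlap(once, self.rule)
        assert twice.frame.drop(columns="notes").equals(once.frame.drop(columns="notes"))

    def test_vacuous_beyond_panel_end(self, panel):
        out = hc.reconcile_overlap(panel, hc.ReconciliationRule("PMI", "KT&G", 2030))
        assert out.frame.equals(panel.frame)

    def test_effective_before_panel_window_is_error(self, panel):
        with pytest.raises(RuleError):
            hc.reconcile_overlap(panel, hc.ReconciliationRule("PMI", "KT&G", 2000))

    def test_absorbed_reported_users_are_dropped(self):
        p = small_panel(
            "A,a,2021,10.0,5.0,,\nB,b,2021,3.0,0.0,,\n", ["A", "B"], [2021]
        )
        out = hc.reconcile_overlap(p, hc.ReconciliationRule("A", "B", 2021))
        # B's global user count is subsumed in A's; with zero domestic sticks
        # it contributes nothing from the effective year
        assert out.users("B", 2021) is None
        assert out.sticks("B", 2021) == 0.0


class TestPrimarySeries:
    def test_2024_total_near_published(self, prepared_panel, config):
        points = hc.build_primary_series(prepared_panel, config.conversion_assumptions())
        last = points[-1]
        assert last.year == 2024
        assert last.total_central == pytest.approx(49.38e6, rel=1e-3)
        assert last.total_lower == pytest.approx(45.89e6, rel=1e-3)
        assert last.total_upper == pytest.approx(52.87e6, rel=1e-3)

    def test_methods_in_2024(self, prepared_panel, config):
        points = hc.build_primary_series(prepared_panel, config.conversion_assumptions())
        per = points[-1].per_company
        assert per["PMI"].method is hc.EstimateMethod.REPORTED
        assert per["PMI"].central == pytest.approx(32.2e6)
        assert per["KT&G"].method is hc.EstimateMethod.CONVERTED
        assert per["KT&G"].central == pytest.approx(1.895e6, rel=1e-3)

    def test_non_decreasing_trajectory(self, prepared_panel, config):
        points = hc.build_primary_series(prepared_panel, config.conversion_assumptions())
        centrals = [p.total_central for p in points]
        assert centrals == sorted(centrals)

    def test_all_reported_panel_has_degenerate_bounds(self):
        p = small_panel("A,a,2020,5.0,1.0,,\nA,a,2021,6.0,1.2,,\n", ["A"], [2020, 2021])
        points = hc.build_primary_series(
            p, [hc.ConsumptionAssumption(frozenset({"A"}), 7.3)]
        )
        for point in points:
            assert point.total_lower == point.total_central == point.total_upper

    def test_uncovered_cell_is_hard_error(self):
        p = small_panel("A,a,2020,N/A,N/A,,\n", ["A"], [2020])
        with pytest.raises(CoverageError, match="2020"):
            hc.build_primary_series(p, [hc.ConsumptionAssumption(frozenset({"A"}), 7.3)])

    def test_additivity(self, prepared_panel, config):
        for point in hc.build_primary_series(prepared_panel, config.conversion_assumptions()):
            assert point.total_central == sum(e.central for e in point.per_company.values())
            assert point.total_lower == sum(e.lower for e in point.per_company.values())
            assert point.total_upper == sum(e.upper for e in point.per_company.values())


class TestAlternativeSeries:
    def test_2024_total_near_published(self, prepared_panel, config):
        points = hc.build_alternative_series(prepared_panel, config.literature)
        last = points[-1]
        assert last.total_central == pytest.approx(68.72e6, rel=1e-3)
        assert last.total_lower == pytest.approx(60.66e6, rel=1e-3)
        assert last.total_upper == pytest.approx(79.25e6, rel=1e-3)

    def test_exceeds_primary_on_fixture_2024(self, prepared_panel, config):
        prim = hc.build_primary_series(prepared_panel, config.conversion_assumptions())
        alt = hc.build_alternative_series(prepared_panel, config.literature)
        assert alt[-1].total_central > prim[-1].total_central

    def test_zero_shipment_year(self, prepared_panel, config):
        first = hc.build_alternative_series(prepared_panel, config.literature)[0]
        assert first.year == 2014
        assert (first.total_lower, first.total_central, first.total_upper) == (0, 0, 0)

    @given(fake_users_millions=st.floats(0.1, 100))
    def test_ignores_reported_user_counts(self, prepared_panel, config, fake_users_millions):
        """Perturbing any reported user count leaves the series bit-identical."""
        baseline = hc.build_alternative_series(prepared_panel, config.literature)
        perturbed_panel = prepared_panel.copy()
        perturbed_panel.frame.loc[("PMI", 2024), "users"] = fake_users_millions * 1e6
        perturbed = hc.build_alternative_series(perturbed_panel, config.literature)
        assert [p.total_central for p in perturbed] == [p.total_central for p in baseline]
        assert [p.total_lower for p in perturbed] == [p.total_lower for p in baseline]

    def test_missing_sticks_is_hard_error(self, panel, config):
        # without imputation the fixture still has stick gaps
        with pytest.raises(CoverageError):
            hc.build_alternative_series(panel, config.literature)


class TestBreakdown:
    def test_long_format_totals_match_series(self, prepared_panel, config):
        points = hc.build_primary_series(prepared_panel, config.conversion_assumptions())
        table = hc.company_breakdown(points)
        yearly = table.groupby("year")["central"].sum()
        for point in points:
            assert yearly.loc[point.year] == pytest.approx(point.total_central)
        row = table[(table.company == "PMI") & (table.year == 2024)].iloc[0]
        assert row.method == "reported" and row.central == pytest.approx(32.2e6)

    def test_empty_series_gives_empty_table(self):
        table = hc.company_breakdown([])
        assert table.empty
        assert list(table.columns) == ["company", "year", "central", "lower", "upper", "method"]
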