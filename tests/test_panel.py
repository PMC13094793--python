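"""Disclosure panel loading, vintage selection, and inventory classification."""

import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

import heatcount as hc
from heatcount.errors import (
    AmbiguousVintageError,
    PanelParseError,
    PanelValidationError,
)

HEADER = "company,brand,year,users_millions,sticks_billions,report_vintage,notes\n"


def csv_panel(rows: str):
    return io.StringIO(HEADER + rows)


class TestLoadPanel:
    def test_canonical_units(self, panel):
        # 2.1 million users and 7.4 billion sticks become persons and units
        assert panel.users("PMI", 2016) == pytest.approx(2.1e6)
        assert panel.sticks("PMI", 2016) == pytest.approx(7.4e9)

    def test_na_parsed_as_missing_and_zero_as_value(self, panel):
        assert panel.users("JT", 2024) is None
        assert panel.sticks("JT", 2024) == pytest.approx(14.1e9)
        # explicit zeros are reported data, not gaps
        assert panel.users("KT&G", 2014) == 0.0
        assert panel.sticks("KT&G", 2014) == 0.0

    def test_rectangular_index(self, panel):
        assert len(panel) == 44
        assert panel.companies == ["PMI", "KT&G", "BAT", "JT"]
        assert panel.years == list(range(2014, 2025))

    def test_empty_file_gives_empty_panel(self):
        assert len(hc.load_panel(csv_panel(""))) == 0

    def test_malformed_numeric_names_row(self):
        with pytest.raises(PanelParseError, match="row 2"):
            hc.load_panel(csv_panel("PMI,IQOS,2016,abc,7.4,,\n"))

    def test_unknown_company_rejected(self):
        with pytest.raises(PanelValidationError, match="Acme"):
            hc.load_panel(csv_panel("Acme,x,2016,1.0,1.0,,\n"))

    def test_year_outside_window_rejected(self):
        with pytest.raises(PanelValidationError, match="2013"):
            hc.load_panel(csv_panel("PMI,IQOS,2013,1.0,1.0,,\n"))

    def test_negative_value_rejected(self):
        with pytest.raises(PanelValidationError):
            hc.load_panel(csv_panel("PMI,IQOS,2016,-1.0,1.0,,\n"))

    def test_custom_company_universe(self):
        p = hc.load_panel(
            csv_panel("Acme,x,2016,1.0,1.0,,\n"),
            companies=["Acme"],
            years=[2016],
        )
        assert p.users("Acme", 2016) == pytest.approx(1e6)


class TestVintageSelection:
    @staticmethod
    def rec(vintage, users):
        return hc.CompanyYearRecord("BAT", "glo", 2020, users, None, vintage)

    def test_latest_vintage_wins(self):
        chosen = hc.select_latest_vintage([self.rec("2023", 8.0e6), self.rec("2024", 8.6e6)])
        assert chosen.users == 8.6e6

    def test_single_record_is_identity(self):
        r = self.rec("2023", 8.0e6)
        assert hc.select_latest_vintage([r]) is r

    def test_undated_loses_to_dated(self):
        chosen = hc.select_latest_vintage([self.rec(None, 1.0e6), self.rec("2020", 2.0e6)])
        assert chosen.users == 2.0e6

    def test_tie_with_different_values_is_ambiguous(self):
        with pytest.raises(AmbiguousVintageError):
            hc.select_latest_vintage([self.rec("2024", 1.0e6), self.rec("2024", 2.0e6)])

    @given(st.permutations(range(4)))
    def test_order_independent(self, order):
        records = [self.rec(f"202{i}", float(i + 1) * 1e6) for i in range(4)]
        shuffled = [records[i] for i in order]
        assert hc.select_latest_vintage(shuffled).users == 4e6

    def test_vintage_resolution_during_load(self):
        p = hc.load_panel(
            csv_panel(
                "BAT,glo,2020,8.0,11.0,2023,\nBAT,glo,2020,8.6,11.0,2024,\n"
            )
        )
        assert p.users("BAT", 2020) == pytest.approx(8.6e6)


class TestInventory:
    def test_fixture_inventory_matches_published_counts(self, panel):
        inv = hc.inventory_stats(panel)
        assert (inv.n_total, inv.n_users_reported, inv.n_sticks_only, inv.n_neither) == (
            44, 25, 14, 5,
        )
        assert inv.n_any == 39
        assert inv.pct(inv.n_users_reported) == pytest.approx(56.8, abs=0.05)
        assert inv.pct(inv.n_any) == pytest.approx(88.6, abs=0.05)

    def test_single_cell_with_both_values(self):
        p = hc.load_panel(csv_panel("PMI,IQOS,2016,2.1,7.4,,\n"), years=[2016])
        inv = hc.inventory_stats(p)
        assert (inv.n_total, inv.n_users_reported, inv.n_sticks_only, inv.n_neither) == (
            4, 1, 0, 3,
        )

    def test_all_missing_panel(self):
        p = hc.load_panel(csv_panel("PMI,IQOS,2016,N/A,N/A,,\n"), years=[2016])
        inv = hc.inventory_stats(p)
        assert inv.n_neither == inv.n_total == 4

    @given(
        st.lists(
            st.tuples(
                st.one_of(st.none(), st.floats(0, 100)),
                st.one_of(st.none(), st.floats(0, 100)),
            ),
            min_size=1,
            max_size=24,
        )
    )
    def test_partition_sums_to_total(self, cells):
        records = [
            hc.CompanyYearRecord("PMI", "IQOS", 2014 + i % 11,
                                 None if u is None else u * 1e6,
                                 None if s is None else s * 1e9)
            for i, (u, s) in enumerate(cells[:11])
        ]
        p = hc.DisclosurePanel.from_records(records, companies=["PMI"])
        inv = hc.inventory_stats(p)
        assert inv.n_users_reported + inv.n_sticks_only + inv.n_neither == inv.n_total


one_decimal_m = st.one_of(
    st.none(), st.integers(0, 4000).map(lambda k: k / 10.0)
)


class TestRoundTrip:
    @given(st.lists(st.tuples(one_decimal_m, one_decimal_m), min_size=11, max_size=11))
    def test_write_reload_identity(self, cells):
        """One-decimal input units survive a write/reload cycle exactly."""
        records = [
            hc.CompanyYearRecord(
                "BAT", "glo", 2014 + i,
                None if u is None else u * 1e6,
                None if s is None else s * 1e9,
            )
            for i, (u, s) in enumerate(cells)
        ]
        p = hc.DisclosurePanel.from_records(records, companies=["BAT"])
        buf = io.StringIO()
        p.to_csv(buf)
        buf.seek(0)
        reloaded = hc.load_panel(buf, companies=["BAT"], years=p.years)
        assert reloaded.frame["users"].equals(p.frame["users"])
        assert reloaded.frame["sticks"].equals(p.frame["sticks"])

    def test_fixture_round_trip(self, panel):
        buf = io.StringIO()
        panel.to_csv(buf)
        buf.seek(0)
        reloaded = hc.load_panel(buf)
        assert reloaded.frame["users"].equals(panel.frame["users"])
        assert reloaded.frame["sticks"].equals(panel.frame["sticks"])
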