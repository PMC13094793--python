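"""Company-year disclosure panel: loading, validation, vintage selection, inventory.

The panel is the atomic input of the disclosure-based estimation: one row per
manufacturer per calendar year, holding the publicly reported user count (if
any) and the annual heated-stick shipment volume (if any). Input files carry
users in millions and sticks in billions, the display units of corporate
reports; internally everything is canonicalized to persons and stick units so
that mixed formulas never juggle scales.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousVintageError,
    PanelIntegrityError,
    PanelParseError,
    PanelValidationError,
)

#: The four manufacturers operating heated tobacco brands at material global
#: scale over 2014-2024 (Imperial Brands entered late, discloses nothing
#: product-specific, and is excluded by the inclusion criteria).
DEFAULT_COMPANIES: tuple[str, ...] = ("PMI", "KT&G", "BAT", "JT")

#: Study window: first commercial launch through the latest full year.
DEFAULT_YEARS: tuple[int, ...] = tuple(range(2014, 2025))

USERS_SCALE = 1e6  # input unit: millions of persons
STICKS_SCALE = 1e9  # input unit: billions of sticks

REQUIRED_COLUMNS = ("company", "brand", "year", "users_millions", "sticks_billions")

#: Origin tag for a value that came straight from a disclosure (incl. explicit
#: zeros, which count as reported data, not gaps).
REPORTED = "reported"
MISSING = "missing"


@dataclass(frozen=True)
class CompanyYearRecord:
    """One manufacturer's disclosures for one calendar year.

    ``users`` and ``sticks`` are canonical (persons, stick units) and ``None``
    when the company published nothing for that cell.
    """

    company: str
    brand: str
    year: int
    users: float | None
    sticks: float | None
    report_vintage: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.users is not None and self.users < 0:
            raise PanelValidationError(
                f"{self.company} {self.year}: negative user count {self.users}"
            )
        if self.sticks is not None and self.sticks < 0:
            raise PanelValidationError(
                f"{self.company} {self.year}: negative shipment volume {self.sticks}"
            )


@dataclass
class DataInventory:
    """Classification of every panel cell by data availability."""

    n_total: int
    n_users_reported: int
    n_sticks_only: int
    n_neither: int
    classification: Mapping[tuple[str, int], str] = field(default_factory=dict)

    @property
    def n_any(self) -> int:
        return self.n_total - self.n_neither

    def pct(self, count: int) -> float:
        return 100.0 * count / self.n_total if self.n_total else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_users_reported": self.n_users_reported,
            "n_sticks_only": self.n_sticks_only,
            "n_neither": self.n_neither,
            "n_any": self.n_any,
            "pct_users_reported": self.pct(self.n_users_reported),
            "pct_sticks_only": self.pct(self.n_sticks_only),
            "pct_neither": self.pct(self.n_neither),
            "pct_any": self.pct(self.n_any),
        }


class DisclosurePanel:
    """Rectangular company x year panel in canonical units.

    Backed by a :class:`pandas.DataFrame` indexed by ``(company, year)`` with
    columns ``brand, users, sticks, report_vintage, notes, users_origin,
    sticks_origin, domestic_only``. Origin columns distinguish reported values
    from rule-imputed ones so the data inventory and provenance logs survive
    imputation.
    """

    COLUMNS = (
        "brand",
        "users",
        "sticks",
        "report_vintage",
        "notes",
        "users_origin",
        "sticks_origin",
        "domestic_only",
    )

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise PanelIntegrityError(f"panel frame missing columns {sorted(missing)}")
        self.frame = frame

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[CompanyYearRecord],
        companies: Sequence[str] | None = None,
        years: Sequence[int] | None = None,
    ) -> "DisclosurePanel":
        """Build a rectangular panel; absent cells become double-missing.

        ``companies``/``years`` default to the ordered lists observed in the
        records (company order of first appearance, years as a contiguous
        range). The rectangular index is materialized even for pre-launch
        years so inventory denominators always count every company-year.
        """
        recs = list(records)
        if companies is None:
            seen: list[str] = []
            for r in recs:
                if r.company not in seen:
                    seen.append(r.company)
            companies = seen
        if years is None:
            if recs:
                lo = min(r.year for r in recs)
                hi = max(r.year for r in recs)
                years = list(range(lo, hi + 1))
            else:
                years = []
        index = pd.MultiIndex.from_product(
            [list(companies), list(years)], names=["company", "year"]
        )
        brands = {r.company: r.brand for r in recs if r.brand}
        frame = pd.DataFrame(
            {
                "brand": [brands.get(c, "") for c, _ in index],
                "users": np.nan,
                "sticks": np.nan,
                "report_vintage": None,
                "notes": "",
                "users_origin": MISSING,
                "sticks_origin": MISSING,
                "domestic_only": False,
            },
            index=index,
        )
        for r in recs:
            key = (r.company, r.year)
            if key not in frame.index:
                raise PanelIntegrityError(
                    f"record {key} outside the panel index {companies} x {years}"
                )
            frame.loc[key, "brand"] = r.brand
            frame.loc[key, "report_vintage"] = r.report_vintage
            frame.loc[key, "notes"] = r.notes
            if r.users is not None:
                frame.loc[key, "users"] = r.users
                frame.loc[key, "users_origin"] = REPORTED
            if r.sticks is not None:
                frame.loc[key, "sticks"] = r.sticks
                frame.loc[key, "sticks_origin"] = REPORTED
        return cls(frame)

    def copy(self) -> "DisclosurePanel":
        return DisclosurePanel(self.frame.copy())

    # -- accessors -----------------------------------------------------------

    @property
    def companies(self) -> list[str]:
        return list(self.frame.index.get_level_values("company").unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.frame.index.get_level_values("year").unique())

    def __len__(self) -> int:
        return len(self.frame)

    def cell(self, company: str, year: int) -> CompanyYearRecord:
        row = self.frame.loc[(company, year)]
        return CompanyYearRecord(
            company=company,
            brand=row["brand"],
            year=year,
            users=None if pd.isna(row["users"]) else float(row["users"]),
            sticks=None if pd.isna(row["sticks"]) else float(row["sticks"]),
            report_vintage=row["report_vintage"],
            notes=row["notes"],
        )

    def records(self) -> list[CompanyYearRecord]:
        return [self.cell(c, y) for c, y in self.frame.index]

    def users(self, company: str, year: int) -> float | None:
        v = self.frame.loc[(company, year), "users"]
        return None if pd.isna(v) else float(v)

    def sticks(self, company: str, year: int) -> float | None:
        v = self.frame.loc[(company, year), "sticks"]
        return None if pd.isna(v) else float(v)

    # -- I/O -----------------------------------------------------------------

    def to_input_frame(self) -> pd.DataFrame:
        """Panel in input units (millions/billions at one decimal, N/A gaps)."""
        out = []
        for (company, year), row in self.frame.iterrows():
            out.append(
                {
                    "company": company,
                    "brand": row["brand"],
                    "year": year,
                    "users_millions": (
                        "N/A" if pd.isna(row["users"]) else f"{row['users'] / USERS_SCALE:.1f}"
                    ),
                    "sticks_billions": (
                        "N/A" if pd.isna(row["sticks"]) else f"{row['sticks'] / STICKS_SCALE:.1f}"
                    ),
                    "report_vintage": row["report_vintage"] or "",
                    "notes": row["notes"] or "",
                }
            )
        return pd.DataFrame(out, columns=list(REQUIRED_COLUMNS) + ["report_vintage", "notes"])

    def to_csv(self, path) -> None:
        self.to_input_frame().to_csv(path, index=False)


def _parse_cell(raw: str, what: str, rowno: int) -> float | None:
    """Parse one numeric cell; 'N/A', 'NA' and blanks are missing."""
    text = (raw or "").strip()
    if text == "" or text.upper() in {"N/A", "NA"}:
        return None
    try:
        return float(text)
    except ValueError:
        raise PanelParseError(f"row {rowno}: malformed {what} value {raw!r}") from None


def select_latest_vintage(records: Sequence[CompanyYearRecord]) -> CompanyYearRecord:
    """Resolve revised disclosures for one company-year: latest vintage wins.

    Manufacturers revise historical figures in later reports; the analysis
    always keeps the most recently published number. Undated records lose to
    any dated record. Two records sharing the maximal vintage but disagreeing
    on values are an error — the rule offers no tiebreak.
    """
    recs = list(records)
    if not recs:
        raise PanelIntegrityError("select_latest_vintage needs at least one record")
    keys = {(r.company, r.year) for r in recs}
    if len(keys) > 1:
        raise PanelIntegrityError(f"records span multiple company-years: {sorted(keys)}")
    dated = [r for r in recs if r.report_vintage]
    pool = dated if dated else recs
    best_vintage = max((r.report_vintage or "") for r in pool)
    winners = [r for r in pool if (r.report_vintage or "") == best_vintage]
    values = {(r.users, r.sticks) for r in winners}
    if len(values) > 1:
        raise AmbiguousVintageError(
            f"{recs[0].company} {recs[0].year}: conflicting values at vintage "
            f"{best_vintage!r}: {sorted(values, key=str)}"
        )
    return winners[0]


def load_panel(
    source,
    companies: Sequence[str] | None = DEFAULT_COMPANIES,
    years: Sequence[int] | None = DEFAULT_YEARS,
) -> DisclosurePanel:
    """Load a disclosure CSV into a canonical rectangular panel.

    Parameters
    ----------
    source
        Path or file-like object with columns
        ``company, brand, year, users_millions, sticks_billions`` and optional
        ``report_vintage, notes``. ``N/A`` or blank means not disclosed; an
        explicit ``0.0`` is a reported zero, not a gap.
    companies, years
        The panel window. ``None`` infers both from the file (used for
        synthetic markets); the defaults enforce the four-manufacturer,
        2014-2024 study window and reject unknown companies or out-of-window
        years.

    Multiple rows for one company-year are resolved by
    :func:`select_latest_vintage`; exact duplicates of
    ``(company, year, vintage)`` with different values raise an integrity
    error via the ambiguity rule.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        raw = pd.read_csv(source, dtype=str, keep_default_na=False)
    else:
        raw = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing_cols = set(REQUIRED_COLUMNS) - set(raw.columns)
    if missing_cols:
        raise PanelParseError(f"input is missing columns {sorted(missing_cols)}")
    if raw.empty:
        return DisclosurePanel.from_records([], companies=[], years=[])

    records: list[CompanyYearRecord] = []
    for rowno, row in enumerate(raw.itertuples(index=False), start=2):
        company = row.company.strip()
        if companies is not None and company not in companies:
            raise PanelValidationError(f"row {rowno}: unknown company {company!r}")
        try:
            year = int(row.year)
        except ValueError:
            raise PanelParseError(f"row {rowno}: malformed year {row.year!r}") from None
        if years is not None and year not in years:
            raise PanelValidationError(
                f"row {rowno}: year {year} outside window {min(years)}-{max(years)}"
            )
        users_m = _parse_cell(row.users_millions, "users_millions", rowno)
        sticks_b = _parse_cell(row.sticks_billions, "sticks_billions", rowno)
        vintage = getattr(row, "report_vintage", "") or None
        if vintage is not None:
            vintage = vintage.strip() or None
        notes = getattr(row, "notes", "") or ""
        try:
            records.append(
                CompanyYearRecord(
                    company=company,
                    brand=row.brand.strip(),
                    year=year,
                    users=None if users_m is None else users_m * USERS_SCALE,
                    sticks=None if sticks_b is None else sticks_b * STICKS_SCALE,
                    report_vintage=vintage,
                    notes=notes,
                )
            )
        except PanelValidationError as exc:
            raise PanelValidationError(f"row {rowno}: {exc}") from None

    # vintage resolution per company-year
    by_cell: dict[tuple[str, int], list[CompanyYearRecord]] = {}
    for r in records:
        by_cell.setdefault((r.company, r.year), []).append(r)
    resolved = []
    for cell_records in by_cell.values():
        if len(cell_records) > 1:
            vintages = [r.report_vintage for r in cell_records]
            if len(vintages) != len(set(vintages)):
                dupes = {
                    (r.company, r.year, r.report_vintage)
                    for r in cell_records
                    if vintages.count(r.report_vintage) > 1
                }
                # identical values at a duplicated vintage are harmless; the
                # ambiguity check below rejects conflicting ones
                if len({(r.users, r.sticks) for r in cell_records}) > 1 and any(
                    v is None for _, _, v in dupes
                ):
                    raise PanelIntegrityError(
                        f"duplicate undated records for {sorted(dupes)}"
                    )
        resolved.append(select_latest_vintage(cell_records))

    return DisclosurePanel.from_records(resolved, companies=companies, years=years)


def inventory_stats(panel: DisclosurePanel) -> DataInventory:
    """Classify every company-year cell by what the manufacturer disclosed.

    A cell is *users-reported* when a user count was published (explicit zeros
    included), *sticks-only* when only shipments were, and *neither*
    otherwise. Classification keys on provenance, not current values, so an
    inventory taken after imputation still describes the raw disclosures.
    """
    classification: dict[tuple[str, int], str] = {}
    for (company, year), row in panel.frame.iterrows():
        if row["users_origin"] == REPORTED:
            cls = "users_reported"
        elif row["sticks_origin"] == REPORTED:
            cls = "sticks_only"
        else:
            cls = "neither"
        classification[(company, int(year))] = cls
    counts = pd.Series(classification.values()).value_counts() if classification else {}
    n_users = int(counts.get("users_reported", 0)) if len(classification) else 0
    n_sticks = int(counts.get("sticks_only", 0)) if len(classification) else 0
    n_neither = int(counts.get("neither", 0)) if len(classification) else 0
    return DataInventory(
        n_total=len(classification),
        n_users_reported=n_users,
        n_sticks_only=n_sticks,
        n_neither=n_neither,
        classification=classification,
    )


def load_bundled_panel() -> DisclosurePanel:
    """Load the packaged manufacturer-disclosure table (2014-2024)."""
    from importlib.resources import files

    data = files("heatcount.data").joinpath("table1_disclosures.csv").read_text()
    return load_panel(io.StringIO(data))
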