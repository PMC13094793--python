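"""Panel imputation, double-counting reconciliation, and global series assembly.

Two disclosure-based annual series are built from the same panel:

* the **primary** series uses manufacturer-reported user counts where
  published and converts shipments to users elsewhere, with +/-50% user-space
  sensitivity on every converted component;
* the **alternative** series ignores all reported user counts and converts
  every company's shipments under a single literature consumption parameter,
  bounding with that parameter's 95% CI.

Before either series is built the panel must be complete: launch-year zeros,
market-share carry rules and domestic-split carry rules fill the cells where
manufacturers disclosed nothing, and a reconciliation rule prevents one
company's user totals from double-counting another's licensed international
customers. Coverage failures are hard errors, never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .conversion import (
    ConsumptionAssumption,
    EstimateMethod,
    UserEstimate,
    sensitivity_bounds,
    sticks_to_users,
)
from .errors import ConfigurationError, CoverageError, RuleConflictError, RuleError
from .panel import DisclosurePanel


@dataclass(frozen=True)
class ShareCarryRule:
    """Fill a company's missing shipments from its assumed global market share.

    With share ``s`` of the global stick total (own volume included), the
    company's missing volume in a target year is ``s/(1-s)`` times the sum of
    the other companies' volumes that year.
    """

    company: str
    source_year: int
    target_years: tuple[int, ...]
    share: float

    def __post_init__(self) -> None:
        if not 0 < self.share < 1:
            raise RuleError(f"share must lie in (0, 1), got {self.share}")


@dataclass(frozen=True)
class SplitCarryRule:
    """Scale a total-market stick figure down to its domestic component.

    Used when a year's disclosure is a global total but the series needs the
    domestic part only: the domestic proportion observed in ``source_year``
    (``source_domestic / source_total``) is carried to the target years.
    """

    company: str
    source_year: int
    target_years: tuple[int, ...]
    source_domestic: float | None = None
    source_total: float | None = None

    def proportion(self) -> float:
        if not self.source_domestic or not self.source_total:
            raise RuleError(
                f"{self.company}: split-carry needs source-year domestic and "
                "total stick figures"
            )
        return self.source_domestic / self.source_total


@dataclass
class ImputationRuleSet:
    """All documented assumptions filling gaps in the disclosure panel."""

    launch_zero: list[tuple[str, int]] = field(default_factory=list)
    share_carry: list[ShareCarryRule] = field(default_factory=list)
    split_carry: list[SplitCarryRule] = field(default_factory=list)


@dataclass(frozen=True)
class ReconciliationRule:
    """One company's totals subsume another's international customers.

    From ``effective_from_year`` onward the absorbed company contributes only
    its domestic market: its shipments are flagged domestic-only and any user
    counts it reports are dropped rather than added on top of the absorbing
    company's totals.
    """

    absorbing_company: str
    absorbed_company: str
    effective_from_year: int
    domestic_market_retained: bool = True

    def __post_init__(self) -> None:
        if self.absorbing_company == self.absorbed_company:
            raise RuleError("a company cannot absorb itself")


def impute_panel(
    panel: DisclosurePanel,
    rules: ImputationRuleSet,
    override: bool = False,
) -> DisclosurePanel:
    """Apply the documented gap-filling assumptions to a validated panel.

    Launch-zero rules set users and sticks to zero for pre-launch years;
    split-carry rules rescale total-market figures to domestic-only; share
    carry rules fill missing shipment volumes from an assumed global share.
    Every imputed cell is tagged with its rule id and logged. A rule
    targeting a cell that already holds data raises
    :class:`~heatcount.errors.RuleConflictError` unless ``override`` is set.
    """
    out = panel.copy()
    frame = out.frame
    log: list[str] = list(getattr(panel, "log", []))

    for company, year in rules.launch_zero:
        if (company, year) not in frame.index:
            raise RuleError(f"launch-zero rule targets unknown cell ({company}, {year})")
        row = frame.loc[(company, year)]
        if (not pd.isna(row["users"]) or not pd.isna(row["sticks"])) and not override:
            raise RuleConflictError(
                f"launch-zero rule conflicts with disclosed data at ({company}, {year})"
            )
        frame.loc[(company, year), ["users", "sticks"]] = 0.0
        frame.loc[(company, year), "users_origin"] = "imputed:launch_zero"
        frame.loc[(company, year), "sticks_origin"] = "imputed:launch_zero"
        log.append(f"launch_zero: {company} {year} set to 0 users / 0 sticks")

    for rule in rules.split_carry:
        proportion = rule.proportion()
        for year in rule.target_years:
            if (rule.company, year) not in frame.index:
                raise RuleError(
                    f"split-carry rule targets unknown cell ({rule.company}, {year})"
                )
            total = frame.loc[(rule.company, year), "sticks"]
            if pd.isna(total):
                raise RuleError(
                    f"split-carry needs a total-market stick figure at "
                    f"({rule.company}, {year})"
                )
            frame.loc[(rule.company, year), "sticks"] = float(total) * proportion
            frame.loc[(rule.company, year), "sticks_origin"] = "imputed:split_carry"
            log.append(
                f"split_carry: {rule.company} {year} sticks scaled by "
                f"{proportion:.4f} (domestic share of {rule.source_year})"
            )

    for rule in rules.share_carry:
        for year in rule.target_years:
            if (rule.company, year) not in frame.index:
                raise RuleError(
                    f"share-carry rule targets unknown cell ({rule.company}, {year})"
                )
            if not pd.isna(frame.loc[(rule.company, year), "sticks"]) and not override:
                raise RuleConflictError(
                    f"share-carry rule conflicts with disclosed sticks at "
                    f"({rule.company}, {year})"
                )
            others = [
                panel_sticks
                for (c, y), panel_sticks in frame["sticks"].items()
                if y == year and c != rule.company and not pd.isna(panel_sticks)
            ]
            missing_others = [
                c
                for (c, y), panel_sticks in frame["sticks"].items()
                if y == year and c != rule.company and pd.isna(panel_sticks)
            ]
            if missing_others:
                raise RuleError(
                    f"share-carry for {rule.company} {year} needs all other "
                    f"companies' sticks; missing {missing_others}"
                )
            imputed = rule.share / (1.0 - rule.share) * sum(others)
            frame.loc[(rule.company, year), "sticks"] = imputed
            frame.loc[(rule.company, year), "sticks_origin"] = "imputed:share_carry"
            log.append(
                f"share_carry: {rule.company} {year} sticks = "
                f"{rule.share:.3%}/(1-{rule.share:.3%}) x {sum(others):.3e} = "
                f"{imputed:.3e} (share carried from {rule.source_year})"
            )

    out.log = log
    return out


def reconcile_overlap(panel: DisclosurePanel, rule: ReconciliationRule) -> DisclosurePanel:
    """Restrict the absorbed company to its domestic market from the rule's year.

    Idempotent: flags already-restricted cells are simply re-set. A rule whose
    effective year lies beyond the panel window is vacuous; one predating the
    panel window is an error.
    """
    companies = panel.companies
    for c in (rule.absorbing_company, rule.absorbed_company):
        if c not in companies:
            raise RuleError(f"reconciliation rule references unknown company {c!r}")
    years = panel.years
    if years and rule.effective_from_year < min(years):
        raise RuleError(
            f"reconciliation effective year {rule.effective_from_year} predates "
            f"the panel window starting {min(years)}"
        )
    out = panel.copy()
    log = list(getattr(panel, "log", []))
    for year in years:
        if year < rule.effective_from_year:
            continue
        key = (rule.absorbed_company, year)
        out.frame.loc[key, "domestic_only"] = True
        if not pd.isna(out.frame.loc[key, "users"]):
            out.frame.loc[key, "users"] = float("nan")
            out.frame.loc[key, "users_origin"] = "reconciled:dropped"
            log.append(
                f"reconcile: dropped {rule.absorbed_company} {year} reported users "
                f"(subsumed in {rule.absorbing_company} totals)"
            )
    log.append(
        f"reconcile: {rule.absorbed_company} restricted to domestic market from "
        f"{rule.effective_from_year} ({rule.absorbing_company} totals inclusive)"
    )
    out.log = log
    return out


@dataclass(frozen=True)
class GlobalSeriesPoint:
    """One year's global user total with bounds and per-company breakdown."""

    year: int
    total_central: float
    total_lower: float
    total_upper: float
    per_company: Mapping[str, UserEstimate]
    series_variant: str

    def __post_init__(self) -> None:
        if not (self.total_lower <= self.total_central <= self.total_upper):
            raise ValueError(f"year {self.year}: unordered totals")


def _point(year: int, estimates: dict[str, UserEstimate], variant: str) -> GlobalSeriesPoint:
    return GlobalSeriesPoint(
        year=year,
        total_central=sum(e.central for e in estimates.values()),
        total_lower=sum(e.lower for e in estimates.values()),
        total_upper=sum(e.upper for e in estimates.values()),
        per_company=estimates,
        series_variant=variant,
    )


def _scope_map(
    assumptions: Iterable[ConsumptionAssumption] | Mapping[str, ConsumptionAssumption],
) -> dict[str, ConsumptionAssumption]:
    if isinstance(assumptions, Mapping):
        return dict(assumptions)
    out: dict[str, ConsumptionAssumption] = {}
    for a in assumptions:
        for company in a.brand_scope:
            if company in out:
                raise ConfigurationError(f"company {company!r} covered by two assumptions")
            out[company] = a
    return out


def build_primary_series(
    panel: DisclosurePanel,
    assumptions: Iterable[ConsumptionAssumption] | Mapping[str, ConsumptionAssumption],
) -> list[GlobalSeriesPoint]:
    """Assemble the primary mixed reported/converted global series.

    Per company-year: a published user count is used as reported (no
    sensitivity); otherwise shipments are converted with the company's brand
    assumption and bounded per its mode. Cells resolving to neither raise
    :class:`~heatcount.errors.CoverageError` naming every offender.
    """
    amap = _scope_map(assumptions)
    points = []
    uncovered: list[tuple[str, int]] = []
    for year in panel.years:
        estimates: dict[str, UserEstimate] = {}
        for company in panel.companies:
            row = panel.frame.loc[(company, year)]
            users, sticks = row["users"], row["sticks"]
            if not pd.isna(users):
                method = (
                    EstimateMethod.IMPUTED_ZERO
                    if str(row["users_origin"]).startswith("imputed")
                    else EstimateMethod.REPORTED
                )
                estimates[company] = UserEstimate(
                    company, year, float(users), float(users), float(users), method
                )
            elif not pd.isna(sticks):
                assumption = amap.get(company)
                if assumption is None:
                    raise ConfigurationError(
                        f"no consumption assumption covers {company!r}"
                    )
                central = sticks_to_users(float(sticks), assumption)
                lower, upper = sensitivity_bounds(
                    central, EstimateMethod.CONVERTED, assumption
                )
                estimates[company] = UserEstimate(
                    company, year, central, lower, upper,
                    EstimateMethod.CONVERTED, assumption,
                )
            else:
                uncovered.append((company, year))
        if not uncovered:
            points.append(_point(year, estimates, "primary"))
    if uncovered:
        raise CoverageError(
            f"company-years with neither users nor sticks after imputation: {uncovered}"
        )
    return points


def build_alternative_series(
    panel: DisclosurePanel,
    literature: ConsumptionAssumption,
) -> list[GlobalSeriesPoint]:
    """Assemble the shipment-only series under the literature parameter.

    Every company-year's shipments are converted at the common central
    consumption; bounds come from re-conversion at the parameter's CI
    endpoints. Manufacturer-reported user counts are ignored entirely.
    """
    points = []
    uncovered: list[tuple[str, int]] = []
    for year in panel.years:
        estimates: dict[str, UserEstimate] = {}
        for company in panel.companies:
            sticks = panel.frame.loc[(company, year), "sticks"]
            if pd.isna(sticks):
                uncovered.append((company, year))
                continue
            central = sticks_to_users(float(sticks), literature)
            lower, upper = sensitivity_bounds(
                central, EstimateMethod.CONVERTED, literature
            )
            estimates[company] = UserEstimate(
                company, year, central, lower, upper,
                EstimateMethod.CONVERTED, literature,
            )
        if not uncovered:
            points.append(_point(year, estimates, "alternative"))
    if uncovered:
        raise CoverageError(
            f"company-years with no shipment volume after imputation: {uncovered}"
        )
    return points


def company_breakdown(series: Sequence[GlobalSeriesPoint]) -> pd.DataFrame:
    """Long-format per-company table (company, year, central, lower, upper, method)."""
    rows = [
        {
            "company": est.company,
            "year": point.year,
            "central": est.central,
            "lower": est.lower,
            "upper": est.upper,
            "method": est.method.value,
        }
        for point in series
        for est in point.per_company.values()
    ]
    return pd.DataFrame(
        rows, columns=["company", "year", "central", "lower", "upper", "method"]
    )


def series_frame(series: Sequence[GlobalSeriesPoint]) -> pd.DataFrame:
    """Wide annual table (year, total_central, total_lower, total_upper)."""
    return pd.DataFrame(
        [
            {
                "year": p.year,
                "total_central": p.total_central,
                "total_lower": p.total_lower,
                "total_upper": p.total_upper,
            }
            for p in series
        ],
        columns=["year", "total_central", "total_lower", "total_upper"],
    )
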