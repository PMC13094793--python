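"""Synthetic disclosure markets with known ground truth.

Emulates the structure of the manufacturer panel so every pipeline stage can
be exercised against a known answer: per-company user uptake follows a
logistic curve (launch, acceleration, saturation), shipments are users x
daily consumption x 365 with optional multiplicative lognormal noise, and a
disclosure mask hides users and/or sticks per company-year the way real
corporate reporting does. Masked values receive the same display rounding as
published figures (users to 0.1 million, sticks to 0.1 billion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import AlignmentError, ScenarioError
from .panel import CompanyYearRecord, DisclosurePanel, STICKS_SCALE, USERS_SCALE
from .series import GlobalSeriesPoint

Mask = Literal["both", "users_only", "sticks_only", "none"]
_MASKS = {"both", "users_only", "sticks_only", "none"}

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class CompanySpec:
    """Generative parameters for one synthetic manufacturer."""

    name: str
    launch_year: int
    carrying_capacity: float  # persons at saturation (K)
    growth_rate: float  # logistic rate r, per year
    midpoint_year: float  # inflection year t0
    consumption: float  # mean sticks per user per day
    brand: str = ""

    def __post_init__(self) -> None:
        if self.carrying_capacity < 0:
            raise ScenarioError(f"{self.name}: carrying capacity must be >= 0")
        if self.growth_rate <= 0:
            raise ScenarioError(f"{self.name}: growth rate must be positive")
        if self.consumption <= 0:
            raise ScenarioError(f"{self.name}: consumption must be positive")

    def users_at(self, year: int) -> float:
        if year < self.launch_year:
            return 0.0
        return self.carrying_capacity / (
            1.0 + math.exp(-self.growth_rate * (year - self.midpoint_year))
        )


@dataclass
class MarketScenario:
    """A complete synthetic market: companies, years, noise, disclosure mask."""

    companies: list[CompanySpec]
    years: tuple[int, ...]
    disclosure_pattern: Mapping[tuple[str, int], Mask]
    shipment_noise_sd: float = 0.05  # lognormal sigma on sticks; users are exact truth
    users_rounding: float = 0.1 * USERS_SCALE  # display grid for masked user counts
    sticks_rounding: float = 0.1 * STICKS_SCALE
    seed: int = 0

    def __post_init__(self) -> None:
        names = {c.name for c in self.companies}
        cells = {(c.name, y) for c in self.companies for y in self.years}
        for key, mask in self.disclosure_pattern.items():
            if mask not in _MASKS:
                raise ScenarioError(f"unknown disclosure mask {mask!r} at {key}")
            if key not in cells:
                raise ScenarioError(f"disclosure mask references unknown cell {key}")
        undefined = cells - set(self.disclosure_pattern)
        if undefined:
            raise ScenarioError(f"disclosure mask undefined for {sorted(undefined)}")
        if self.shipment_noise_sd < 0:
            raise ScenarioError("shipment noise sigma must be >= 0")
        _ = names


def uniform_pattern(
    companies: Sequence[str], years: Sequence[int], mask: Mask
) -> dict[tuple[str, int], Mask]:
    """The same disclosure mask for every company-year."""
    return {(c, y): mask for c in companies for y in years}


def _snap(value: float, grid: float, scale: float) -> float:
    """Round to the display grid, reproducing the CSV load arithmetic exactly.

    Published figures are printed in display units (millions/billions) at one
    decimal; computing the snapped value as display-units-float x scale makes
    a generated panel bit-identical to the same panel written out and
    reloaded.
    """
    if grid <= 0:
        return value
    return (round(value / grid) / (scale / grid)) * scale


def generate_market(scenario: MarketScenario) -> tuple[pd.DataFrame, DisclosurePanel]:
    """Generate (truth table, masked panel) for a scenario.

    The truth table carries exact users, noisy sticks and the true
    consumption per company-year; the masked panel is what the pipeline sees
    after partial disclosure and display rounding. Pure function of the
    scenario (including its seed).
    """
    rng = np.random.default_rng(scenario.seed)
    truth_rows = []
    records: list[CompanyYearRecord] = []
    for spec in scenario.companies:
        for year in scenario.years:
            users = spec.users_at(year)
            sticks = users * spec.consumption * DAYS_PER_YEAR
            if scenario.shipment_noise_sd > 0 and sticks > 0:
                sticks *= float(
                    rng.lognormal(mean=0.0, sigma=scenario.shipment_noise_sd)
                )
            truth_rows.append(
                {
                    "company": spec.name,
                    "year": year,
                    "users": users,
                    "sticks": sticks,
                    "consumption": spec.consumption,
                }
            )
            mask = scenario.disclosure_pattern[(spec.name, year)]
            records.append(
                CompanyYearRecord(
                    company=spec.name,
                    brand=spec.brand or spec.name.lower(),
                    year=year,
                    users=(
                        _snap(users, scenario.users_rounding, USERS_SCALE)
                        if mask in ("both", "users_only")
                        else None
                    ),
                    sticks=(
                        _snap(sticks, scenario.sticks_rounding, STICKS_SCALE)
                        if mask in ("both", "sticks_only")
                        else None
                    ),
                    notes=f"synthetic mask={mask}",
                )
            )
    truth = pd.DataFrame(truth_rows).set_index(["company", "year"])
    panel = DisclosurePanel.from_records(
        records,
        companies=[c.name for c in scenario.companies],
        years=list(scenario.years),
    )
    return truth, panel


@dataclass
class RecoveryReport:
    """How well an estimated global series recovers synthetic ground truth."""

    years: tuple[int, ...]
    relative_error: dict[int, float]  # (estimate - truth) / truth per year
    covered: dict[int, bool]  # truth inside [lower, upper]?
    consumption_bias: float | None = None  # estimated/true parameter - 1

    @property
    def max_abs_relative_error(self) -> float:
        finite = [abs(e) for e in self.relative_error.values() if math.isfinite(e)]
        return max(finite) if finite else 0.0

    @property
    def coverage_rate(self) -> float:
        return sum(self.covered.values()) / len(self.covered) if self.covered else 1.0


def recovery_report(
    estimates: Sequence[GlobalSeriesPoint],
    truth: pd.DataFrame,
    true_consumption: float | None = None,
    estimated_consumption: float | None = None,
) -> RecoveryReport:
    """Compare an estimated series against the generator's truth table.

    Relative error compares yearly global totals; coverage asks whether the
    true total lies inside the reported interval. Years with zero truth and
    zero estimate contribute zero error.
    """
    truth_by_year = truth.groupby(level="year")["users"].sum()
    est_years = tuple(p.year for p in estimates)
    if set(est_years) != set(truth_by_year.index):
        raise AlignmentError(
            f"estimate years {sorted(est_years)} != truth years "
            f"{sorted(truth_by_year.index)}"
        )
    rel: dict[int, float] = {}
    cov: dict[int, bool] = {}
    for point in estimates:
        true_total = float(truth_by_year.loc[point.year])
        if true_total == 0:
            rel[point.year] = 0.0 if point.total_central == 0 else math.inf
        else:
            rel[point.year] = (point.total_central - true_total) / true_total
        cov[point.year] = point.total_lower <= true_total <= point.total_upper
    bias = None
    if true_consumption is not None and estimated_consumption is not None:
        bias = estimated_consumption / true_consumption - 1.0
    return RecoveryReport(
        years=est_years, relative_error=rel, covered=cov, consumption_bias=bias
    )


def default_scenario(seed: int = 0, noise_sd: float = 0.05) -> MarketScenario:
    """A four-company market shaped like the real panel.

    One dominant early entrant approaching saturation around 35 million
    users, two mid-size followers and one small domestic player; consumption
    parameters span the 7-12 sticks/day range observed in calibrations. The
    disclosure pattern mirrors real reporting habits: the leader publishes
    both figures from its third year, followers publish sticks only, and the
    smallest discloses nothing for its first two years.
    """
    companies = [
        CompanySpec("AlphaTobacco", 2014, 35e6, 0.55, 2019.5, 11.9, brand="alpha"),
        CompanySpec("BravoBrands", 2016, 12e6, 0.60, 2021.0, 7.8, brand="bravo"),
        CompanySpec("CedarGlobal", 2016, 8e6, 0.55, 2022.0, 7.3, brand="cedar"),
        CompanySpec("DomesticCo", 2017, 3e6, 0.50, 2022.0, 12.2, brand="dom"),
    ]
    years = tuple(range(2014, 2025))
    pattern: dict[tuple[str, int], Mask] = {}
    for spec in companies:
        for year in years:
            if year < spec.launch_year:
                pattern[(spec.name, year)] = "none"
            elif spec.name == "AlphaTobacco":
                pattern[(spec.name, year)] = "both" if year >= 2016 else "none"
            elif spec.name == "DomesticCo":
                pattern[(spec.name, year)] = (
                    "none" if year < spec.launch_year + 2 else "sticks_only"
                )
            else:
                pattern[(spec.name, year)] = "sticks_only"
    return MarketScenario(
        companies=companies,
        years=years,
        disclosure_pattern=pattern,
        shipment_noise_sd=noise_sd,
        seed=seed,
    )


def scenario_from_yaml(source) -> MarketScenario:
    """Load a scenario document (see the packaged default for the schema)."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    companies = [
        CompanySpec(
            name=c["name"],
            launch_year=int(c["launch_year"]),
            carrying_capacity=float(c["carrying_capacity"]),
            growth_rate=float(c["growth_rate"]),
            midpoint_year=float(c["midpoint_year"]),
            consumption=float(c["consumption"]),
            brand=c.get("brand", ""),
        )
        for c in doc["companies"]
    ]
    years = tuple(range(int(doc["years"][0]), int(doc["years"][1]) + 1))
    pattern_doc = doc.get("disclosure_pattern")
    if pattern_doc == "sticks_only" or isinstance(pattern_doc, str):
        pattern = uniform_pattern([c.name for c in companies], years, pattern_doc)
    else:
        pattern = {
            (p["company"], int(p["year"])): p["mask"] for p in pattern_doc or []
        }
    return MarketScenario(
        companies=companies,
        years=years,
        disclosure_pattern=pattern,
        shipment_noise_sd=float(doc.get("shipment_noise_sd", 0.05)),
        seed=int(doc.get("seed", 0)),
    )
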