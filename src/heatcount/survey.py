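"""Survey-based user counts: prevalence x population per country, aggregated.

A complementary check on the disclosure-based series: each country's current
heated-tobacco-use prevalence from a nationally representative survey is
multiplied by the cohort population for the survey year, and the resulting
user counts are summed. Coverage is partial (35 countries with usable
surveys), so the aggregate is a conservative lower bound on the global total,
not a competing estimate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import pandas as pd

from .errors import PanelIntegrityError


@dataclass(frozen=True)
class SurveyRecord:
    """One country's prevalence input and its derived user count.

    ``users_printed`` is the user count as published in the source table;
    ``users_recomputed`` is prevalence/100 x population recomputed here.
    The two can differ by a few persons where the published cell was computed
    from unrounded denominators; ``users`` prefers the printed value.
    """

    country: str
    prevalence: float  # percent of cohort currently using HTP
    survey_year: int
    survey_name: str
    cohort: str
    population_thousands: float
    users_printed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 100:
            raise ValueError(
                f"{self.country}: prevalence must lie in [0, 100], got {self.prevalence}"
            )
        if self.population_thousands <= 0:
            raise ValueError(
                f"{self.country}: population must be positive, got "
                f"{self.population_thousands}"
            )

    @property
    def users_recomputed(self) -> int:
        return users_from_prevalence(self.prevalence, self.population_thousands)

    @property
    def users(self) -> int:
        return self.users_printed if self.users_printed is not None else self.users_recomputed


@dataclass(frozen=True)
class SurveyAggregate:
    """Multi-country total with the largest contributors broken out."""

    n_countries: int
    total_users: int
    top_contributors: tuple[tuple[str, int], ...]
    top_k_share: float  # percent of the total held by the listed contributors


def users_from_prevalence(prevalence: float, population_thousands: float) -> int:
    """Country user count: prevalence (%) x cohort population (thousands).

    Rounded to the nearest whole person, ties half away from zero (the
    convention of the published per-country cells).
    """
    if not 0 <= prevalence <= 100:
        raise ValueError(f"prevalence must lie in [0, 100], got {prevalence}")
    if population_thousands <= 0:
        raise ValueError(f"population must be positive, got {population_thousands}")
    exact = prevalence / 100.0 * population_thousands * 1000.0
    return int(math.floor(exact + 0.5))


def load_survey_table(source) -> list[SurveyRecord]:
    """Load a per-country survey CSV.

    Expected columns: ``country, prevalence_pct, year, survey, cohort,
    population_thousands`` and optionally ``users_printed``. One row per
    country; duplicates are an integrity error.
    """
    raw = pd.read_csv(source, dtype=str, keep_default_na=False)
    records = []
    seen: set[str] = set()
    for row in raw.itertuples(index=False):
        country = row.country.strip()
        if country in seen:
            raise PanelIntegrityError(f"duplicate survey record for {country!r}")
        seen.add(country)
        printed = getattr(row, "users_printed", "").strip()
        records.append(
            SurveyRecord(
                country=country,
                prevalence=float(row.prevalence_pct),
                survey_year=int(row.year),
                survey_name=row.survey.strip(),
                cohort=row.cohort.strip(),
                population_thousands=float(row.population_thousands),
                users_printed=int(printed) if printed else None,
            )
        )
    return records


def aggregate_survey(records: list[SurveyRecord], top_k: int = 5) -> SurveyAggregate:
    """Total the per-country user counts and rank the top contributors.

    Countries are ranked by user count descending, ties broken by country
    label; ``top_k_share`` is the percentage of the aggregate held by the
    ``top_k`` largest countries.
    """
    if not records:
        raise PanelIntegrityError("survey aggregation needs at least one record")
    countries = [r.country for r in records]
    if len(countries) != len(set(countries)):
        raise PanelIntegrityError("duplicate country in survey records")
    total = sum(r.users for r in records)
    ranked = sorted(records, key=lambda r: (-r.users, r.country))
    top = tuple((r.country, r.users) for r in ranked[: max(top_k, 0)])
    share = 100.0 * sum(u for _, u in top) / total if total else 0.0
    return SurveyAggregate(
        n_countries=len(records),
        total_users=total,
        top_contributors=top,
        top_k_share=share,
    )


def survey_frame(records: list[SurveyRecord]) -> pd.DataFrame:
    """Per-country table with printed and recomputed user counts side by side."""
    return pd.DataFrame(
        [
            {
                "country": r.country,
                "prevalence_pct": r.prevalence,
                "survey_year": r.survey_year,
                "survey": r.survey_name,
                "cohort": r.cohort,
                "population_thousands": r.population_thousands,
                "users": r.users,
                "users_recomputed": r.users_recomputed,
            }
            for r in records
        ]
    )


def aggregate_to_json(agg: SurveyAggregate) -> str:
    return json.dumps(
        {
            "n_countries": agg.n_countries,
            "total_users": agg.total_users,
            "top_contributors": [list(t) for t in agg.top_contributors],
            "top_k_share_pct": agg.top_k_share,
        },
        indent=2,
    )


def load_bundled_survey() -> list[SurveyRecord]:
    """Load the packaged 35-country survey table."""
    import io
    from importlib.resources import files

    data = files("heatcount.data").joinpath("table2_surveys.csv").read_text()
    return load_survey_table(io.StringIO(data))
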