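"""Assumption configuration: brand consumption parameters and panel rules.

All tunable analysis choices live in one YAML document — per-brand
sticks-per-day parameters (with their calibration donors and published
rounding), the literature parameter with its 95% CI, the gap-filling
imputation rules, and the double-counting reconciliation rule — so a run is
fully determined by a panel file plus a config file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import yaml

from .conversion import BoundMode, ConsumptionAssumption, calibrate_brand_consumption
from .errors import ConfigurationError
from .series import ImputationRuleSet, ReconciliationRule, ShareCarryRule, SplitCarryRule


@dataclass
class BrandEntry:
    """One brand's conversion settings as declared in the config."""

    company: str
    central: float
    donor: str | None = None
    rounding: int = 1
    bound_mode: BoundMode = BoundMode.MULTIPLICATIVE

    def assumption(self) -> ConsumptionAssumption:
        return ConsumptionAssumption(
            brand_scope=frozenset([self.company]),
            sticks_per_day_central=float(self.central),
            bound_mode=self.bound_mode,
            provenance=f"configured central (donor {self.donor}, rounding {self.rounding})",
        )


@dataclass
class AssumptionsConfig:
    """Parsed assumptions document."""

    brands: dict[str, BrandEntry]
    literature: ConsumptionAssumption
    imputation: ImputationRuleSet = field(default_factory=ImputationRuleSet)
    reconciliation: ReconciliationRule | None = None

    def conversion_assumptions(self) -> dict[str, ConsumptionAssumption]:
        """Per-company assumptions at the configured central values."""
        return {c: e.assumption() for c, e in self.brands.items()}

    def calibrated_assumptions(self, panel) -> dict[str, ConsumptionAssumption]:
        """Recalibrate every donor-backed parameter from the panel itself.

        Brands sharing a donor share the calibration; brands without a donor
        keep their configured central. The configured centrals are expected to
        equal the recalibrated ones on the shipped panel — a mismatch means
        the panel and config drifted apart.
        """
        by_donor: dict[tuple[str, int], ConsumptionAssumption] = {}
        out: dict[str, ConsumptionAssumption] = {}
        for company, entry in self.brands.items():
            if entry.donor is None:
                out[company] = entry.assumption()
                continue
            key = (entry.donor, entry.rounding)
            if key not in by_donor:
                by_donor[key] = calibrate_brand_consumption(
                    panel, entry.donor, entry.rounding, bound_mode=entry.bound_mode
                )
            base = by_donor[key]
            out[company] = ConsumptionAssumption(
                brand_scope=frozenset([company]),
                sticks_per_day_central=base.sticks_per_day_central,
                bound_mode=entry.bound_mode,
                provenance=base.provenance,
            )
        return out


def _parse_bound_mode(raw: str | None) -> BoundMode:
    if raw is None:
        return BoundMode.MULTIPLICATIVE
    try:
        return BoundMode(raw)
    except ValueError:
        raise ConfigurationError(f"unknown bound mode {raw!r}") from None


def parse_assumptions(doc: dict) -> AssumptionsConfig:
    """Build an :class:`AssumptionsConfig` from a parsed YAML document."""
    brands: dict[str, BrandEntry] = {}
    for company, entry in (doc.get("conversion") or {}).items():
        if "central" not in entry:
            raise ConfigurationError(f"brand entry {company!r} lacks a central value")
        brands[company] = BrandEntry(
            company=company,
            central=float(entry["central"]),
            donor=entry.get("donor"),
            rounding=int(entry.get("rounding", 1)),
            bound_mode=_parse_bound_mode(entry.get("bound_mode")),
        )

    lit = doc.get("literature")
    if not lit or "central" not in lit:
        raise ConfigurationError("config lacks a literature consumption block")
    ci = lit.get("ci")
    literature = ConsumptionAssumption(
        brand_scope=frozenset(brands) or frozenset({"*"}),
        sticks_per_day_central=float(lit["central"]),
        bound_mode=BoundMode.PARAMETER_CI if ci else BoundMode.NONE,
        lower_param=float(ci[0]) if ci else None,
        upper_param=float(ci[1]) if ci else None,
        provenance="literature mean daily consumption with 95% CI",
    )

    imp = doc.get("imputation") or {}
    rules = ImputationRuleSet(
        launch_zero=[(c, int(y)) for c, y in imp.get("launch_zero", [])],
        share_carry=[
            ShareCarryRule(
                company=r["company"],
                source_year=int(r["source_year"]),
                target_years=tuple(int(y) for y in r["target_years"]),
                share=float(r["share"]),
            )
            for r in imp.get("share_carry", [])
        ],
        split_carry=[
            SplitCarryRule(
                company=r["company"],
                source_year=int(r["source_year"]),
                target_years=tuple(int(y) for y in r["target_years"]),
                source_domestic=r.get("source_domestic"),
                source_total=r.get("source_total"),
            )
            for r in imp.get("split_carry", [])
        ],
    )

    rec_doc = doc.get("reconciliation")
    reconciliation = None
    if rec_doc:
        reconciliation = ReconciliationRule(
            absorbing_company=rec_doc["absorbing"],
            absorbed_company=rec_doc["absorbed"],
            effective_from_year=int(rec_doc["effective_from"]),
            domestic_market_retained=bool(rec_doc.get("domestic_market_retained", True)),
        )

    return AssumptionsConfig(
        brands=brands,
        literature=literature,
        imputation=rules,
        reconciliation=reconciliation,
    )


def load_assumptions(source) -> AssumptionsConfig:
    """Load an assumptions YAML file (path or file-like)."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    return parse_assumptions(doc or {})


def default_assumptions() -> AssumptionsConfig:
    """The packaged default assumptions for the 2014-2024 analysis."""
    from importlib.resources import files

    text = files("heatcount.data").joinpath("assumptions.yaml").read_text()
    return parse_assumptions(yaml.safe_load(io.StringIO(text)))
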