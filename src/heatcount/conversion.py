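"""Shipment-to-user conversion, consumption calibration, sensitivity bounds.

The core estimator: a company-year with shipments but no published user count
is assigned

    users = sticks / (sticks_per_day * 365)

where ``sticks_per_day`` is the brand's assumed mean daily consumption per
user. Parameters are either calibrated from a donor company's dual-disclosure
years (years publishing both users and sticks) or taken from survey
literature. Converted estimates carry uncertainty bounds; directly reported
user counts carry none.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .errors import CalibrationError, ConfigurationError

DAYS_PER_YEAR = 365  # fixed by convention; leap years ignored


class BoundMode(str, Enum):
    """How uncertainty bounds are attached to a converted estimate.

    ``multiplicative_user_bounds``
        +/-50% applied to the converted user count itself (x0.5, x1.5) —
        symmetric in user space.
    ``parameter_ci_bounds``
        Recompute users at the consumption parameter's CI endpoints; the
        upper consumption endpoint yields the lower user bound and vice
        versa.
    ``none``
        Bounds collapse onto the central value.
    """

    MULTIPLICATIVE = "multiplicative_user_bounds"
    PARAMETER_CI = "parameter_ci_bounds"
    NONE = "none"


class EstimateMethod(str, Enum):
    REPORTED = "reported"
    CONVERTED = "converted"
    IMPUTED_ZERO = "imputed_zero"


@dataclass(frozen=True)
class ConsumptionAssumption:
    """A sticks-per-day parameter and the rule bounding estimates made with it."""

    brand_scope: frozenset[str]
    sticks_per_day_central: float
    bound_mode: BoundMode = BoundMode.MULTIPLICATIVE
    lower_param: float | None = None
    upper_param: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sticks_per_day_central <= 0:
            raise ValueError(
                f"consumption must be positive, got {self.sticks_per_day_central}"
            )
        if self.lower_param is not None and self.upper_param is not None:
            if not (self.lower_param <= self.sticks_per_day_central <= self.upper_param):
                raise ValueError(
                    "consumption CI must bracket the central value: "
                    f"{self.lower_param} <= {self.sticks_per_day_central} "
                    f"<= {self.upper_param} fails"
                )


@dataclass(frozen=True)
class UserEstimate:
    """Central/lower/upper user count for one company-year."""

    company: str
    year: int
    central: float
    lower: float
    upper: float
    method: EstimateMethod
    assumption: ConsumptionAssumption | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.central <= self.upper):
            raise ValueError(
                f"{self.company} {self.year}: bounds must satisfy "
                f"0 <= lower <= central <= upper, got "
                f"({self.lower}, {self.central}, {self.upper})"
            )
        if self.method is EstimateMethod.REPORTED and not (
            self.lower == self.central == self.upper
        ):
            raise ValueError("reported estimates carry no sensitivity bounds")


def sticks_to_users(sticks: float, assumption: ConsumptionAssumption) -> float:
    """Convert an annual shipment volume to an implied user count.

    Exact real-valued result; display rounding is deferred to reporting.
    """
    if sticks < 0:
        raise ValueError(f"shipment volume must be non-negative, got {sticks}")
    return sticks / (assumption.sticks_per_day_central * DAYS_PER_YEAR)


def implied_daily_consumption(sticks: float, users: float) -> float:
    """Mean sticks per user per day implied by one dual-disclosure year."""
    if users <= 0:
        raise ZeroDivisionError(
            f"implied consumption undefined for non-positive user count {users}"
        )
    if sticks < 0:
        raise ValueError(f"shipment volume must be non-negative, got {sticks}")
    return sticks / (users * DAYS_PER_YEAR)


def calibrate_brand_consumption(
    panel,
    donor_company: str,
    rounding: int,
    scope: Sequence[str] | None = None,
    bound_mode: BoundMode = BoundMode.MULTIPLICATIVE,
) -> ConsumptionAssumption:
    """Calibrate a sticks-per-day parameter from a donor's dual-disclosure years.

    Takes the arithmetic mean of the per-year implied consumption ratios over
    every donor year with strictly positive users and sticks, then rounds to
    ``rounding`` decimals (the published precision of the parameter). The
    mean of per-year ratios weights each disclosure year equally rather than
    weighting by volume as a pooled ratio would.

    ``scope`` names the companies the parameter will be applied to (defaults
    to the donor itself — useful when a company that discloses no user counts
    borrows another brand's calibration).
    """
    ratios = []
    years = []
    for year in panel.years:
        users = panel.users(donor_company, year)
        sticks = panel.sticks(donor_company, year)
        if users and sticks and users > 0 and sticks > 0:
            ratios.append(implied_daily_consumption(sticks, users))
            years.append(year)
    if not ratios:
        raise CalibrationError(
            f"{donor_company}: no dual-disclosure year with positive users and sticks"
        )
    mean_ratio = sum(ratios) / len(ratios)
    central = round(mean_ratio, rounding)
    if rounding <= 0:
        central = float(int(central))
    return ConsumptionAssumption(
        brand_scope=frozenset(scope if scope is not None else [donor_company]),
        sticks_per_day_central=central,
        bound_mode=bound_mode,
        provenance=(
            f"mean of per-year implied ratios for {donor_company} over "
            f"{years} (unrounded {mean_ratio:.4f})"
        ),
    )


def sensitivity_bounds(
    central: float,
    method: EstimateMethod,
    assumption: ConsumptionAssumption | None = None,
) -> tuple[float, float]:
    """Lower/upper user bounds for one estimate.

    Reported (and imputed-zero) counts are taken at face value. Converted
    estimates are bounded according to the assumption's mode: +/-50% in user
    space, or re-conversion at the consumption CI endpoints (users scale as
    1/consumption, so the upper endpoint gives the lower user bound).
    """
    if central < 0:
        raise ValueError(f"central estimate must be non-negative, got {central}")
    if method in (EstimateMethod.REPORTED, EstimateMethod.IMPUTED_ZERO):
        return central, central
    if assumption is None:
        raise ConfigurationError("converted estimate needs a consumption assumption")
    mode = assumption.bound_mode
    if mode is BoundMode.NONE:
        return central, central
    if mode is BoundMode.MULTIPLICATIVE:
        return 0.5 * central, 1.5 * central
    if mode is BoundMode.PARAMETER_CI:
        if assumption.lower_param is None or assumption.upper_param is None:
            raise ConfigurationError(
                "parameter_ci_bounds requires lower and upper consumption params"
            )
        c = assumption.sticks_per_day_central
        return central * c / assumption.upper_param, central * c / assumption.lower_param
    raise ConfigurationError(f"unknown bound mode {mode!r}")
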