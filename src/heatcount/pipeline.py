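"""End-to-end runs wiring the packaged data and default assumptions together."""

from __future__ import annotations

from .config import AssumptionsConfig, default_assumptions
from .panel import DisclosurePanel, load_bundled_panel
from .series import (
    GlobalSeriesPoint,
    build_alternative_series,
    build_primary_series,
    impute_panel,
    reconcile_overlap,
)
from .survey import SurveyAggregate, aggregate_survey, load_bundled_survey


def prepare_panel(
    panel: DisclosurePanel | None = None,
    config: AssumptionsConfig | None = None,
) -> DisclosurePanel:
    """Impute gaps and apply reconciliation; the panel both series start from."""
    panel = panel if panel is not None else load_bundled_panel()
    config = config if config is not None else default_assumptions()
    prepared = impute_panel(panel, config.imputation)
    if config.reconciliation is not None:
        prepared = reconcile_overlap(prepared, config.reconciliation)
    return prepared


def run_primary(
    panel: DisclosurePanel | None = None,
    config: AssumptionsConfig | None = None,
) -> list[GlobalSeriesPoint]:
    """Primary mixed reported/converted series on the (default) panel."""
    config = config if config is not None else default_assumptions()
    prepared = prepare_panel(panel, config)
    return build_primary_series(prepared, config.conversion_assumptions())


def run_alternative(
    panel: DisclosurePanel | None = None,
    config: AssumptionsConfig | None = None,
) -> list[GlobalSeriesPoint]:
    """Shipment-only series under the literature consumption parameter."""
    config = config if config is not None else default_assumptions()
    prepared = prepare_panel(panel, config)
    return build_alternative_series(prepared, config.literature)


def run_survey(top_k: int = 5) -> SurveyAggregate:
    """Aggregate the packaged 35-country survey table."""
    return aggregate_survey(load_bundled_survey(), top_k=top_k)
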