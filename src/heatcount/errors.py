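"""Exception hierarchy for the disclosure-estimation pipeline."""


class HeatcountError(Exception):
    """Base class for all pipeline errors."""


class PanelParseError(HeatcountError):
    """A cell in a disclosure table could not be parsed."""


class PanelIntegrityError(HeatcountError):
    """Duplicate or structurally inconsistent panel records."""


class PanelValidationError(HeatcountError):
    """A record violates the panel's domain constraints."""


class AmbiguousVintageError(HeatcountError):
    """Two disclosures share the latest vintage but disagree on values."""


class CalibrationError(HeatcountError):
    """No usable dual-disclosure year for consumption calibration."""


class ConfigurationError(HeatcountError):
    """Missing or inconsistent assumption configuration."""


class RuleConflictError(HeatcountError):
    """An imputation rule targets a cell that already holds data."""


class RuleError(HeatcountError):
    """A rule references companies or years outside the panel."""


class CoverageError(HeatcountError):
    """A company-year resolves to neither a value nor an applicable rule."""


class AlignmentError(HeatcountError):
    """Estimate and truth series cover different years."""


class ScenarioError(HeatcountError):
    """A synthetic market scenario is internally inconsistent."""
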