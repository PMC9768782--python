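"""Exception hierarchy shared across the pipeline."""


class IcushiftError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IcushiftError):
    """Invalid configuration (bad proportions, empty grids, degenerate specs)."""


class InputError(IcushiftError):
    """Invalid numeric input (non-finite features, non-positive creatinine)."""


class SchemaError(IcushiftError):
    """Tabular input violates the documented cohort schema."""


class DataError(IcushiftError):
    """Semantically impossible data (e.g. readmission before ICU discharge)."""


class MissingBaselineError(IcushiftError):
    """No creatinine observation in the baseline window; the stay cannot be staged."""


class DegenerateTaskError(IcushiftError):
    """Training labels contain a single class."""


class InterfaceError(IcushiftError):
    """Feature-name mismatch between a trained model and the matrix offered to it."""


class UndefinedMetricError(IcushiftError):
    """Metric undefined for the given labels (e.g. AUROC with one class)."""


class InfeasibleSplitError(IcushiftError):
    """A scenario split cannot be realized on this cohort (empty side/group)."""
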