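"""Exception hierarchy shared across the pipeline."""


class MrflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrflowError):
    """Invalid configuration: bad column map, unknown key, out-of-domain value."""


class DataError(MrflowError):
    """Invalid input data: duplicate identifiers, malformed rows."""


class InsufficientDataError(MrflowError):
    """Too few SNPs for the requested estimator or test."""


class EstimationError(MrflowError):
    """Estimation failed (empty set, degenerate design, non-convergence)."""


class PanelLookupError(MrflowError):
    """A variant required for an LD lookup is absent from the reference panel."""


class StateError(MrflowError):
    """An operation was called before its prerequisite (e.g. outlier test before global)."""
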