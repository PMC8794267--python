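"""Exception hierarchy shared across the simulator."""


class EmbryoPhaseError(Exception):
    """Base class for all package errors."""


class GeometryError(EmbryoPhaseError):
    """A shape does not fit the computational grid."""


class NumericError(EmbryoPhaseError):
    """A numerical procedure failed to converge or produced non-finite values."""


class InstabilityError(NumericError):
    """Time integration produced non-finite field values."""


class DegenerateFieldError(EmbryoPhaseError):
    """An operation requires a field with positive mass."""


class DivisionError(EmbryoPhaseError):
    """Cytokinesis bisection could not reach the requested volume ratio."""


class LineageError(EmbryoPhaseError):
    """Cell naming is inconsistent with the lineage bookkeeping."""


class ConfigError(EmbryoPhaseError):
    """A scenario configuration is invalid; the message names offending keys."""


class FitError(EmbryoPhaseError):
    """A regression is degenerate (too few points or zero variance)."""
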