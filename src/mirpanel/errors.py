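"""Exception hierarchy for the mirpanel pipeline.

Every stage raises a subclass of :class:`MirPanelError`, so callers can
distinguish configuration problems (bad parameters, impossible designs)
from data problems (malformed files, missing values) and from numerically
degenerate inputs.
"""


class MirPanelError(Exception):
    """Base class for all mirpanel errors."""


class ConfigurationError(MirPanelError):
    """Invalid configuration: a named invariant or precondition is violated."""


class DegenerateInputError(MirPanelError):
    """Input is structurally valid but numerically degenerate (e.g. trimming
    would empty the negative-control set, or no probe survives background
    subtraction in a sample)."""


class DataError(MirPanelError):
    """Required data are missing or inconsistent (e.g. a recurrence subject
    without a recurrence time, or a sample lacking a panel member value)."""


class FitError(MirPanelError):
    """A model fit failed, e.g. a singular pooled covariance."""


class ParseError(MirPanelError):
    """A file could not be parsed; the message carries file/location context."""
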